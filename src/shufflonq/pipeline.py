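"""Run configuration and the end-to-end analysis pipeline.

``run_pipeline`` ties the stages together the way the quantitative
structural-variation analysis is meant to be run on one isolate:
enumerate candidate arrangements, quantify them from spanning long reads,
type pilV variants on each platform, compare platforms when both read sets
are present, and characterise the inverted repeats.  Every output is a
deterministic function of the config plus inputs, and the run summary
records all parameters needed to reproduce them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .enumeration import build_candidates, count_arrangements
from .locus import load_locus
from .pilv import LONG, SHORT, TypeParams, compare_platforms, variant_ratios
from .quantify import AssignParams, quantify_structures
from .repeats import (
    degenerate_consensus,
    extract_repeats,
    hamming_matrix,
    min_spanning_network,
    pairwise_identity,
    position_frequency_matrix,
)
from .seqio import read_sequences, write_sequences

log = logging.getLogger("shufflonq")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    locus_gff: str
    plasmid_fasta: str
    out_dir: str
    long_reads: str | None = None
    short_reads_r1: str | None = None
    short_reads_r2: str | None = None
    seed: int = 0
    min_anchor_len: int = 50
    min_identity: float = 0.80
    margin: float = 0.02
    short_identity: float = 0.90
    long_identity: float = 0.80
    repeat_window: int = 23

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _tsv_header(stage: str, config: RunConfig) -> str:
    return f"# shufflonq {__version__} | stage={stage} | seed={config.seed}\n"


def _write_tsv(df, path: Path, stage: str, config: RunConfig, extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(stage, config))
        if extra:
            fh.write(extra)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all applicable stages; returns the run summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:
                summary["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            summary["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info("stage %s: done", name)
            return result

        return wrap

    @stage("load_locus")
    def locus():
        return load_locus(
            config.plasmid_fasta, config.locus_gff, min_anchor_len=config.min_anchor_len
        )

    @stage("enumerate")
    def candidates():
        cands = build_candidates(locus)
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq(cands.sequences[arr]), id=cands.labels[arr].replace(" ", "_"), description="")
            for arr in cands.space
        ]
        write_sequences(recs, out / "candidates.fa")
        summary["n_segments"] = locus.n
        summary["n_candidates"] = len(cands.space)
        summary["count_formula"] = count_arrangements(locus.n)
        return cands

    long_table = None
    if config.long_reads:

        @stage("quantify")
        def long_table():
            reads = read_sequences(config.long_reads)
            params = AssignParams(min_identity=config.min_identity, margin=config.margin)
            table = quantify_structures(reads, locus, params)
            totals = "".join(f"# {k}={v}\n" for k, v in table.totals.items())
            _write_tsv(table.table, out / "abundance.tsv", "quantify", config, totals)
            summary["abundance_totals"] = table.totals
            return table

        @stage("type_pilv_long")
        def variants_long():
            reads = read_sequences(config.long_reads)
            vt = variant_ratios(
                reads, locus, platform=LONG, params=TypeParams(min_identity=config.long_identity)
            )
            _write_tsv(vt.table, out / "variants_long.tsv", "type_pilv_long", config)
            summary["informative_long"] = vt.total_informative
            return vt

    variants_short = None
    if config.short_reads_r1:

        @stage("type_pilv_short")
        def variants_short():
            r1 = read_sequences(config.short_reads_r1)
            if config.short_reads_r2:
                r2 = read_sequences(config.short_reads_r2)
                items, paired = list(zip(r1, r2)), True
            else:
                items, paired = r1, False
            vt = variant_ratios(
                items,
                locus,
                platform=SHORT,
                params=TypeParams(min_identity=config.short_identity),
                paired=paired,
            )
            _write_tsv(vt.table, out / "variants_short.tsv", "type_pilv_short", config)
            summary["informative_short"] = vt.total_informative
            return vt

    if config.long_reads and config.short_reads_r1:

        @stage("compare_platforms")
        def comparison():
            comp = compare_platforms(variants_long, variants_short)
            _write_tsv(comp.as_frame(), out / "platform_comparison.tsv", "compare_platforms", config)
            summary["r_squared"] = comp.r_squared
            return comp

    @stage("repeats")
    def _repeats():
        reps = extract_repeats(locus, window_len=config.repeat_window)
        (out / "consensus.txt").write_text(degenerate_consensus(reps.sequences) + "\n")
        import pandas as pd

        ident = pd.DataFrame(pairwise_identity(reps.sequences), index=reps.labels, columns=reps.labels)
        ident.to_csv(out / "identity.tsv", sep="\t", float_format="%.2f")
        ham = hamming_matrix(reps.sequences, window=min(config.repeat_window, len(reps.sequences[0])))
        pd.DataFrame(ham, index=reps.labels, columns=reps.labels).to_csv(out / "hamming.tsv", sep="\t")
        msn = min_spanning_network(ham, labels=reps.labels)
        _write_tsv(msn.as_frame(), out / "msn.tsv", "repeats", config)
        position_frequency_matrix(reps.sequences).to_csv(out / "pfm.tsv", sep="\t")
        summary["repeat_consensus"] = degenerate_consensus(reps.sequences)
        return reps

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
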