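"""Synthetic shufflon loci, heterogeneous populations and sequencing reads.

The generator emulates, at desk scale, the statistical structure of the
study design this package targets: a single-copy circular plasmid carrying
a shufflon of 1-3 invertible segments; a clonal population heterogeneous
over whole-shufflon arrangements with a known frequency vector; PacBio-like
long reads (multi-kb, indel-dominated errors) and MiSeq-like ~2x300 bp
pairs from ~400 bp inserts.  Every read carries a ground-truth record, and
all output is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enumeration import build_candidates, enumerate_arrangements
from .locus import Arrangement, ArrangementSpace, SegmentDef, ShufflonLocus, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: where the locus is embedded on the synthetic plasmid (0-based)
LOCUS_OFFSET = 10_000


@dataclass(frozen=True)
class LongReadConfig:
    """PacBio-subread-like reads: lognormal lengths, indel-dominated errors."""

    mean_len: int = 8_000
    sigma: float = 0.5  # lognormal shape; mean is mean_len
    min_len: int = 500
    sub_rate: float = 0.015
    ins_rate: float = 0.09
    del_rate: float = 0.04


@dataclass(frozen=True)
class ShortReadConfig:
    """MiSeq-like 2x300 pairs from ~400 bp inserts, substitution errors only."""

    read_len: int = 300
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    sub_rate: float = 0.005


@dataclass(frozen=True)
class SimConfig:
    seed: int  # mandatory: every generator output is a function of it
    n_segments: int = 3
    segment_len: int = 300
    anchor_len: int = 500
    repeat_consensus: str = "GTGCCAATCCGGTNNGTGGA"
    plasmid_len: int = 60_000
    two_orf: tuple[bool, ...] | None = None  # default: all segments two-ORF
    long_read: LongReadConfig = field(default_factory=LongReadConfig)
    short_read: ShortReadConfig = field(default_factory=ShortReadConfig)

    def __post_init__(self) -> None:
        for r in (
            self.long_read.sub_rate,
            self.long_read.ins_rate,
            self.long_read.del_rate,
            self.short_read.sub_rate,
        ):
            if not 0 <= r < 1:
                raise ValueError("error rates must be in [0, 1)")
        if self.two_orf is not None and len(self.two_orf) != self.n_segments:
            raise ValueError("two_orf flags must match n_segments")


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config_seed, spawn_key=(stream,)))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


_SEGMENT_NAMES = "ABCDEFGHJK"
_PRIME = "′"


def make_locus(config: SimConfig) -> ShufflonLocus:
    """Generate a random plasmid carrying a shufflon locus (seed-determined).

    Segment bodies are random (hence pairwise non-homologous and
    non-palindromic with overwhelming probability at default lengths);
    junction repeats are the consensus with its N positions drawn
    independently per junction; the locus replaces the plasmid sequence at
    a fixed offset.  Segment names are A, B, C, ...; a two-ORF segment X
    carries ORFs "X" and "X'".
    """
    rng = _rng(config.seed, 0)
    n = config.n_segments
    if n < 1:
        raise ValueError("need at least one segment")
    plasmid = list(_random_dna(rng, config.plasmid_len))
    pilv = _random_dna(rng, config.anchor_len)
    rci = _random_dna(rng, config.anchor_len)
    junctions = []
    for _ in range(n + 1):
        junctions.append(
            "".join(
                b if b != "N" else "ACGT"[rng.integers(4)] for b in config.repeat_consensus
            )
        )
    two_orf = config.two_orf or (True,) * n
    segments = []
    for i in range(n):
        name = _SEGMENT_NAMES[i]
        body = _random_dna(rng, config.segment_len)
        if two_orf[i]:
            ol, orr = name, name + _PRIME
        else:
            ol, orr = name + _PRIME, None
        segments.append(
            SegmentDef(
                name=name,
                body=body,
                left_repeat=junctions[i],
                right_repeat=junctions[i + 1],
                orf_left=ol,
                orf_right=orr,
            )
        )
    locus_seq = pilv + junctions[0]
    for i, seg in enumerate(segments):
        locus_seq += seg.body + junctions[i + 1]
    locus_seq += rci
    plasmid[LOCUS_OFFSET : LOCUS_OFFSET + len(locus_seq)] = locus_seq
    return ShufflonLocus(
        plasmid_id=f"sim_plasmid_n{n}",
        plasmid_seq="".join(plasmid),
        pilv_anchor=pilv,
        rci_anchor=rci,
        segments=tuple(segments),
        junctions=tuple(junctions),
        locus_start=LOCUS_OFFSET,
        circular=True,
    )


@dataclass(frozen=True)
class Population:
    """A clonal population: one locus, a frequency per arrangement."""

    locus: ShufflonLocus
    space: ArrangementSpace
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.space):
            raise ValueError("frequency vector length must equal arrangement count")
        freqs = np.asarray(self.frequencies)
        if (freqs < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    def as_series(self) -> pd.Series:
        labels = [self.locus.label(a) for a in self.space]
        return pd.Series(self.frequencies, index=labels)


def sample_population(
    locus: ShufflonLocus,
    frequencies=None,
    seed: int | None = None,
) -> Population:
    """Fix the arrangement mixture used by the read simulators.

    ``frequencies=None`` draws a flat Dirichlet(1,...,1) vector with the
    given seed (reproducible); an explicit vector is validated and used
    as-is, ordered like ``enumerate_arrangements``.
    """
    space = enumerate_arrangements(locus)
    if frequencies is None:
        if seed is None:
            raise ValueError("a seed is required to draw a Dirichlet frequency vector")
        rng = np.random.default_rng(seed)
        frequencies = rng.dirichlet(np.ones(len(space)))
    freqs = tuple(float(f) for f in frequencies)
    return Population(locus=locus, space=space, frequencies=freqs)


# ---------------------------------------------------------------------------
# Error model


def mutate(seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float) -> str:
    """Apply per-base substitution/insertion/deletion errors to a sequence."""
    if sub == ins == dele == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    u = rng.random(arr.size)
    keep = u >= dele
    do_sub = (u >= dele) & (u < dele + sub)
    if do_sub.any():
        # replace with one of the three other bases
        idx = np.searchsorted(_BASES, arr[do_sub])
        shift = rng.integers(1, 4, size=int(do_sub.sum()))
        arr[do_sub] = _BASES[(idx + shift) % 4]
    kept = arr[keep]
    if ins > 0:
        gaps = rng.random(kept.size + 1) < ins
        pos = np.nonzero(gaps)[0]
        if pos.size:
            kept = np.insert(kept, pos, rng.choice(_BASES, size=pos.size))
    return kept.tobytes().decode()


def _variant_plasmid(population: Population, arrangement: Arrangement) -> str:
    """Whole plasmid carrying the given arrangement at the locus."""
    locus = population.locus
    cand = build_candidates(locus).sequences[arrangement]
    return locus.plasmid_seq[: locus.locus_start] + cand + locus.plasmid_seq[locus.locus_end :]


def _record(read_id: str, seq: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = [40] * len(seq)
    return rec


def simulate_long_reads(
    population: Population,
    count: int,
    config: SimConfig,
    spanning_only: bool = False,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Draw long reads from a heterogeneous circular-plasmid population.

    Per read: arrangement ~ population frequencies; start uniform on the
    circular plasmid; length lognormal; random strand; substitution /
    insertion / deletion errors at the configured rates.  With
    ``spanning_only`` the (start, length) draw is rejection-sampled until
    the read covers the full pilV-to-rci locus, emulating the informative
    subset of a whole-genome run.  Returns (records, ground-truth table);
    truth coordinates are modulo plasmid length.
    """
    locus = population.locus
    lr = config.long_read
    rng = _rng(config.seed, 1)
    plen = locus.plasmid_len
    locus_span = locus.locus_end - locus.locus_start
    mu = np.log(lr.mean_len) - lr.sigma**2 / 2
    variants: dict[Arrangement, str] = {}
    arrs = list(population.space)
    freqs = np.asarray(population.frequencies)
    records: list[SeqRecord] = []
    truth_rows = []
    for i in range(count):
        k = int(rng.choice(len(arrs), p=freqs))
        arr = arrs[k]
        while True:
            length = int(np.clip(rng.lognormal(mu, lr.sigma), lr.min_len, 4 * lr.mean_len))
            start = int(rng.integers(plen))
            if not spanning_only:
                break
            if (locus.locus_start - start) % plen + locus_span <= length:
                break
        if arr not in variants:
            variants[arr] = _variant_plasmid(population, arr)
        doubled = variants[arr] + variants[arr]
        raw = doubled[start : start + min(length, plen)]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = revcomp(raw)
        seq = mutate(raw, rng, lr.sub_rate, lr.ins_rate, lr.del_rate)
        rid = f"lr{i:05d}"
        records.append(_record(rid, seq))
        truth_rows.append(
            {
                "read_id": rid,
                "arrangement": locus.label(arr),
                "start": start,
                "length": len(raw),
                "strand": strand,
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["frequencies"] = dict(population.as_series())
    return records, truth


def simulate_short_pairs(
    population: Population,
    pairs: int,
    config: SimConfig,
    region: tuple[int, int] | None = None,
) -> tuple[list[SeqRecord], list[SeqRecord], pd.DataFrame]:
    """Draw FR-orientation paired-end reads from the population.

    Insert lengths are Normal(insert_mean, insert_sd) truncated at
    read_len; insert start is uniform on the circular plasmid, or within
    ``region`` (0-based half-open; inserts start inside it) when given -
    e.g. the locus span, to emulate the junction-informative subset of a
    deep run at desk scale.  Substitution errors only.
    """
    locus = population.locus
    sr = config.short_read
    rng = _rng(config.seed, 2)
    plen = locus.plasmid_len
    variants: dict[Arrangement, str] = {}
    arrs = list(population.space)
    freqs = np.asarray(population.frequencies)
    r1s: list[SeqRecord] = []
    r2s: list[SeqRecord] = []
    truth_rows = []
    for i in range(pairs):
        k = int(rng.choice(len(arrs), p=freqs))
        arr = arrs[k]
        insert = max(sr.read_len, int(round(rng.normal(sr.insert_mean, sr.insert_sd))))
        if region is None:
            start = int(rng.integers(plen))
        else:
            start = int(rng.integers(region[0], region[1]))
        if arr not in variants:
            variants[arr] = _variant_plasmid(population, arr)
        doubled = variants[arr] + variants[arr]
        frag = doubled[start : start + insert]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        m1 = mutate(frag[: sr.read_len], rng, sr.sub_rate, 0.0, 0.0)
        m2 = mutate(revcomp(frag)[: sr.read_len], rng, sr.sub_rate, 0.0, 0.0)
        rid = f"pr{i:05d}"
        r1s.append(_record(rid + "/1", m1))
        r2s.append(_record(rid + "/2", m2))
        truth_rows.append(
            {
                "read_id": rid,
                "arrangement": locus.label(arr),
                "start": start,
                "insert": insert,
                "strand": strand,
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["frequencies"] = dict(population.as_series())
    return r1s, r2s, truth
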