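"""Coverage summaries, plasmid copy numbers, and paired-end class tracks.

Copy number of a plasmid is estimated as its mean read coverage divided by
the chromosomal mean coverage (a single-copy plasmid gives ~1.0).  The
paired-end class track splits per-position coverage into pairs mapped in
the expected FR orientation at a sane insert size ("proper") versus
orientation-discordant / cross-replicon / mate-unmapped pairs ("broken");
against a reference carrying one fixed arrangement, broken coverage piles
up inside a rearranged shufflon and stays flat elsewhere.

Alignments are consumed from coordinate-sorted SAM produced by an external
mapper; mapping itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import pysam


@dataclass(frozen=True)
class DepthSummary:
    replicon: str
    mean_depth: float
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("replicon length must be positive")
        if self.mean_depth < 0:
            raise ValueError("mean depth cannot be negative")


def mean_depth(depth_records, replicon: str, length: int | None = None) -> DepthSummary:
    """Arithmetic mean depth over all reference positions of a replicon.

    ``depth_records`` is a DataFrame with columns (replicon, pos, depth) or
    an iterable of such tuples, as produced by ``samtools depth``.
    Positions absent from the records count as zero: the sum of depths is
    divided by the replicon length (default: the maximum listed position).
    """
    if isinstance(depth_records, pd.DataFrame):
        df = depth_records
        df = df.rename(columns=dict(zip(df.columns[:3], ("replicon", "pos", "depth"))))
    else:
        df = pd.DataFrame(depth_records, columns=["replicon", "pos", "depth"])
    sub = df[df["replicon"] == replicon]
    if sub.empty:
        raise ValueError(f"no depth records for replicon {replicon!r}")
    if length is None:
        length = int(sub["pos"].max())
    return DepthSummary(replicon, float(sub["depth"].sum()) / length, length)


@dataclass(frozen=True)
class CopyNumberEntry:
    plasmid: str
    ratio: float
    rounded: float  # half-up to one decimal, as printed in genome tables


def copy_number(plasmid_summary: DepthSummary, chromosome_summary: DepthSummary) -> CopyNumberEntry:
    """Plasmid copy number = plasmid mean depth / chromosomal mean depth."""
    if chromosome_summary.mean_depth <= 0:
        raise ValueError("chromosome mean depth must be positive")
    ratio = plasmid_summary.mean_depth / chromosome_summary.mean_depth
    rounded = float(Decimal(repr(ratio)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return CopyNumberEntry(plasmid_summary.replicon, ratio, rounded)


def copy_number_report(
    summaries: list[DepthSummary], chromosome: str
) -> pd.DataFrame:
    """Copy numbers of every replicon relative to the named chromosome."""
    by_name = {s.replicon: s for s in summaries}
    if chromosome not in by_name:
        raise ValueError(f"chromosome {chromosome!r} not among summaries")
    chrom = by_name[chromosome]
    rows = []
    for s in summaries:
        entry = copy_number(s, chrom)
        rows.append(
            {
                "replicon": s.replicon,
                "mean_depth": s.mean_depth,
                "length": s.length,
                "ratio": entry.ratio,
                "copy_number": entry.rounded,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PairClassTrack:
    """Per-position coverage split into proper vs broken read pairs."""

    replicon: str
    proper_cov: np.ndarray
    broken_cov: np.ndarray

    @property
    def length(self) -> int:
        return self.proper_cov.size


def _is_fr(read) -> bool:
    """Expected FR orientation: mates on opposite strands, leftmost forward."""
    if read.is_reverse == read.mate_is_reverse:
        return False
    if not read.is_reverse:
        return read.reference_start <= read.next_reference_start
    return read.next_reference_start <= read.reference_start


def estimate_insert_bounds(sam_path, n_sd: float = 4.0) -> tuple[float, float]:
    """Proper-insert bounds as mean +/- n_sd * SD of same-replicon FR pairs."""
    tlens = []
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for read in sam:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_paired
                or not read.is_read1
                or read.reference_id != read.next_reference_id
                or read.template_length == 0
                or not _is_fr(read)
            ):
                continue
            tlens.append(abs(read.template_length))
    if not tlens:
        raise ValueError("no same-replicon FR pairs to estimate insert size from")
    arr = np.asarray(tlens, dtype=float)
    mean, sd = float(arr.mean()), float(arr.std())
    return max(0.0, mean - n_sd * sd), mean + n_sd * sd


def pair_class_coverage(
    sam_path,
    target_replicon: str,
    insert_bounds: tuple[float, float] | None = None,
) -> PairClassTrack:
    """Classify mapped pairs as proper or broken and accumulate coverage.

    A read contributes its aligned span to the proper track when its mate
    maps to the same replicon in FR orientation with |insert| inside the
    bounds (default: estimated mean +/- 4 SD); otherwise - wrong
    orientation, cross-replicon, unmapped mate, or aberrant insert - to the
    broken track.  Input must be coordinate-sorted; unsorted input raises.
    """
    if insert_bounds is None:
        insert_bounds = estimate_insert_bounds(sam_path)
    lo, hi = insert_bounds
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        if target_replicon not in sam.references:
            raise ValueError(f"replicon {target_replicon!r} not in SAM header")
        length = sam.get_reference_length(target_replicon)
        proper = np.zeros(length, dtype=np.int64)
        broken = np.zeros(length, dtype=np.int64)
        last: dict[int, int] = {}
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            prev = last.get(read.reference_id, -1)
            if read.reference_start < prev:
                raise ValueError("SAM input is not coordinate-sorted")
            last[read.reference_id] = read.reference_start
            if not read.is_paired or read.reference_name != target_replicon:
                continue
            if (
                not read.mate_is_unmapped
                and read.reference_id == read.next_reference_id
                and _is_fr(read)
                and read.template_length != 0
                and lo <= abs(read.template_length) <= hi
            ):
                track = proper
            else:
                track = broken
            track[read.reference_start : read.reference_end] += 1
    return PairClassTrack(target_replicon, proper, broken)
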