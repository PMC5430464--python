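"""Assign long reads to whole-shufflon arrangements and quantify abundance.

A read is informative for the whole-shufflon structure only if it spans
from the pilV-adjacent anchor through the rci-adjacent anchor.  Assignment
is a two-stage alignment: (1) locate both anchors in the read (either
strand) by semi-global alignment of anchor probes; (2) score the read's
inter-anchor core against every candidate arrangement core with a banded
edit distance, and assign to the best candidate when it clears the
identity threshold and the ambiguity margin over the runner-up.

``reconstruct_from_markers`` is a deliberately independent second route
(order the anchor/segment-body marker hits along the read and read off the
signed permutation directly); the two modes must concur on error-free
reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._align import banded_distance, encode, identity, locate
from .enumeration import CandidateSet, build_candidates
from .locus import Arrangement, ShufflonLocus, revcomp

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
NON_SPANNING = "non_spanning"
NO_MATCH = "no_match"
STATUSES = (ASSIGNED, AMBIGUOUS, NON_SPANNING, NO_MATCH)


@dataclass(frozen=True)
class AssignParams:
    """Alignment thresholds for long-read arrangement assignment.

    There is no standard parameterisation for this kind of homology
    search; these defaults are chosen for indel-heavy long reads and are
    all exposed as parameters.  ``min_identity`` applies to the
    inter-anchor core (1 - edits/length); the anchor probes must each be
    found at ``min_anchor_identity``; the best candidate must beat the
    runner-up by ``margin`` (fraction of the best score) to count as
    assigned rather than ambiguous.
    """

    min_identity: float = 0.80
    min_anchor_identity: float = 0.80
    margin: float = 0.02
    anchor_probe_len: int = 150
    # band covers net indel drift (~5% of length) with an order of magnitude
    # to spare at default error rates; widened automatically for length gaps
    band_frac: float = 0.15
    min_band: int = 32


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str
    arrangement: str | None = None  # canonical label, present iff assigned
    score: float | None = None
    runner_up_score: float | None = None


@dataclass
class AbundanceTable:
    """Per-arrangement spanning-read counts and ratios.

    ``table`` columns: arrangement_label, count, ratio (over assigned
    reads), sorted by ratio descending then label.  ``totals`` carries the
    per-status read counts; ``empty`` flags a run with zero assigned reads.
    """

    table: pd.DataFrame
    totals: dict[str, int]
    assignments: list[ReadAssignment]

    @property
    def empty(self) -> bool:
        return self.totals[ASSIGNED] == 0

    @property
    def spanning_reads(self) -> int:
        return self.totals[ASSIGNED] + self.totals[AMBIGUOUS]

    def ratios(self) -> pd.Series:
        return self.table.set_index("arrangement_label")["ratio"]


def _read_id_seq(read) -> tuple[str, str]:
    if hasattr(read, "seq"):
        return read.id, str(read.seq).upper()
    if isinstance(read, tuple):
        return read[0], read[1].upper()
    return "read", str(read).upper()


def _locate_anchors(seq: str, pilv_probe: str, rci_probe: str, params: AssignParams):
    """Locate both anchor probes on one strand; returns (hits, span, total_id)."""
    enc = encode(seq)
    p_start, p_end, p_dist = locate(pilv_probe, enc)
    r_start, r_end, r_dist = locate(rci_probe, enc)
    p_id = identity(len(pilv_probe), p_end - p_start, p_dist)
    r_id = identity(len(rci_probe), r_end - r_start, r_dist)
    p_ok = p_id >= params.min_anchor_identity
    r_ok = r_id >= params.min_anchor_identity
    ordered = p_end <= r_start
    hits = int(p_ok) + int(r_ok)
    return hits, p_ok and r_ok and ordered, (p_end, r_start), p_id + r_id


def assign_read(
    read,
    candidates: CandidateSet,
    params: AssignParams | None = None,
) -> ReadAssignment:
    """Assign one read (str, (id, seq) or SeqRecord) to an arrangement.

    Strand-symmetric: the read and its reverse complement give the same
    assignment.  Status is ``non_spanning`` when the read does not contain
    both anchors in order, ``no_match`` when no anchor is found at all or
    no candidate clears the identity threshold, ``ambiguous`` when the
    margin test fails.
    """
    params = params or AssignParams()
    read_id, seq = _read_id_seq(read)
    if not seq:
        raise ValueError(f"read {read_id}: empty sequence")
    locus = candidates.locus
    probe_len = min(params.anchor_probe_len, len(locus.pilv_anchor), len(locus.rci_anchor))
    pilv_probe = locus.pilv_anchor[-probe_len:]
    rci_probe = locus.rci_anchor[:probe_len]

    rc = revcomp(seq)
    fwd = _locate_anchors(seq, pilv_probe, rci_probe, params)
    rev = _locate_anchors(rc, pilv_probe, rci_probe, params)
    key = lambda r: (r[0], r[1], r[3])  # noqa: E731 - (anchor hits, spanning, identity)
    (hits, spanning, (p_end, r_start), _), oriented = (
        (fwd, seq) if key(fwd) >= key(rev) else (rev, rc)
    )
    if not spanning:
        return ReadAssignment(read_id, NO_MATCH if hits == 0 else NON_SPANNING)

    core = encode(oriented[p_end:r_start])
    by_label = candidates.by_label()
    scored: list[tuple[float, str]] = []
    for label in sorted(by_label):
        cand_core = candidates.core(by_label[label])
        band = max(params.min_band, int(params.band_frac * max(len(cand_core), core.size)))
        d = banded_distance(core, encode(cand_core), band)
        scored.append((identity(core.size, len(cand_core), d), label))
    scored.sort(key=lambda t: (-t[0], t[1]))
    best_score, best_label = scored[0]
    runner = scored[1][0] if len(scored) > 1 else None
    if best_score < params.min_identity:
        return ReadAssignment(read_id, NO_MATCH, score=best_score, runner_up_score=runner)
    if runner is not None and (best_score - runner) < params.margin * best_score:
        return ReadAssignment(read_id, AMBIGUOUS, score=best_score, runner_up_score=runner)
    return ReadAssignment(read_id, ASSIGNED, best_label, best_score, runner)


def quantify_structures(
    reads,
    locus: ShufflonLocus,
    params: AssignParams | None = None,
) -> AbundanceTable:
    """Run assignment over all reads and tabulate per-arrangement ratios.

    Ambiguous reads are excluded from the ratio denominator (the analysis
    counts only confidently detected spanning reads) but reported in the
    totals.  The table is sorted by ratio descending with a deterministic
    label tie-break.
    """
    params = params or AssignParams()
    candidates = build_candidates(locus)
    assignments = [assign_read(r, candidates, params) for r in reads]
    totals = {s: 0 for s in STATUSES}
    counts: Counter[str] = Counter()
    for a in assignments:
        totals[a.status] += 1
        if a.status == ASSIGNED:
            counts[a.arrangement] += 1
    assigned = totals[ASSIGNED]
    rows = [
        {
            "arrangement_label": lab,
            "count": c,
            "ratio": c / assigned if assigned else float("nan"),
        }
        for lab, c in counts.items()
    ]
    table = pd.DataFrame(rows, columns=["arrangement_label", "count", "ratio"])
    if len(table):
        table = table.sort_values(
            ["ratio", "arrangement_label"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return AbundanceTable(table=table, totals=totals, assignments=assignments)


# ---------------------------------------------------------------------------
# Independent marker-based reconstruction (oracle for assign_read)


def _find_exact(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i >= 0:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def reconstruct_from_markers(
    read,
    locus: ShufflonLocus,
    params: AssignParams | None = None,
) -> Arrangement | None:
    """Read the arrangement directly off marker positions in the read.

    Locates the two anchors and each segment body (both orientations)
    independently, orders the hits by read position, and returns the
    implied (order, orientations) - no candidate sequences involved, which
    makes this an oracle for ``assign_read``.  Exact string search is tried
    first (sufficient for error-free reads); alignment-based location is
    the fallback.  Returns None when markers are missing, duplicated or
    out of order.
    """
    params = params or AssignParams()
    _, seq = _read_id_seq(read)
    if not seq:
        return None
    probe_len = min(params.anchor_probe_len, len(locus.pilv_anchor), len(locus.rci_anchor))
    pilv_probe = locus.pilv_anchor[-probe_len:]
    rci_probe = locus.rci_anchor[:probe_len]

    for strand_seq in (seq, revcomp(seq)):
        arr = _reconstruct_one_strand(strand_seq, locus, pilv_probe, rci_probe, params)
        if arr is not None:
            return arr
    return None


def _reconstruct_one_strand(seq, locus, pilv_probe, rci_probe, params):
    p_hits = _find_exact(seq, pilv_probe)
    r_hits = _find_exact(seq, rci_probe)
    exact = len(p_hits) == 1 and len(r_hits) == 1
    if exact:
        p_end = p_hits[0] + len(pilv_probe)
        r_start = r_hits[0]
    else:
        enc = encode(seq)
        ps, pe, pd_ = locate(pilv_probe, enc)
        rs, re_, rd = locate(rci_probe, enc)
        if (
            identity(len(pilv_probe), pe - ps, pd_) < params.min_anchor_identity
            or identity(len(rci_probe), re_ - rs, rd) < params.min_anchor_identity
        ):
            return None
        p_end, r_start = pe, rs
    if p_end >= r_start:
        return None
    between = seq[p_end:r_start]

    found: list[tuple[int, int, int, str]] = []  # (start, end, seg index, orientation)
    for i, seg in enumerate(locus.segments, start=1):
        hit = None
        for ori, marker in (("+", seg.body), ("-", revcomp(seg.body))):
            if exact:
                pos = _find_exact(between, marker)
                if len(pos) == 1:
                    cand = (pos[0], pos[0] + len(marker), i, ori, 0.0)
                elif len(pos) > 1:
                    return None
                else:
                    cand = None
            else:
                s, e, d = locate(marker, encode(between))
                ident = identity(len(marker), e - s, d)
                cand = (s, e, i, ori, 1 - ident) if ident >= params.min_identity else None
            if cand is not None and (hit is None or cand[4] < hit[4]):
                hit = cand
        if hit is None:
            return None
        found.append(hit[:4])
    found.sort()
    for (s1, e1, _, _), (s2, _, _, _) in zip(found, found[1:]):
        if s2 < e1:  # overlapping marker hits: not a clean arrangement
            return None
    order = tuple(h[2] for h in found)
    orients = tuple(h[3] for h in found)
    try:
        return Arrangement(order, orients)
    except ValueError:
        return None


def marginal_variant_counts(abundance: AbundanceTable, locus: ShufflonLocus) -> pd.Series:
    """Collapse arrangement counts to pilV-variant counts.

    The variant of an arrangement is the ORF end of its pilV-proximal
    segment facing the pilV 3' end ('+' -> orf_left, '-' -> orf_right);
    one-ORF segments in the non-coding orientation contribute nothing.
    """
    cands = build_candidates(locus)
    by_label = cands.by_label()
    counts: Counter[str] = Counter()
    for _, row in abundance.table.iterrows():
        arr = by_label[row["arrangement_label"]]
        seg = locus.segments[arr.order[0] - 1]
        variant = seg.orf_left if arr.orientations[0] == "+" else seg.orf_right
        if variant is not None:
            counts[variant] += int(row["count"])
    return pd.Series(counts).sort_index()
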