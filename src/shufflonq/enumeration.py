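"""Enumeration of the whole-shufflon arrangement space.

For a shufflon of n two-ORF segments the number of distinct structures is
``2^n * n!`` (each segment can sit at any position in either orientation).
This module enumerates that space directly as signed permutations, builds
one candidate locus sequence per arrangement, and provides an independent
inversion-closure oracle: breadth-first exploration of the states reachable
from the reference by inverting the DNA strictly between any two repeat
sites, the operation catalysed by the Rci recombinase.

One-ORF segments are still two-orientation elements at the sequence level;
the closed-form count holds only for two-ORF loci, so mixed loci
should be handled by enumerating and deduplicating by candidate sequence
(`distinct_sequence_count`) rather than via `count_arrangements`.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache

from .locus import (
    Arrangement,
    ArrangementSpace,
    LocusError,
    SegmentDef,
    ShufflonLocus,
    junction_consensus,
    revcomp,
)

#: BFS guard for inversion-closure searches.
DEFAULT_MAX_STATES = 500_000


def count_arrangements(n: int) -> int:
    """Number of whole-shufflon structures for n two-ORF segments: 2^n * n!."""
    if n < 0:
        raise ValueError("segment count must be non-negative")
    return (2**n) * math.factorial(n)


def enumerate_arrangements(locus: ShufflonLocus | int) -> ArrangementSpace:
    """All (order, orientation) pairs, lexicographic by order then orientation.

    Accepts a locus or a bare segment count.
    """
    n = locus if isinstance(locus, int) else locus.n
    arrangements = tuple(
        Arrangement(order, orients)
        for order in itertools.permutations(range(1, n + 1))
        for orients in itertools.product("+-", repeat=n)
    )
    return ArrangementSpace(arrangements)


def count_pilv_variants(segments: tuple[SegmentDef, ...] | list[SegmentDef]) -> int:
    """Number of pilV 3'-end variants a shufflon can encode.

    Each two-ORF segment contributes both of its partial ORFs, a one-ORF
    segment contributes one: 2*(#two-ORF) + (#one-ORF).  The classic IncI1
    R64 shufflon (A, B, C two-ORF plus D one-ORF) gives seven.
    """
    return sum(2 if seg.two_orf else 1 for seg in segments)


# ---------------------------------------------------------------------------
# Inversion state space
#
# A full state is the alternating chain of signed elements
#   (R,0,s) (S,i1,s) (R,j1,s) ... (S,in,s) (R,n,s)
# where R/S index junction repeats and segment bodies of the *reference*
# locus and s is +1/-1.  Inversion between repeat sites at chain positions
# 2i and 2j (i<j) reverses the slice strictly between them and flips signs;
# the outermost sites (pilV-proximal R0 and rci-proximal Rn) can therefore
# never move, which is what pins the anchors.

_R, _S = 0, 1


def _reference_state(n: int) -> tuple:
    items: list[tuple[int, int, int]] = [(_R, 0, 1)]
    for i in range(1, n + 1):
        items.append((_S, i, 1))
        items.append((_R, i, 1))
    return tuple(items)


def _invert(state: tuple, i: int, j: int) -> tuple:
    """Invert between repeat sites i < j (chain positions 2i, 2j)."""
    a, b = 2 * i, 2 * j
    mid = tuple((kind, idx, -sign) for kind, idx, sign in reversed(state[a + 1 : b]))
    return state[: a + 1] + mid + state[b:]


def _project(state: tuple) -> Arrangement:
    segs = [item for item in state if item[0] == _S]
    return Arrangement(
        tuple(idx for _, idx, _ in segs),
        tuple("+" if sign > 0 else "-" for _, _, sign in segs),
    )


def inversion_closure(
    locus: ShufflonLocus | int, max_states: int = DEFAULT_MAX_STATES
) -> set[Arrangement]:
    """Arrangements reachable from the reference by repeated inversions.

    BFS over (order, orientation) states under the signed-interval-reversal
    move; for any locus this closure equals the full signed-permutation
    space, independently corroborating ``enumerate_arrangements``.
    """
    n = locus if isinstance(locus, int) else locus.n
    start = Arrangement(tuple(range(1, n + 1)), ("+",) * n)
    seen = {start}
    queue: deque[Arrangement] = deque([start])
    # inversion between repeat sites i < j flips segment slots i..j-1
    moves = [(i, j) for i in range(n) for j in range(i + 1, n + 1)]
    while queue:
        arr = queue.popleft()
        for i, j in moves:
            order = list(arr.order)
            ori = list(arr.orientations)
            order[i:j] = order[i:j][::-1]
            ori[i:j] = ["-" if o == "+" else "+" for o in ori[i:j][::-1]]
            nxt = Arrangement(tuple(order), tuple(ori))
            if nxt not in seen:
                if len(seen) >= max_states:
                    raise RuntimeError(f"inversion closure exceeded max_states={max_states}")
                seen.add(nxt)
                queue.append(nxt)
    return seen


# ---------------------------------------------------------------------------
# Candidate sequences


@dataclass(frozen=True)
class CandidateSet:
    """One candidate locus sequence per arrangement, pilV anchor to rci anchor.

    Junction repeats in each candidate are those propagated by the
    inversion model (BFS from the reference), so the reference candidate
    reproduces the annotated locus byte-for-byte and every other candidate
    carries a physically consistent repeat layout.
    """

    locus: ShufflonLocus
    space: ArrangementSpace
    sequences: dict[Arrangement, str] = field(repr=False)
    labels: dict[Arrangement, str] = field(repr=False)

    @property
    def anchor_spans(self) -> dict[Arrangement, tuple[tuple[int, int], tuple[int, int]]]:
        p = len(self.locus.pilv_anchor)
        out = {}
        for arr, seq in self.sequences.items():
            out[arr] = ((0, p), (len(seq) - len(self.locus.rci_anchor), len(seq)))
        return out

    def core(self, arrangement: Arrangement) -> str:
        """Candidate sequence with the anchors stripped (R0 ... Rn)."""
        seq = self.sequences[arrangement]
        return seq[len(self.locus.pilv_anchor) : len(seq) - len(self.locus.rci_anchor)]

    def by_label(self) -> dict[str, Arrangement]:
        return {lab: arr for arr, lab in self.labels.items()}


def _state_sequence(locus: ShufflonLocus, state: tuple) -> str:
    parts = [locus.pilv_anchor]
    for kind, idx, sign in state:
        seq = locus.junctions[idx] if kind == _R else locus.segments[idx - 1].body
        parts.append(seq if sign > 0 else revcomp(seq))
    parts.append(locus.rci_anchor)
    return "".join(parts)


def _consensus_state(locus: ShufflonLocus, arrangement: Arrangement) -> str:
    """Fallback construction: consensus repeat at every junction."""
    cons = junction_consensus(locus)
    parts = [locus.pilv_anchor, cons]
    for idx, ori in zip(arrangement.order, arrangement.orientations):
        body = locus.segments[idx - 1].body
        parts.append(body if ori == "+" else revcomp(body))
        parts.append(cons)
    parts.append(locus.rci_anchor)
    return "".join(parts)


@lru_cache(maxsize=8)
def build_candidates(locus: ShufflonLocus, max_states: int = DEFAULT_MAX_STATES) -> CandidateSet:
    """Construct all candidate whole-shufflon sequences for a locus.

    A full-state BFS (tracking repeat identities and signs) assigns each
    arrangement the repeat layout of the first state that reaches it; the
    search stops as soon as every arrangement has a layout.  Arrangements
    the bounded search fails to reach (not expected for the 2^n n! space)
    fall back to consensus junction repeats.
    """
    space = enumerate_arrangements(locus)
    n = locus.n
    target = len(space)
    start = _reference_state(n)
    layouts: dict[Arrangement, tuple] = {_project(start): start}
    seen = {start}
    queue: deque[tuple] = deque([start])
    moves = [(i, j) for i in range(n + 1) for j in range(i + 1, n + 1)]
    while queue and len(layouts) < target:
        state = queue.popleft()
        for i, j in moves:
            nxt = _invert(state, i, j)
            if nxt in seen:
                continue
            if len(seen) >= max_states:
                queue.clear()
                break
            seen.add(nxt)
            queue.append(nxt)
            layouts.setdefault(_project(nxt), nxt)

    sequences: dict[Arrangement, str] = {}
    labels: dict[Arrangement, str] = {}
    for arr in space:
        state = layouts.get(arr)
        sequences[arr] = (
            _state_sequence(locus, state) if state is not None else _consensus_state(locus, arr)
        )
        labels[arr] = locus.label(arr)
    return CandidateSet(locus=locus, space=space, sequences=sequences, labels=labels)


def build_candidate_sequence(locus: ShufflonLocus, arrangement: Arrangement) -> str:
    """Candidate sequence (anchors included) for one arrangement."""
    cands = build_candidates(locus)
    try:
        return cands.sequences[arrangement]
    except KeyError:
        raise LocusError(f"arrangement {arrangement} is not in the locus space") from None


def distinct_sequence_count(locus: ShufflonLocus) -> int:
    """Number of sequence-distinct arrangements (dedupe path for mixed loci)."""
    return len(set(build_candidates(locus).sequences.values()))
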