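"""Inverted-repeat conservation analysis.

The recombination sites bounding shufflon segments are short imperfect
inverted repeats (a 20-bp consensus, conserved over a 23-bp window at the
segment ends, with 1-6 SNVs between sites).  This module computes the
degenerate consensus, identity / Hamming matrices, a per-position identity
profile, a position frequency matrix for logo tools, and the minimum
spanning network of SNVs between sites.

Repeats are fixed-length sites: all comparisons are gap-free, and repeats
are compared in a common orientation (segment left-end windows are
reverse-complemented onto the right-end strand before comparison).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .locus import ShufflonLocus, revcomp

_BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class RepeatSet:
    """Labelled equal-length repeat windows (one per segment end)."""

    labels: tuple[str, ...]
    sequences: tuple[str, ...]
    window_len: int = 23
    consensus_len: int = 20

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("repeat labels must be unique")


def extract_repeats(locus: ShufflonLocus, window_len: int = 23) -> RepeatSet:
    """Segment-end repeat windows of a locus, two per segment.

    Each window is the flanking repeat extended ``window_len - len(repeat)``
    nt into the segment body; left-end windows are reverse-complemented so
    that every window reads extension-then-repeat on the right-end strand.
    """
    labels: list[str] = []
    seqs: list[str] = []
    for i, seg in enumerate(locus.segments):
        ext_l = max(0, window_len - len(seg.left_repeat))
        ext_r = max(0, window_len - len(seg.right_repeat))
        left = revcomp(seg.left_repeat + seg.body[:ext_l])
        right = seg.body[len(seg.body) - ext_r :] + seg.right_repeat
        labels.extend((f"{seg.name}_left", f"{seg.name}_right"))
        seqs.extend((left, right))
    rep_len = len(locus.junctions[0])
    return RepeatSet(tuple(labels), tuple(seqs), window_len=window_len, consensus_len=rep_len)


def _matrix(repeats) -> np.ndarray:
    seqs = [s.upper() for s in repeats]
    if not seqs:
        raise ValueError("empty repeat set")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("repeats must be equal length for gap-free comparison")
    return np.array([list(s) for s in seqs])


def degenerate_consensus(repeats, ambiguity_threshold: float = 1.0) -> str:
    """Per-position consensus with N wherever conservation is below threshold.

    With the strict default (1.0) a position is emitted as a base only
    under unanimity, so N marks exactly the positions with any
    disagreement - the convention behind a consensus such as
    5'-GTGCCAATCCGGTNNGTGGA-3'.
    """
    if not 0.5 < ambiguity_threshold <= 1.0:
        raise ValueError("ambiguity_threshold must be in (0.5, 1]")
    m = _matrix(repeats)
    out = []
    for col in m.T:
        vals, counts = np.unique(col, return_counts=True)
        k = int(np.argmax(counts))
        out.append(vals[k] if counts[k] / len(col) >= ambiguity_threshold else "N")
    return "".join(out)


def pairwise_identity(repeats) -> np.ndarray:
    """Symmetric matrix of % identity (matches/length * 100), diagonal 100."""
    m = _matrix(repeats)
    n, length = m.shape
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.count_nonzero(m[i] == m[j]) / length * 100.0
    return out


def hamming_matrix(repeats, window: int | None = 23) -> np.ndarray:
    """Integer Hamming distances over the first ``window`` positions."""
    m = _matrix(repeats)
    if window is not None:
        if window > m.shape[1]:
            raise ValueError(f"window {window} exceeds repeat length {m.shape[1]}")
        m = m[:, :window]
    n = m.shape[0]
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = int(np.count_nonzero(m[i] != m[j]))
            out[i, j] = out[j, i] = d
    return out


def position_frequency_matrix(repeats) -> pd.DataFrame:
    """Base counts per position (rows A,C,G,T), for sequence-logo tools."""
    m = _matrix(repeats)
    if not set(m.ravel()) <= set(_BASE_ORDER):
        raise ValueError("position frequency matrix requires ACGT-only repeats")
    data = {b: (m == b).sum(axis=0) for b in _BASE_ORDER}
    pfm = pd.DataFrame(data).T
    pfm.index.name = "base"
    return pfm


def identity_profile(sequences, reference: str, window: int = 1) -> np.ndarray:
    """Fraction of sequences matching the reference base, per position.

    ``window`` > 1 returns a centred sliding mean ('valid' positions only).
    Sequences must be anchored to reference coordinates (equal lengths).
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty input")
    ref = np.array(list(reference.upper()))
    m = _matrix(seqs)
    if m.shape[1] != ref.size:
        raise ValueError("sequences are not anchored to the reference length")
    prof = (m == ref).mean(axis=0)
    if window > 1:
        prof = np.convolve(prof, np.ones(window) / window, mode="valid")
    return prof


@dataclass(frozen=True)
class SnvNetwork:
    """Minimum spanning tree plus co-minimal alternative edges (epsilon-0 MSN)."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]
    tree_weight: int
    connected: bool = True

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["from", "to", "snvs"])


def min_spanning_network(dist_matrix: np.ndarray, labels=None) -> SnvNetwork:
    """Minimum spanning network over a symmetric SNV distance matrix.

    A Kruskal minimum spanning tree is augmented with every non-tree edge
    whose weight ties the maximum edge weight on the tree path between its
    endpoints (so all co-minimal alternatives are retained, as haplotype
    MSN programs draw them).  Deterministic under label-sorted tie-breaks.
    """
    d = np.asarray(dist_matrix)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    labels = tuple(labels) if labels is not None else tuple(f"R{i + 1}" for i in range(n))
    if len(labels) != n:
        raise ValueError("label count must match matrix size")
    g = nx.Graph()
    g.add_nodes_from(labels)
    order = sorted(range(n), key=lambda i: labels[i])
    for a, b in itertools.combinations(order, 2):
        u, v = sorted((labels[a], labels[b]))
        g.add_edge(u, v, weight=int(d[a, b]))
    tree = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = {tuple(sorted((u, v))): w["weight"] for u, v, w in tree.edges(data=True)}
    for u, v, w in g.edges(data="weight"):
        key = tuple(sorted((u, v)))
        if key in edges:
            continue
        path = nx.shortest_path(tree, u, v)
        path_max = max(tree[a][b]["weight"] for a, b in zip(path, path[1:]))
        if w == path_max:
            edges[key] = w
    out = tuple(sorted((u, v, w) for (u, v), w in edges.items()))
    tree_weight = int(sum(w["weight"] for _, _, w in tree.edges(data=True)))
    return SnvNetwork(nodes=labels, edges=out, tree_weight=tree_weight)


def conserved_fraction(conserved_bp: int, total_bp: int) -> float:
    """Conserved share of a sequence as a percentage, rounded to 2 decimals."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    return round(100.0 * conserved_bp / total_bp, 2)
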