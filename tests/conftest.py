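"""Shared fixtures: small hand-built loci and seeded synthetic data.

Session-scoped fixtures are used for anything that runs alignment kernels
so the numba JIT cost and read simulation are paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from shufflonq import SegmentDef, ShufflonLocus, SimConfig, make_locus, sample_population

PRIME = "′"  # ′
DASH = "–"  # – (en dash, used in arrangement labels)

CONSENSUS = "GTGCCAATCCGGTNNGTGGA"


def _fill_n(consensus: str, rng: np.random.Generator) -> str:
    return "".join(b if b != "N" else "ACGT"[rng.integers(4)] for b in consensus)


def toy_locus(n: int = 1, seed: int = 0, segment_len: int = 60, anchor_len: int = 60,
              two_orf: tuple[bool, ...] | None = None) -> ShufflonLocus:
    """A minimal hand-built locus (short anchors/bodies, fast alignments)."""
    rng = np.random.default_rng(seed)

    def dna(k):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, k))

    pilv, rci = dna(anchor_len), dna(anchor_len)
    junctions = tuple(_fill_n(CONSENSUS, rng) for _ in range(n + 1))
    two_orf = two_orf or (True,) * n
    segments = []
    names = "ABCDEFG"
    for i in range(n):
        name = names[i]
        ol, orr = (name, name + PRIME) if two_orf[i] else (name + PRIME, None)
        segments.append(
            SegmentDef(
                name=name,
                body=dna(segment_len),
                left_repeat=junctions[i],
                right_repeat=junctions[i + 1],
                orf_left=ol,
                orf_right=orr,
            )
        )
    core = junctions[0]
    for i, seg in enumerate(segments):
        core += seg.body + junctions[i + 1]
    locus_seq = pilv + core + rci
    plasmid = dna(700) + locus_seq + dna(700)
    return ShufflonLocus(
        plasmid_id="toy",
        plasmid_seq=plasmid,
        pilv_anchor=pilv,
        rci_anchor=rci,
        segments=tuple(segments),
        junctions=junctions,
        locus_start=700,
        circular=True,
    )


@pytest.fixture(scope="session")
def locus1():
    return toy_locus(n=1, seed=11)


@pytest.fixture(scope="session")
def locus2():
    return toy_locus(n=2, seed=12)


@pytest.fixture(scope="session")
def locus3():
    return toy_locus(n=3, seed=13, segment_len=300)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=20, n_segments=3)


@pytest.fixture(scope="session")
def sim_locus(sim_config):
    return make_locus(sim_config)


@pytest.fixture(scope="session")
def sim_population(sim_locus):
    return sample_population(sim_locus, seed=20)
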