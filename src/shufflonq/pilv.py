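"""Type the pilV 3'-end variant from junction-containing reads.

Shufflon rearrangement fuses one partial ORF end to the constant 3' region
of pilV.  A read is informative for the variant if it contains the fusion
junction: part of the main pilV region, the pilV-proximal inverted repeat,
and part of the adjacent segment end.  Because the outermost repeat site
never moves under inversion, the junction probe for variant v is::

    pilV_3'[-k:] + R0 + variant_prefix[:k]

where the variant prefix is the segment body 5' end (orf_left) or the
reverse-complemented body 5' end (orf_right).  Typing works on both
platforms; only the identity threshold differs (substitution-only short
reads vs indel-heavy long reads).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._align import encode, identity, locate
from .locus import ShufflonLocus, revcomp

LONG = "long"
SHORT = "short"

#: per-platform junction identity defaults
_PLATFORM_IDENTITY = {SHORT: 0.90, LONG: 0.80}


@dataclass(frozen=True)
class TypeParams:
    """Junction-typing thresholds.

    ``pilv_flank``/``segment_flank`` are the minimum matched lengths either
    side of the repeat (20 nt each: far beyond the 4^-20 chance-match
    scale).  Long reads (above ``long_read_len``) are first narrowed to the
    junction neighbourhood by locating the pilV anchor tail, keeping the
    probe scan cheap on multi-kb reads.
    """

    pilv_flank: int = 20
    segment_flank: int = 20
    min_identity: float = 0.90
    anchor_probe_len: int = 100
    long_read_len: int = 600


@dataclass
class VariantTable:
    """Per-variant informative-read counts and ratios for one platform."""

    table: pd.DataFrame  # columns: variant, count, ratio
    total_informative: int
    platform: str

    @property
    def empty(self) -> bool:
        return self.total_informative == 0

    def ratios(self) -> pd.Series:
        return self.table.set_index("variant")["ratio"]


def junction_probes(locus: ShufflonLocus, params: TypeParams | None = None) -> dict[str, str]:
    """Expected junction sequence per pilV variant label."""
    params = params or TypeParams()
    pilv_side = locus.pilv_anchor[-params.pilv_flank :]
    r0 = locus.junctions[0]
    probes: dict[str, str] = {}
    for seg in locus.segments:
        if seg.orf_left is not None:
            probes[seg.orf_left] = pilv_side + r0 + seg.body[: params.segment_flank]
        if seg.orf_right is not None:
            probes[seg.orf_right] = pilv_side + r0 + revcomp(seg.body)[: params.segment_flank]
    return probes


def _read_seq(read) -> str:
    if hasattr(read, "seq"):
        return str(read.seq).upper()
    if isinstance(read, tuple):
        return read[1].upper()
    return str(read).upper()


def type_read(read, locus: ShufflonLocus, params: TypeParams | None = None) -> str | None:
    """Return the pilV variant fused in the read's junction, or None.

    Strand-symmetric; None when the junction is absent, no probe clears
    the identity threshold, or the best two probes tie.
    """
    params = params or TypeParams()
    seq = _read_seq(read)
    if not seq:
        return None
    probes = junction_probes(locus, params)
    best: tuple[float, str] | None = None
    second = -1.0
    for strand_seq in (seq, revcomp(seq)):
        window = strand_seq
        if len(strand_seq) > params.long_read_len:
            window = _junction_window(strand_seq, locus, params)
            if window is None:
                continue
        enc = encode(window)
        for variant in sorted(probes):
            probe = probes[variant]
            _, e, d = locate(probe, enc)
            ident = 1.0 - d / len(probe)
            if best is None or ident > best[0]:
                if best is not None and best[1] != variant:
                    second = best[0]
                best = (ident, variant)
            elif best[1] != variant and ident > second:
                second = ident
    if best is None or best[0] < params.min_identity or best[0] <= second:
        return None
    return best[1]


def _junction_window(seq: str, locus: ShufflonLocus, params: TypeParams) -> str | None:
    """Narrow a long read to the neighbourhood of the pilV 3' junction."""
    probe_len = min(params.anchor_probe_len, len(locus.pilv_anchor))
    probe = locus.pilv_anchor[-probe_len:]
    _, end, d = locate(probe, encode(seq))
    if identity(probe_len, probe_len, d) < 0.70:
        return None
    pad = len(locus.junctions[0]) + params.segment_flank + 30
    lo = max(0, end - params.pilv_flank - 15)
    return seq[lo : end + pad]


def variant_ratios(
    reads,
    locus: ShufflonLocus,
    platform: str = LONG,
    params: TypeParams | None = None,
    paired: bool = False,
) -> VariantTable:
    """Count informative reads per pilV variant and normalise.

    With ``paired=True`` the items are (mate1, mate2) tuples; mates are
    typed independently and a pair contributes at most once (typed mates
    must agree, otherwise the pair is uninformative, avoiding double
    counting one junction).  Rows cover every ORF label of the locus, zero
    counts included; ratios are over informative reads.
    """
    if platform not in _PLATFORM_IDENTITY:
        raise ValueError(f"unknown platform {platform!r}")
    if params is None:
        params = TypeParams(min_identity=_PLATFORM_IDENTITY[platform])
    counts: Counter[str] = Counter()
    total = 0
    for item in reads:
        if paired:
            calls = {type_read(m, locus, params) for m in item}
            calls.discard(None)
            call = calls.pop() if len(calls) == 1 else None
        else:
            call = type_read(item, locus, params)
        if call is not None:
            counts[call] += 1
            total += 1
    labels = sorted(locus.orf_labels())
    rows = [
        {
            "variant": lab,
            "count": counts.get(lab, 0),
            "ratio": counts.get(lab, 0) / total if total else float("nan"),
        }
        for lab in labels
    ]
    return VariantTable(
        table=pd.DataFrame(rows, columns=["variant", "count", "ratio"]),
        total_informative=total,
        platform=platform,
    )


@dataclass(frozen=True)
class PlatformComparison:
    """Paired per-variant ratios from two platforms and their R^2."""

    variants: tuple[str, ...]
    ratios_a: tuple[float, ...]
    ratios_b: tuple[float, ...]
    r_squared: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant": self.variants, "ratio_a": self.ratios_a, "ratio_b": self.ratios_b}
        )


def compare_platforms(table_a: VariantTable, table_b: VariantTable) -> PlatformComparison:
    """Pair variant ratios across platforms; R^2 = squared Pearson r.

    Symmetric in its inputs.  Identical ratio vectors give exactly 1.0;
    mismatched variant label sets, fewer than two shared variants, or a
    degenerate (constant, non-identical) pairing raise ValueError.
    """
    la = set(table_a.table["variant"])
    lb = set(table_b.table["variant"])
    if la != lb:
        raise ValueError(f"variant label sets differ: {sorted(la ^ lb)}")
    if len(la) < 2:
        raise ValueError("need at least two shared variants for a correlation")
    variants = tuple(sorted(la))
    a = table_a.ratios().loc[list(variants)].to_numpy(dtype=float)
    b = table_b.ratios().loc[list(variants)].to_numpy(dtype=float)
    if np.allclose(a, b):
        r2 = 1.0
    elif np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant ratio vector: correlation undefined")
    else:
        r = stats.pearsonr(a, b).statistic
        r2 = float(r * r)
    return PlatformComparison(variants, tuple(a), tuple(b), r2)
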