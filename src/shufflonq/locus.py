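"""Domain model and I/O for a plasmid shufflon locus.

A shufflon is a site-specific DNA inversion system found on IncI-family
conjugative plasmids: 1-3 invertible segments, each bounded by short
(~20 bp) imperfect inverted repeats, sit between the 3' constant region of
the pilV adhesin gene and the rci recombinase gene.  The Rci recombinase
inverts the DNA between any two repeat sites, so a clonal plasmid
population is heterogeneous over segment orders and orientations
("arrangements"), and each arrangement fuses a different partial ORF to the
pilV 3' end.

The locus is modelled as an alternating chain::

    pilV_anchor  R0  S1  R1  S2  ...  Sn  Rn  rci_anchor

with n segment bodies and n+1 junction repeats.  Inversion between repeat
sites i < j reverse-complements everything strictly between them; the
recombining sites themselves stay in place.

Coordinates are GFF3 (1-based, inclusive) at the file boundary and 0-based
half-open internally.  Feature sequences are stored in locus orientation
(= plasmid forward strand, pilV upstream of rci); for a minus-strand
annotated segment, the ORF attributes are swapped so that ``orf_left`` /
``orf_right`` always refer to the locus-forward left and right segment
ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

DNA_STRICT = set("ACGT")
DNA_IUPAC = set("ACGTRYSWKMBDHVN")

#: default minimum anchor length: read assignment needs flanks long enough
#: to be unambiguously located in error-bearing reads.
MIN_ANCHOR_LEN = 50

MIN_REPEAT_LEN = 10

LABEL_SEP = "–"  # en dash, as in "pilV–B′–D′–rci"


class LocusError(ValueError):
    """Raised when an annotation or locus fails validation."""


def revcomp(seq: str) -> str:
    return reverse_complement(seq)


@dataclass(frozen=True)
class SegmentDef:
    """One invertible shufflon segment (repeat-free body plus its flanks).

    A two-ORF segment carries a partial pilV ORF at each end, on opposite
    strands (plus-strand ORF at the left end, minus-strand ORF at the right
    end), so either end can be fused to pilV depending on orientation.  A
    one-ORF segment (like R64 segment D) carries a single ORF.
    """

    name: str
    body: str
    left_repeat: str
    right_repeat: str
    orf_left: str | None = None
    orf_right: str | None = None

    def __post_init__(self) -> None:
        if len(self.body) < 1:
            raise LocusError(f"segment {self.name}: empty body")
        if not self.left_repeat or not self.right_repeat:
            raise LocusError(f"segment {self.name}: empty flanking repeat")
        if not set(self.body.upper()) <= DNA_STRICT:
            raise LocusError(
                f"segment {self.name}: body contains non-ACGT characters "
                "(ambiguity codes are only allowed in repeats)"
            )
        for rep in (self.left_repeat, self.right_repeat):
            if not set(rep.upper()) <= DNA_IUPAC:
                raise LocusError(f"segment {self.name}: invalid repeat characters")
        if self.orf_left is None and self.orf_right is None:
            raise LocusError(f"segment {self.name}: segment must carry at least one ORF label")

    @property
    def two_orf(self) -> bool:
        return self.orf_left is not None and self.orf_right is not None

    @property
    def single_orf(self) -> str | None:
        if self.two_orf:
            return None
        return self.orf_left if self.orf_left is not None else self.orf_right


@dataclass(frozen=True)
class Arrangement:
    """One whole-shufflon structure: segment order plus orientations.

    ``order`` is a permutation of 1..n (reference segment indices);
    ``orientations`` holds '+'/'-' per position.  The reference arrangement
    is the identity with all '+'.
    """

    order: tuple[int, ...]
    orientations: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.order)
        if sorted(self.order) != list(range(1, n + 1)):
            raise LocusError(f"order {self.order} is not a permutation of 1..{n}")
        if len(self.orientations) != n:
            raise LocusError("orientations length must equal order length")
        if not set(self.orientations) <= {"+", "-"}:
            raise LocusError("orientations must be '+' or '-'")

    @property
    def n(self) -> int:
        return len(self.order)


@dataclass(frozen=True)
class ArrangementSpace:
    arrangements: tuple[Arrangement, ...]

    @property
    def n_segments(self) -> int:
        return self.arrangements[0].n if self.arrangements else 0

    @property
    def count(self) -> int:
        return len(self.arrangements)

    def __iter__(self):
        return iter(self.arrangements)

    def __len__(self) -> int:
        return len(self.arrangements)


def arrangement_label(arrangement: Arrangement, segments: tuple[SegmentDef, ...]) -> str:
    """Canonical pilV→rci label of an arrangement, e.g. ``pilV–B′–D′–rci``.

    Each two-ORF segment contributes its two ORF labels in resulting
    orientation (a '-' segment swaps them); a one-ORF segment contributes
    its single label.  For two-ORF loci the map (order, orientations) →
    label is injective.
    """
    if len(segments) != arrangement.n:
        raise LocusError("arrangement size does not match segment count")
    parts: list[str] = ["pilV"]
    for idx, ori in zip(arrangement.order, arrangement.orientations):
        seg = segments[idx - 1]
        if seg.two_orf:
            pair = (seg.orf_left, seg.orf_right)
            if ori == "-":
                pair = (seg.orf_right, seg.orf_left)
            parts.extend(pair)  # type: ignore[arg-type]
        else:
            parts.append(seg.single_orf)  # type: ignore[arg-type]
    parts.append("rci")
    return LABEL_SEP.join(parts)


@dataclass(frozen=True)
class ShufflonLocus:
    """A validated shufflon locus embedded in a (circular) plasmid."""

    plasmid_id: str
    plasmid_seq: str
    pilv_anchor: str
    rci_anchor: str
    segments: tuple[SegmentDef, ...]
    junctions: tuple[str, ...]
    locus_start: int
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise LocusError("locus needs at least one segment")
        if len(self.junctions) != len(self.segments) + 1:
            raise LocusError("need exactly n+1 junction repeats for n segments")
        for i, seg in enumerate(self.segments):
            if seg.left_repeat != self.junctions[i] or seg.right_repeat != self.junctions[i + 1]:
                raise LocusError(f"segment {seg.name}: flanking repeats disagree with junctions")
        ref = self.locus_sequence()
        got = self.plasmid_seq[self.locus_start : self.locus_start + len(ref)]
        if got != ref:
            raise LocusError("reference locus sequence does not match the plasmid substring")

    @property
    def n(self) -> int:
        return len(self.segments)

    @property
    def plasmid_len(self) -> int:
        return len(self.plasmid_seq)

    @property
    def locus_end(self) -> int:
        return self.locus_start + len(self.locus_sequence())

    @property
    def reference_arrangement(self) -> Arrangement:
        n = self.n
        return Arrangement(tuple(range(1, n + 1)), ("+",) * n)

    def locus_sequence(self) -> str:
        """pilV anchor + alternating repeats/segment bodies + rci anchor."""
        parts = [self.pilv_anchor, self.junctions[0]]
        for i, seg in enumerate(self.segments):
            parts.append(seg.body)
            parts.append(self.junctions[i + 1])
        parts.append(self.rci_anchor)
        return "".join(parts)

    def orf_labels(self) -> tuple[str, ...]:
        labels: list[str] = []
        for seg in self.segments:
            if seg.two_orf:
                labels.extend((seg.orf_left, seg.orf_right))  # type: ignore[arg-type]
            else:
                labels.append(seg.single_orf)  # type: ignore[arg-type]
        return tuple(labels)

    def label(self, arrangement: Arrangement) -> str:
        return arrangement_label(arrangement, self.segments)


def junction_consensus(locus: ShufflonLocus) -> str:
    """Column-majority consensus of the junction repeats (ties -> first repeat).

    Only defined for equal-length repeats; falls back to the pilV-proximal
    repeat otherwise.  Used where a generic junction sequence is needed
    (e.g. pilV-junction typing probes).
    """
    reps = locus.junctions
    if len({len(r) for r in reps}) != 1:
        return reps[0]
    cols = zip(*[r.upper() for r in reps])
    out = []
    for j, col in enumerate(cols):
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        winners = [b for b, c in counts.items() if c == best]
        out.append(reps[0][j].upper() if reps[0][j].upper() in winners else winners[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# GFF3 subset I/O

_FEATURE_TYPES = ("pilv_anchor", "rci_anchor", "shufflon_segment", "inverted_repeat")


def _attr(feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def load_locus(
    fasta_path: str | Path,
    annotation_path: str | Path,
    min_anchor_len: int = MIN_ANCHOR_LEN,
    circular: bool = True,
) -> ShufflonLocus:
    """Parse a plasmid FASTA plus a GFF3-subset annotation into a locus.

    The annotation must define one ``pilv_anchor``, one ``rci_anchor`` and a
    gapless alternating run of ``inverted_repeat`` / ``shufflon_segment``
    features between them.  Segment features carry ``Name``, ``orf_left``
    and/or ``orf_right`` attributes; minus-strand segments have their ORF
    attributes swapped into locus orientation on load.
    """
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(annotation_path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    feats = [f for f in db.all_features() if f.featuretype in _FEATURE_TYPES]
    if not feats:
        raise LocusError(f"{annotation_path}: no shufflon features found")
    seqids = {f.seqid for f in feats}
    if len(seqids) != 1:
        raise LocusError(f"features span multiple sequences: {sorted(seqids)}")
    plasmid_id = seqids.pop()
    if plasmid_id not in records:
        raise LocusError(f"plasmid record {plasmid_id!r} not present in {fasta_path}")
    plasmid = records[plasmid_id]

    feats.sort(key=lambda f: (f.start, f.end))
    # GFF3 1-based inclusive -> 0-based half-open
    spans = [(f.start - 1, f.end, f) for f in feats]
    for (s1, e1, f1), (s2, e2, f2) in zip(spans, spans[1:]):
        name1 = _attr(f1, "Name") or f1.featuretype
        name2 = _attr(f2, "Name") or f2.featuretype
        if s2 < e1:
            raise LocusError(f"feature {name2} overlaps feature {name1}")
        if s2 > e1:
            raise LocusError(f"gap between features {name1} and {name2}; locus must be contiguous")

    types = [f.featuretype for _, _, f in spans]
    n_seg = types.count("shufflon_segment")
    expected = (
        ["pilv_anchor", "inverted_repeat"]
        + ["shufflon_segment", "inverted_repeat"] * n_seg
        + ["rci_anchor"]
    )
    if types != expected:
        raise LocusError(
            "features do not form pilv_anchor (repeat segment)x n repeat rci_anchor; got: "
            + ", ".join(types)
        )

    def seq_of(span):
        s, e, _ = span
        return plasmid[s:e]

    pilv = seq_of(spans[0])
    rci = seq_of(spans[-1])
    for name, anchor in (("pilv_anchor", pilv), ("rci_anchor", rci)):
        if len(anchor) < min_anchor_len:
            raise LocusError(f"{name} shorter than min_anchor_len={min_anchor_len}")

    junctions: list[str] = []
    segments: list[tuple[str, str, str | None, str | None]] = []
    for s, e, f in spans[1:-1]:
        if f.featuretype == "inverted_repeat":
            rep = plasmid[s:e]
            if len(rep) < MIN_REPEAT_LEN:
                raise LocusError(
                    f"inverted_repeat {_attr(f, 'Name') or s} shorter than {MIN_REPEAT_LEN} nt"
                )
            junctions.append(rep)
        else:
            name = _attr(f, "Name") or f"seg{len(segments) + 1}"
            orf_left = _attr(f, "orf_left")
            orf_right = _attr(f, "orf_right")
            if f.strand == "-":
                # swap ORF ends into locus (plasmid-forward) orientation
                orf_left, orf_right = orf_right, orf_left
            segments.append((name, plasmid[s:e], orf_left, orf_right))

    built = tuple(
        SegmentDef(
            name=name,
            body=body,
            left_repeat=junctions[i],
            right_repeat=junctions[i + 1],
            orf_left=ol,
            orf_right=orr,
        )
        for i, (name, body, ol, orr) in enumerate(segments)
    )
    return ShufflonLocus(
        plasmid_id=plasmid_id,
        plasmid_seq=plasmid,
        pilv_anchor=pilv,
        rci_anchor=rci,
        segments=built,
        junctions=tuple(junctions),
        locus_start=spans[0][0],
        circular=circular,
    )


def write_locus(locus: ShufflonLocus, fasta_path: str | Path, annotation_path: str | Path) -> None:
    """Write the plasmid FASTA and the GFF3-subset annotation for a locus."""
    rec = SeqRecord(Seq(locus.plasmid_seq), id=locus.plasmid_id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")

    lines = ["##gff-version 3", f"##sequence-region {locus.plasmid_id} 1 {locus.plasmid_len}"]
    pos = locus.locus_start  # 0-based cursor; emitted as 1-based inclusive

    def emit(ftype: str, length: int, attrs: str) -> None:
        nonlocal pos
        lines.append(
            "\t".join(
                (
                    locus.plasmid_id,
                    "shufflonq",
                    ftype,
                    str(pos + 1),
                    str(pos + length),
                    ".",
                    "+",
                    ".",
                    attrs,
                )
            )
        )
        pos += length

    emit("pilv_anchor", len(locus.pilv_anchor), "Name=pilV_anchor")
    emit("inverted_repeat", len(locus.junctions[0]), "Name=IR0")
    for i, seg in enumerate(locus.segments):
        attrs = [f"Name={seg.name}"]
        if seg.orf_left:
            attrs.append(f"orf_left={seg.orf_left}")
        if seg.orf_right:
            attrs.append(f"orf_right={seg.orf_right}")
        emit("shufflon_segment", len(seg.body), ";".join(attrs))
        emit("inverted_repeat", len(locus.junctions[i + 1]), f"Name=IR{i + 1}")
    emit("rci_anchor", len(locus.rci_anchor), "Name=rci_anchor")
    Path(annotation_path).write_text("\n".join(lines) + "\n")
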