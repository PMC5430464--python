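"""FASTA/FASTQ readers and writers (gzip-aware), built on Bio.SeqIO."""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_FASTA_EXTS = {".fa", ".fasta", ".fna"}
_FASTQ_EXTS = {".fq", ".fastq"}


def _format_of(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    ext = suffixes[-1] if suffixes else ""
    if ext in _FASTA_EXTS:
        return "fasta"
    if ext in _FASTQ_EXTS:
        return "fastq"
    raise ValueError(f"{path}: cannot infer sequence format from extension")


def _open(path: Path, mode: str):
    if path.suffix.lower() == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode, newline=None)  # universal newlines: CRLF == LF


def read_sequences(path) -> list[SeqRecord]:
    """Read all records from a plain or gzipped FASTA/FASTQ file, uppercased."""
    p = Path(path)
    fmt = _format_of(p)
    with _open(p, "r") as fh:
        try:
            records = list(SeqIO.parse(fh, fmt))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt} record ({exc})") from exc
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        rec.letter_annotations = {}
        rec.seq = Seq(str(rec.seq).upper())
        if quals is not None:
            rec.letter_annotations["phred_quality"] = quals
    if fmt == "fastq" and not records and p.stat().st_size > 0:
        raise ValueError(f"{path}: malformed fastq record (no records parsed)")
    return records


def write_sequences(records, path) -> None:
    """Write records to plain or gzipped FASTA/FASTQ (by extension)."""
    p = Path(path)
    fmt = _format_of(p)
    with _open(p, "w") as fh:
        SeqIO.write(list(records), fh, fmt)
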