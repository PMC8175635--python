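"""File-format plumbing: FASTA/FASTQ (plain or gzipped) and TSV reports.

Gzip is autodetected from the two magic bytes, not the file extension, on
input; on output a ``.gz`` suffix selects compression.  FASTA may be
multi-line; FASTQ must be plain 4-line records.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "open_text",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "write_scores_tsv",
    "write_truth_tsv",
]


class Read(NamedTuple):
    id: str
    sequence: str
    quality: str = ""


def _is_gzip(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def open_text(path, mode: str = "rt"):
    """Open a text file for reading (gzip by magic bytes) or writing (gzip
    by .gz suffix)."""
    path = Path(path)
    if "r" in mode:
        return gzip.open(path, mode) if _is_gzip(path) else open(path, mode)
    return gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """All records of a (possibly gzipped, possibly multi-line) FASTA."""
    with open_text(path) as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[Read]:
    """Iterate 4-line FASTQ records (gzip autodetected)."""
    with open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield Read(id=title.split()[0], sequence=seq, quality=qual)


def read_fastq_pairs(path1, path2) -> Iterator[tuple[Read, Read]]:
    """Iterate synchronized mate pairs from two FASTQ files."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise ValueError(f"{path1} and {path2} have different record counts")
        yield r1, r2


def write_fastq(reads: Iterable[Read], path) -> None:
    with open_text(path, "wt") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_scores_tsv(records, path) -> None:
    from .scoring import records_to_frame

    frame = records_to_frame(list(records))
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_truth_tsv(fragment_set, path) -> None:
    """Truth table for a FragmentSet: fragment_id, label, source, offset."""
    with open_text(path, "wt") as fh:
        fh.write("fragment_id\tlabel\tsource\toffset\n")
        for f in fragment_set.fragments:
            fh.write(f"{f.id}\t{f.label}\t{f.source_genome}\t{f.offset}\n")
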