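"""FASTA/FASTQ reading and writing plus the truth-table format.

Sequence parsing goes through Bio.SeqIO; writers emit plain uncompressed
text (FASTQ qualities are constant 'I', as the simulator carries no quality
model).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .fmindex import Reference
from .simulate import SimRead

TRUTH_HEADER = "read_id\tpos\tstrand"


def _format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    return "fasta"


def read_references(path) -> list[Reference]:
    refs = [Reference(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not refs:
        raise ValueError(f"no FASTA records in {path!r}")
    return refs


def read_reads(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTQ or FASTA (by file extension)."""
    for rec in SeqIO.parse(path, _format(path)):
        yield rec.id, str(rec.seq)


def write_fasta(path, refs: Iterable[Reference]) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n")
            for i in range(0, len(ref.seq), 70):
                fh.write(ref.seq[i:i + 70] + "\n")


def write_fastq(path, reads: Iterable[SimRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth(path, reads: Iterable[SimRead]) -> None:
    with open(path, "w") as fh:
        fh.write(TRUTH_HEADER + "\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.true_pos}\t{r.true_strand}\n")


def read_truth(path) -> dict[str, tuple[int, str]]:
    truth: dict[str, tuple[int, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != TRUTH_HEADER:
            raise ValueError(f"{path!r} is not a truth table")
        for line in fh:
            read_id, pos, strand = line.rstrip("\n").split("\t")
            truth[read_id] = (int(pos), strand)
    return truth
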