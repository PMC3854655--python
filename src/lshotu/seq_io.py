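"""Sequence and table I/O: multi-FASTA input, TSV OTU-assignment tables.

Reads are held as plain uppercase nucleotide strings over {A, C, G, T, N}.
Input order is preserved everywhere — the greedy clustering stage is
order-sensitive under its deterministic seeding mode, so a ``SampleSet``
iterates its records exactly in file order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import OTUAssignment

VALID_ALPHABET = frozenset("ACGTN")

OTU_TABLE_HEADER = ("sequence_id", "otu_id", "sample_id")


@dataclass(frozen=True)
class SequenceRecord:
    """One read: a unique identifier plus an uppercase nucleotide string."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SampleSet:
    """An ordered, stable collection of reads from one sample."""

    sample_id: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def min_length(self) -> int:
        return min(len(r) for r in self.records)


def normalize_sequence(raw: str, record_id: str) -> str:
    """Uppercase, map RNA 'U' to 'T', and enforce the {A,C,G,T,N} alphabet."""
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise ValueError(f"invalid alphabet: record '{record_id}' has empty sequence")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(
            f"invalid alphabet: record '{record_id}' contains {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path, sample_id: str | None = None) -> SampleSet:
    """Parse a multi-FASTA file into a :class:`SampleSet`, in file order.

    Sequences are normalized with :func:`normalize_sequence`. Duplicate
    identifiers and characters outside the alphabet are rejected.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate identifier '{rec.id}' in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SampleSet(sample_id or path.stem, records)


def write_fasta(sample: SampleSet, path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in sample.records
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_otu_table(assignment: "OTUAssignment", path: str | Path) -> None:
    """Write an OTU assignment as a three-column TSV.

    Columns: ``sequence_id``, ``otu_id``, ``sample_id``. Rows follow the
    assignment's insertion order (input order for clustering output).
    """
    sample_ids = assignment.sample_ids or {}
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(OTU_TABLE_HEADER) + "\n")
        for seq_id, otu_id in assignment.labels.items():
            fh.write(f"{seq_id}\t{otu_id}\t{sample_ids.get(seq_id, 'sample')}\n")


def read_otu_table(path: str | Path) -> "OTUAssignment":
    """Read a TSV OTU table back into an :class:`~lshotu.clustering.OTUAssignment`.

    Round-trips :func:`write_otu_table` exactly. Malformed lines raise a
    parse error naming the line number.
    """
    from .clustering import OTUAssignment

    labels: dict[str, str] = {}
    sample_ids: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != OTU_TABLE_HEADER:
            raise ValueError(f"line 1: expected header {OTU_TABLE_HEADER} in {path}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3 or not all(row):
                raise ValueError(f"line {lineno}: malformed OTU-table row {row!r}")
            seq_id, otu_id, sid = row
            if seq_id in labels:
                raise ValueError(f"line {lineno}: duplicate identifier '{seq_id}'")
            labels[seq_id] = otu_id
            sample_ids[seq_id] = sid
    if not labels:
        raise ValueError(f"no assignments in {path}")
    return OTUAssignment(labels=labels, sample_ids=sample_ids)
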