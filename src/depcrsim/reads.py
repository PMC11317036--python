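"""Read container and FASTQ I/O (Biopython-backed)."""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqIO import parse as seqio_parse
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .design import reverse_complement


@dataclass
class ReadRecord:
    """One sequencing read: id, sequence, per-base Phred qualities, replicate tag."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    replicate_id: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.sequence)} bases vs "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities)

    def reverse_complement(self) -> "ReadRecord":
        return ReadRecord(
            self.read_id,
            reverse_complement(self.sequence),
            tuple(reversed(self.qualities)),
            self.replicate_id,
            self.description,
        )

    def to_seqrecord(self) -> SeqRecord:
        rec = SeqRecord(Seq(self.sequence), id=self.read_id, description=self.description)
        rec.letter_annotations["phred_quality"] = list(self.qualities)
        return rec

    @classmethod
    def from_seqrecord(cls, rec: SeqRecord, replicate_id: Optional[str] = None) -> "ReadRecord":
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        return cls(
            rec.id,
            str(rec.seq),
            tuple(rec.letter_annotations["phred_quality"]),
            replicate_id,
            desc,
        )


def read_fastq(path, replicate_id: Optional[str] = None) -> Iterator[ReadRecord]:
    for rec in seqio_parse(path, "fastq"):
        yield ReadRecord.from_seqrecord(rec, replicate_id)


def write_fastq(reads: Iterable[ReadRecord], path) -> int:
    return seqio_write((r.to_seqrecord() for r in reads), path, "fastq")
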