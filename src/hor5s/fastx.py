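"""Plain-text FASTQ/FASTA records and readers/writers (Phred+33)."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ParseError


@dataclass(frozen=True)
class FastqRecord:
    id: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ParseError(f"record {self.id!r}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream FASTQ records; raises ParseError with the offending record index."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            if not lines[3]:
                raise ParseError("truncated FASTQ record", record_index=idx)
            header, seq, plus, qual = (ln.rstrip("\n") for ln in lines)
            if not header.startswith("@") or not plus.startswith("+"):
                raise ParseError("malformed FASTQ record", record_index=idx)
            if len(seq) != len(qual):
                raise ParseError("sequence/quality length mismatch", record_index=idx)
            yield FastqRecord(id=header[1:].split()[0], seq=seq.upper(), qual=qual)
            idx += 1


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> int:
    n = 0
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
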