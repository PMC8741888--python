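"""FASTQ/FASTA readers and writers and the 12-column marker table.

FASTQ is the strict 4-line layout with Phred+33 qualities, as produced by
Illumina instruments.  The results table is tab-separated with a header
row; each data line has exactly twelve fields describing one primer pair
designed for one microsatellite locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

PHRED_OFFSET = 33

OUTPUT_HEADER = (
    "ID",
    "Size",
    "Forward",
    "Tm_F",
    "Reverse",
    "Tm_R",
    "Motif",
    "Range",
    "Alleles",
    "Potential",
    "Flag",
    "Sequence",
)

BEST_FLAG = "|BEST|"


class FastqParseError(ValueError):
    """Malformed FASTQ record; message names the offending line number."""


@dataclass
class Read:
    """One sequencing record: identifier, bases, per-base Phred qualities.

    ``quals`` is None for FASTA-origin records.  Bases must be non-empty;
    when qualities are present they must match the base count.
    """

    id: str
    bases: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


def read_fastq(path) -> Iterator[Read]:
    """Yield reads from a 4-line FASTQ file in file order.

    Raises FastqParseError naming the line number for truncated records,
    missing '+' separators, or sequence/quality length mismatches.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}: line {lineno}: expected '@' header, got "
                    f"{header.strip()!r}"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqParseError(
                    f"{path}: line {lineno}: truncated record"
                )
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: line {lineno + 2}: expected '+' separator"
                )
            seq = seq.strip()
            qual = qual.strip()
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: line {lineno + 3}: quality length "
                    f"{len(qual)} != sequence length {len(seq)}"
                )
            yield Read(
                id=header[1:].strip().split()[0] if header[1:].strip() else "",
                bases=seq.upper(),
                quals=[ord(c) - PHRED_OFFSET for c in qual],
            )
            lineno += 3


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.quals is None:
                raise ValueError(f"read {r.id!r} has no qualities")
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def read_fasta(path) -> Iterator[Read]:
    """Yield FASTA records as Reads with quals=None."""
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield Read(id=name, bases="".join(chunks).upper())
                name = line[1:].split()[0] if line[1:] else ""
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        yield Read(id=name, bases="".join(chunks).upper())


def write_fasta(reads: Iterable[Read], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.bases), width):
                fh.write(r.bases[i : i + width] + "\n")


@dataclass
class OutputRecord:
    """One line of the results table: a primer pair for one locus.

    Twelve fields: locus/pair id, amplicon size, forward primer and Tm,
    reverse primer and Tm, motif "(UNIT)count", allele length range
    "min-max", observed and potential allele counts, best-pair flag
    (``|BEST|`` or empty), and the locus representative sequence.
    """

    id: str
    size: int
    fwd_seq: str
    fwd_tm: float
    rev_seq: str
    rev_tm: float
    motif: str
    range: str
    alleles_observed: int
    alleles_potential: int
    best_flag: str
    sequence: str

    def to_fields(self) -> list[str]:
        return [
            self.id,
            str(self.size),
            self.fwd_seq,
            f"{self.fwd_tm:.2f}",
            self.rev_seq,
            f"{self.rev_tm:.2f}",
            self.motif,
            self.range,
            str(self.alleles_observed),
            str(self.alleles_potential),
            self.best_flag,
            self.sequence,
        ]

    @classmethod
    def from_fields(cls, fields: list[str]) -> "OutputRecord":
        if len(fields) != 12:
            raise ValueError(f"expected 12 fields, got {len(fields)}")
        return cls(
            id=fields[0],
            size=int(fields[1]),
            fwd_seq=fields[2],
            fwd_tm=float(fields[3]),
            rev_seq=fields[4],
            rev_tm=float(fields[5]),
            motif=fields[6],
            range=fields[7],
            alleles_observed=int(fields[8]),
            alleles_potential=int(fields[9]),
            best_flag=fields[10],
            sequence=fields[11],
        )


def write_output_table(records: Iterable[OutputRecord], path) -> None:
    """Write the tab-separated results table with a header row.

    Records are expected ordered by locus number then pair number; melting
    temperatures are printed with two decimals.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(OUTPUT_HEADER) + "\n")
        for rec in records:
            fh.write("\t".join(rec.to_fields()) + "\n")


def parse_output_table(path) -> list[OutputRecord]:
    """Inverse of write_output_table."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and tuple(header.rstrip("\n").split("\t")) != OUTPUT_HEADER:
            raise ValueError(f"{path}: unrecognised header")
        for line in fh:
            if line.strip():
                out.append(OutputRecord.from_fields(line.rstrip("\n").split("\t")))
    return out
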