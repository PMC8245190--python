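"""Assembly input and contig-as-transcript annotation.

The unit of quantification in comparative coverage analysis is the assembly
contig: every contig is treated as a single full-length "transcript" so that
DNA read coverage can be funnelled through an FPKM-style normalisation.  This
module reads the assembly, keeps the contig registry, and emits the
corresponding single-transcript GFF3 annotation.

Coordinates are GFF3 1-based inclusive on disk; internal arithmetic is
0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "ContigRecord",
    "GenomeIndex",
    "ContigAnnotation",
    "read_fasta",
    "build_contig_annotation",
    "write_gff3",
    "read_gff3",
    "write_fasta",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ContigRecord:
    """A single assembly contig."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise ValueError(f"contig id {self.id!r} is empty or contains whitespace")
        bad = next((i for i, b in enumerate(self.sequence) if b not in _VALID_BASES), None)
        if bad is not None:
            raise ValueError(
                f"contig {self.id!r}: non-IUPAC character {self.sequence[bad]!r} at position {bad + 1}"
            )
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeIndex:
    """Ordered collection of contigs; the universe of testable units."""

    contigs: list[ContigRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.contigs:
            if c.id in seen:
                raise ValueError(f"duplicate contig id {c.id!r}")
            seen.add(c.id)
        self._by_id = {c.id: c for c in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.contigs]

    @property
    def lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.contigs}

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[ContigRecord]:
        return iter(self.contigs)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def __getitem__(self, contig_id: str) -> ContigRecord:
        return self._by_id[contig_id]


@dataclass(frozen=True)
class ContigAnnotation:
    """One full-span transcript per contig (1-based inclusive coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"
    transcript_id: str = ""
    gene_id: str = ""


def read_fasta(path: str | Path) -> GenomeIndex:
    """Read an assembly FASTA into a :class:`GenomeIndex`.

    Sequences are upper-cased; the header token before the first whitespace
    becomes the contig id.  Duplicate ids, empty files and non-ACGTN
    characters are hard errors.
    """
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.append(ContigRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeIndex(contigs)


def write_fasta(genome: GenomeIndex, path: str | Path, width: int = 80) -> None:
    """Write the assembly back out (deterministic line wrapping)."""
    with open(path, "w") as fh:
        for c in genome:
            fh.write(f">{c.id}\n")
            for i in range(0, c.length, width):
                fh.write(c.sequence[i : i + width] + "\n")


def build_contig_annotation(genome: GenomeIndex) -> list[ContigAnnotation]:
    """One full-span, plus-strand annotation per contig.

    transcript_id and gene_id both equal the contig id, so every downstream
    table can key on contig id alone.
    """
    if len(genome) == 0:
        raise ValueError("cannot annotate an empty genome")
    return [
        ContigAnnotation(
            contig_id=c.id,
            start=1,
            end=c.length,
            strand="+",
            transcript_id=c.id,
            gene_id=c.id,
        )
        for c in genome
    ]


def write_gff3(annotations: Iterable[ContigAnnotation], path: str | Path) -> None:
    """Write the contig-as-single-transcript annotation as GFF3.

    Each contig gets a ``transcript`` line and one ``exon`` line, both
    spanning the full contig, in input order.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f'gene_id "{a.gene_id}"; transcript_id "{a.transcript_id}";'
            for feature in ("transcript", "exon"):
                fh.write(
                    "\t".join(
                        [
                            a.contig_id,
                            "grcfind",
                            feature,
                            str(a.start),
                            str(a.end),
                            ".",
                            a.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path) -> list[ContigAnnotation]:
    """Parse a contig-as-transcript GFF3 back into annotations.

    Only ``transcript`` lines are consumed; exon lines are redundant by
    construction.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line (expected 9 columns): {line!r}")
            if cols[2] != "transcript":
                continue
            m_gene = re.search(r'gene_id "([^"]+)"', cols[8])
            m_tx = re.search(r'transcript_id "([^"]+)"', cols[8])
            out.append(
                ContigAnnotation(
                    contig_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    transcript_id=m_tx.group(1) if m_tx else cols[0],
                    gene_id=m_gene.group(1) if m_gene else cols[0],
                )
            )
    return out
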