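"""Genome sequences and transcript models.

All coordinates inside the package are 0-based half-open. GFF3 (1-based
closed) and VCF (1-based) are converted at the parser/writer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from Bio.Seq import Seq

Interval = tuple[int, int]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate a coding sequence; internal/terminal stops appear as '*'."""
    return str(Seq(cds).translate())


@dataclass
class Genome:
    """In-memory genome: chromosome name -> uppercase DNA string."""

    sequences: dict[str, str]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 0-based half-open interval [start, end)."""
        return self.sequences[chrom][start:end]


def _merged_length(intervals: list[Interval]) -> int:
    total, prev_end = 0, -1
    for a, b in sorted(intervals):
        a = max(a, prev_end)
        if b > a:
            total += b - a
            prev_end = b
    return total


@dataclass
class TranscriptModel:
    """One gene/transcript with exon, CDS and UTR structure.

    Intervals are genomic, 0-based half-open, sorted by start. On the minus
    strand the first codon sits at the highest genomic coordinate.
    """

    gene_id: str
    tx_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.tx_id}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)
        if sum(b - a for a, b in self.cds) % 3 != 0:
            raise ValueError(f"CDS length of {self.tx_id} not divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[Interval]:
        gaps = []
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 > b1:
                gaps.append((b1, a2))
        return gaps

    @property
    def cds_len(self) -> int:
        return sum(b - a for a, b in self.cds)

    def exonic_length(self) -> int:
        """Union-of-exons length in bp (the FPKM gene length)."""
        return _merged_length(self.exons)

    def promoter(self, flank: int = 2000) -> Interval:
        """Strand-aware upstream flank of the TSS, clipped at 0."""
        if self.strand == "+":
            return (max(0, self.start - flank), self.start)
        return (self.end, self.end + flank)

    def terminator(self, flank: int = 2000) -> Interval:
        """Strand-aware downstream flank of the transcript end."""
        if self.strand == "+":
            return (self.end, self.end + flank)
        return (max(0, self.start - flank), self.start)

    # -- coding-frame helpers -------------------------------------------------

    def coding_sequence(self, genome: Genome) -> str:
        parts = [genome.fetch(self.chrom, a, b) for a, b in self.cds]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def coding_index(self, pos: int) -> int | None:
        """Transcription-order index of genomic position ``pos`` within the CDS,
        or None if the position is not coding."""
        if self.strand == "+":
            off = 0
            for a, b in self.cds:
                if a <= pos < b:
                    return off + (pos - a)
                off += b - a
            return None
        off = 0
        for a, b in reversed(self.cds):
            if a <= pos < b:
                return off + (b - 1 - pos)
            off += b - a
        return None

    def coding_positions(self) -> list[int]:
        """Genomic position of each coding index, in transcription order."""
        out: list[int] = []
        if self.strand == "+":
            for a, b in self.cds:
                out.extend(range(a, b))
        else:
            for a, b in reversed(self.cds):
                out.extend(range(b - 1, a - 1, -1))
        return out

    def splice_sites(self) -> Iterator[tuple[Interval, str]]:
        """Yield (2-bp genomic interval, 'splice_donor'|'splice_acceptor') for
        each intron boundary, in transcription order."""
        for a, b in self.introns:
            if b - a < 4:  # degenerate intron; skip rather than overlap sites
                continue
            if self.strand == "+":
                yield (a, a + 2), "splice_donor"
                yield (b - 2, b), "splice_acceptor"
            else:
                yield (b - 2, b), "splice_donor"
                yield (a, a + 2), "splice_acceptor"

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end
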