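"""Shared domain containers.

The genome is circular: intervals are 0-based half-open on the plus strand
of a fixed rotation; an interval whose end exceeds the genome length wraps
through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from ._seq import revcomp

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class CircularGenome:
    """A (usually circular) plastome sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"genome {self.id}: non-ACGTN characters {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps through the origin when circular."""
        n = len(self.sequence)
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise IndexError(f"[{start}, {end}) outside linear genome of length {n}")
        length = end - start
        start %= n
        doubled = self.sequence + self.sequence
        if length > n:
            reps = length // n
            return (self.sequence * reps + doubled[start:start + (length % n)])[:length]
        return doubled[start:start + length]

    def reverse_complement(self) -> "CircularGenome":
        return replace(self, sequence=revcomp(self.sequence))


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of exon intervals on the genome plus strand.

    ``exons`` are stored in genome (plus-strand) order; for minus-strand
    genes transcription order is the reverse.
    """

    name: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    gene_type: str = "CDS"  # CDS | tRNA | rRNA
    codon_start: int = 1

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.name}: empty exon [{s},{e})")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (gaps between consecutive exons, genome order)."""
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def spliced_sequence(self, genome: CircularGenome) -> str:
        seq = "".join(genome.fetch(s, e) for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    @property
    def family(self) -> str:
        """Gene-family prefix: the leading lowercase run (atpF -> atp,
        rpl22 -> rpl); the member designator (capital letter or number)
        is dropped."""
        out = []
        for ch in self.name:
            if ch.isalpha() and ch.islower():
                out.append(ch)
            else:
                break
        return "".join(out)


@dataclass
class Annotation:
    genome_id: str
    genome_length: int
    genes: list[GeneModel] = field(default_factory=list)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def by_name(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def sorted_by_position(self) -> list[GeneModel]:
        return sorted(self.genes, key=lambda g: g.start)

    def gene_at(self, pos: int) -> GeneModel | None:
        for g in self.genes:
            if g.start <= pos < g.end:
                return g
        return None


@dataclass(frozen=True)
class LongRead:
    """A simulated genomic long read with its planted truth."""

    id: str
    sequence: str
    source_start: int  # on the source genome; end may exceed length (wrap)
    source_end: int
    strand: str
    origin: str  # label of the source genome ('chloroplast', 'decoy', ...)


@dataclass
class LongReadSet:
    reads: list[LongRead]
    seed: int | None = None

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)

    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads)


@dataclass(frozen=True)
class TranscriptRead:
    """A simulated full-length cDNA; ``unit_id`` is its true transcription unit."""

    id: str
    sequence: str
    unit_id: str
    strand: str
    span: tuple[int, int]  # genomic span of the unit it came from


@dataclass
class TranscriptReadSet:
    reads: list[TranscriptRead]
    seed: int | None = None

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)


@dataclass(frozen=True)
class TranscriptionUnit:
    """One transcription unit: ordered co-stranded genes plus short UTRs."""

    id: str
    gene_names: tuple[str, ...]
    strand: str
    start: int  # genomic span including UTR extensions
    end: int


@dataclass(frozen=True)
class IntronTruth:
    gene: str
    donor: int     # genomic position of first intron base
    acceptor: int  # one past the last intron base (half-open end)

    @property
    def length(self) -> int:
        return self.acceptor - self.donor


@dataclass(frozen=True)
class EditingTruth:
    position: int
    strand: str
    efficiency: float
    category: str  # CDS | intron | intergenic


@dataclass
class GroundTruth:
    """Everything the synthetic generator planted, for recovery tests."""

    region_coords: dict[str, tuple[int, int]]  # lsc / ira / ssc / irb
    annotation: Annotation
    introns: list[IntronTruth]
    editing_sites: list[EditingTruth]
    units: list[TranscriptionUnit]
    seed: int
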