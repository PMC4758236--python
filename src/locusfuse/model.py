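"""Core coordinate and annotation types.

All coordinates are 0-based half-open throughout the package; the GFF3
reader/writer converts at the boundary (1-based closed on disk). Strand is
carried on every interval but ignored by the fusion logic unless
strand-aware mode is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A scaffold-anchored span, 0-based half-open: [start, end)."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.scaffold_id}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.scaffold_id}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold_id == other.scaffold_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases strictly between two same-scaffold intervals.

    Returns 0 when the intervals overlap or abut. This is the substrate for
    the "<50 bases apart" vicinity rule: two features are in vicinity when
    their gap is strictly below the threshold.
    """
    if a.scaffold_id != b.scaffold_id:
        raise ValueError(
            f"interval_gap across scaffolds: {a.scaffold_id} vs {b.scaffold_id}"
        )
    gap = max(a.start, b.start) - min(a.end, b.end)
    return max(0, gap)


def span_hull(intervals: list[GenomicInterval]) -> GenomicInterval:
    """Bounding span of same-scaffold intervals."""
    if not intervals:
        raise ValueError("span_hull of empty list")
    scaffolds = {iv.scaffold_id for iv in intervals}
    if len(scaffolds) != 1:
        raise ValueError(f"span_hull across scaffolds: {sorted(scaffolds)}")
    return GenomicInterval(
        intervals[0].scaffold_id,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
        intervals[0].strand,
    )


@dataclass
class GenePrediction:
    """An ab initio gene model: an exon chain plus a coding length.

    ``coding_length_nt`` comes from CDS features where the source GFF3 has
    them, otherwise from the summed exon lengths. The spans between
    consecutive exons are the predicted introns.
    """

    gene_id: str
    exons: list[GenomicInterval]
    coding_length_nt: int = -1  # -1: derive from exons

    span: GenomicInterval = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"prediction {self.gene_id} has no exons")
        scaffolds = {e.scaffold_id for e in self.exons}
        if len(scaffolds) != 1:
            raise ValueError(f"prediction {self.gene_id} spans scaffolds {sorted(scaffolds)}")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"prediction {self.gene_id}: exons unsorted or overlapping "
                    f"([{prev.start},{prev.end}) then [{cur.start},{cur.end}))"
                )
        if self.coding_length_nt < 0:
            self.coding_length_nt = sum(e.length for e in self.exons)
        self.span = span_hull(self.exons)

    @property
    def scaffold_id(self) -> str:
        return self.span.scaffold_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def coding_length_aa(self) -> int:
        # approximate protein length; stop codons are not modelled
        return self.coding_length_nt // 3

    def predicted_introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.scaffold_id, prev.end, cur.start, self.strand)
            for prev, cur in zip(self.exons, self.exons[1:])
            if cur.start > prev.end
        ]


@dataclass
class TranscriptAlignment:
    """A spliced transcript-to-genome alignment (one PSL row).

    ``blocks`` are the ungapped aligned segments on the target scaffold;
    the inter-block gaps on the genome are candidate introns.
    """

    transcript_id: str
    scaffold_id: str
    blocks: list[GenomicInterval]
    query_length: int
    matches: int
    strand: str = "+"

    span: GenomicInterval = field(init=False)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"alignment {self.transcript_id} has no blocks")
        for b in self.blocks:
            if b.scaffold_id != self.scaffold_id:
                raise ValueError(
                    f"alignment {self.transcript_id}: block on {b.scaffold_id}, "
                    f"target is {self.scaffold_id}"
                )
        for prev, cur in zip(self.blocks, self.blocks[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"alignment {self.transcript_id}: blocks unsorted or overlapping"
                )
        if self.query_length <= 0:
            raise ValueError(f"alignment {self.transcript_id}: query_length must be > 0")
        if not (0 < self.matches <= self.query_length):
            raise ValueError(
                f"alignment {self.transcript_id}: matches {self.matches} outside "
                f"(0, {self.query_length}]"
            )
        self.span = GenomicInterval(
            self.scaffold_id, self.blocks[0].start, self.blocks[-1].end, self.strand
        )

    @property
    def identity(self) -> float:
        return self.matches / self.query_length

    def block_gaps(self) -> list[GenomicInterval]:
        """Genomic gaps between consecutive blocks (candidate introns)."""
        return [
            GenomicInterval(self.scaffold_id, prev.end, cur.start, self.strand)
            for prev, cur in zip(self.blocks, self.blocks[1:])
            if cur.start > prev.end
        ]


@dataclass
class DomainTable:
    """Per-genome multiset of (gene_id, domain_id) hits, InterProScan-style."""

    genome_id: str
    hits: list[tuple[str, str]]

    @property
    def total_hits(self) -> int:
        return len(self.hits)

    @property
    def distinct_domains(self) -> int:
        return len({d for _, d in self.hits})

    def domain_set(self) -> set[str]:
        return {d for _, d in self.hits}


@dataclass
class GeneLocus:
    """A consolidated gene locus: a connected component of predictions and
    reference transcripts on one scaffold."""

    locus_id: str
    scaffold_id: str
    span: GenomicInterval
    prediction_ids: list[str]
    transcript_ids: list[str]
    max_coding_length_aa: int

    def __post_init__(self) -> None:
        if not self.prediction_ids and not self.transcript_ids:
            raise ValueError(f"locus {self.locus_id} has no members")

    @property
    def supported(self) -> bool:
        return bool(self.transcript_ids)

    @property
    def length(self) -> int:
        return self.span.length
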