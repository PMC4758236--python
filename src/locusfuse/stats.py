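"""Transcript-based intron confirmation and summary statistics, plus the
comparative protein-domain census.

An intron is *confirmed* when a predicted intron (the gap between two
consecutive exons of a gene model) coincides exactly in genomic
coordinates with a gap between consecutive blocks of a spliced transcript
alignment. Inter-block gaps shorter than ``min_intron_bp`` are treated as
alignment indels, not introns.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .model import DomainTable, GeneLocus, GenePrediction, GenomicInterval, TranscriptAlignment

DEFAULT_MIN_INTRON_BP = 20
DEFAULT_FOLD_THRESHOLD = 3.0

PREDICTED = "predicted"
ALIGNED = "aligned"


@dataclass(frozen=True)
class Intron:
    interval: GenomicInterval
    source: str  # predicted | aligned
    confirmed: bool = False

    @property
    def scaffold_id(self) -> str:
        return self.interval.scaffold_id

    @property
    def length(self) -> int:
        return self.interval.length

    def coords(self) -> tuple[str, int, int]:
        return (self.interval.scaffold_id, self.interval.start, self.interval.end)


def aligned_introns(
    alignments: list[TranscriptAlignment], min_intron_bp: int = DEFAULT_MIN_INTRON_BP
) -> set[Intron]:
    """Candidate introns from spliced alignments: every inter-block gap of
    length >= min_intron_bp, deduplicated on (scaffold, start, end)."""
    if min_intron_bp < 1:
        raise ValueError("min_intron_bp must be >= 1")
    seen: dict[tuple[str, int, int], Intron] = {}
    for aln in alignments:
        for gap in aln.block_gaps():
            if gap.length < min_intron_bp:
                continue
            key = (gap.scaffold_id, gap.start, gap.end)
            if key not in seen:
                seen[key] = Intron(
                    GenomicInterval(gap.scaffold_id, gap.start, gap.end), source=ALIGNED
                )
    return set(seen.values())


def confirm_introns(
    predictions: list[GenePrediction],
    aligned: set[Intron],
    slack_bp: int = 0,
) -> list[Intron]:
    """Mark every predicted intron confirmed iff an aligned intron matches
    its coordinates (exactly by default; ``slack_bp`` tolerates boundary
    wobble for noisy alignments)."""
    by_coords = {i.coords() for i in aligned}
    by_scaffold: dict[str, list[tuple[int, int]]] = defaultdict(list)
    if slack_bp > 0:
        for i in aligned:
            by_scaffold[i.scaffold_id].append((i.interval.start, i.interval.end))
    out: list[Intron] = []
    for p in predictions:
        for gap in p.predicted_introns():
            key = (gap.scaffold_id, gap.start, gap.end)
            ok = key in by_coords
            if not ok and slack_bp > 0:
                ok = any(
                    abs(s - gap.start) <= slack_bp and abs(e - gap.end) <= slack_bp
                    for s, e in by_scaffold[gap.scaffold_id]
                )
            out.append(
                Intron(
                    GenomicInterval(gap.scaffold_id, gap.start, gap.end),
                    source=PREDICTED,
                    confirmed=ok,
                )
            )
    return out


def _lower_median(values: list[int]) -> float | None:
    if not values:
        return None
    ordered = sorted(values)
    return float(ordered[(len(ordered) - 1) // 2])


def intron_summary(
    introns: list[Intron], loci: list[GeneLocus], supported_only: bool = False
) -> dict:
    """Confirmed/predicted intron counts, confirmed-length median (lower
    median for even counts), and confirmed introns per locus, with the
    denominator either all loci or supported loci only."""
    confirmed = [i for i in introns if i.confirmed]
    denom_loci = [lo for lo in loci if lo.supported] if supported_only else loci
    n_denom = len(denom_loci)
    return {
        "n_confirmed": len(confirmed),
        "n_predicted": len(introns),
        "median_confirmed_length": _lower_median([i.length for i in confirmed]),
        "mean_confirmed_per_locus": (len(confirmed) / n_denom) if n_denom else None,
        "n_loci_denominator": n_denom,
    }


@dataclass
class DomainCensus:
    """Cross-genome domain occurrence algebra over per-genome hit tables."""

    tables: list[DomainTable]
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD

    totals: dict[str, dict] = field(init=False)
    counts: dict[str, Counter] = field(init=False)

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("domain census needs at least one table")
        ids = [t.genome_id for t in self.tables]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate genome ids: {ids}")
        self.counts = {t.genome_id: Counter(d for _, d in t.hits) for t in self.tables}
        self.totals = {
            t.genome_id: {
                "total_hits": t.total_hits,
                "distinct_domains": t.distinct_domains,
            }
            for t in self.tables
        }

    def domains(self, genome_id: str) -> set[str]:
        return set(self.counts[genome_id])

    def shared_absent(self, present_a: str, present_b: str, absent: str) -> set[str]:
        """Domains present at least once in both of two genomes but absent
        from a third."""
        return (self.domains(present_a) & self.domains(present_b)) - self.domains(absent)

    def enrichment(self, focal: str) -> list[dict]:
        """Domains over-represented in the focal genome: count fold =
        focal / (1 + max count among the other genomes), reported where
        fold >= fold_threshold. The +1 pseudocount keeps domains absent
        elsewhere finite and comparable."""
        others = [g for g in self.counts if g != focal]
        records = []
        for domain, n_focal in sorted(self.counts[focal].items()):
            n_other_max = max((self.counts[g].get(domain, 0) for g in others), default=0)
            fold = n_focal / (1 + n_other_max)
            if fold >= self.fold_threshold:
                records.append(
                    {
                        "domain_id": domain,
                        "count_focal": n_focal,
                        "max_count_other": n_other_max,
                        "fold": fold,
                    }
                )
        records.sort(key=lambda r: (-r["fold"], r["domain_id"]))
        return records


def domain_census(
    tables: list[DomainTable], fold_threshold: float = DEFAULT_FOLD_THRESHOLD
) -> DomainCensus:
    return DomainCensus(tables=tables, fold_threshold=fold_threshold)


def loci_with_domain(
    loci: list[GeneLocus],
    table: DomainTable,
    domain_id: str,
    min_length_aa: int = 0,
) -> dict:
    """Locus-level query for one domain: which loci contain at least one
    member prediction that carries it. Multiple hit genes fused into one
    locus count that locus once."""
    gene_to_locus: dict[str, GeneLocus] = {}
    for lo in loci:
        for gid in lo.prediction_ids:
            gene_to_locus[gid] = lo
    hit_loci: dict[str, GeneLocus] = {}
    for gid, dom in table.hits:
        if dom == domain_id and gid in gene_to_locus:
            lo = gene_to_locus[gid]
            hit_loci[lo.locus_id] = lo
    found = sorted(hit_loci.values(), key=lambda lo: lo.locus_id)
    return {
        "domain_id": domain_id,
        "n_loci": len(found),
        "n_supported": sum(lo.supported for lo in found),
        "n_passing_length": sum(lo.max_coding_length_aa >= min_length_aa for lo in found),
        "locus_ids": [lo.locus_id for lo in found],
    }
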