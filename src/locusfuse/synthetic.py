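"""Synthetic genomes with known gene loci for exercising the pipeline.

The generator emulates the statistical structure the consolidation method
assumes in a fragmented, repeat-rich amoebozoan assembly:

* multi-exon gene models with many introns (intron count Poisson with mean
  ``introns_per_gene_mean``, default 9; intron lengths log-normal with
  median ``intron_length_log_median``, default 231 bp, with a
  low-complexity tandem-repeat core);
* simple-repeat spacers ("ATAT...", "CAGCAG...") between genes, at which
  scaffolds may fracture (``scaffold_split_rate``), leaving the two halves
  of a gene on differently named scaffolds;
* ab initio predictions that over-split a gene at a random internal intron
  (``prediction_split_rate``), mimicking overprediction on fragmented
  sequence;
* transcript evidence for roughly half the loci
  (``transcript_support_fraction``), as redundant slightly diverged copies
  whose undiverged original is always the longest, so centroid clustering
  has real work to do.

Alignments are emitted from truth rather than produced by an aligner: the
method under study starts downstream of the mapping step, and emitting
truth keeps runs deterministic. All outputs are plain text (FASTA, GFF3,
PSL, TSV) plus a params JSON sidecar; a fixed seed gives byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import write_fasta, write_gff3, write_psl
from .model import DomainTable, GeneLocus, GenePrediction, GenomicInterval, TranscriptAlignment

_BASES = np.array(list("ACGT"))
_REPEAT_UNITS = ("AT", "CAG", "TA", "CTG")

TRUTH_COLUMNS = ["locus_id", "parts", "prediction_ids", "transcript_ids", "supported"]


@dataclass
class SimulationParams:
    """Study conditions for the synthetic genome.

    Defaults mirror the annotated organism's reported structure: about
    half the loci have transcript evidence, introns are log-normal with
    median 231 bp, genes average 9 introns, and the 126 bp mean exon gives
    a mean transcript length near 1,260 bases.
    """

    n_true_loci: int = 100
    scaffold_split_rate: float = 0.01
    prediction_split_rate: float = 0.05
    transcript_support_fraction: float = 0.5
    redundancy: float = 2.0
    divergence: float = 0.01
    intron_length_log_median: float = 231.0
    intron_length_log_sigma: float = 0.75
    introns_per_gene_mean: float = 9.0
    exon_length_mean: float = 126.0
    min_exon_bp: int = 30
    min_intron_bp: int = 30
    spacer_length: int = 150
    genes_per_scaffold: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_loci < 1:
            raise ValueError("n_true_loci must be >= 1")
        for name in (
            "scaffold_split_rate",
            "prediction_split_rate",
            "transcript_support_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if self.redundancy < 0:
            raise ValueError("redundancy must be >= 0")
        if self.intron_length_log_median <= 0 or self.exon_length_mean <= 0:
            raise ValueError("length parameters must be positive")


@dataclass
class TruthLocus:
    locus_id: str
    parts: list[tuple[str, int, int]]  # (scaffold, start, end) per scaffold piece
    prediction_ids: list[str]
    transcript_ids: list[str]

    @property
    def supported(self) -> bool:
        return bool(self.transcript_ids)


@dataclass
class TruthTable:
    loci: list[TruthLocus]

    def all_transcript_ids(self) -> list[str]:
        return sorted(t for lo in self.loci for t in lo.transcript_ids)

    def n_supported(self) -> int:
        return sum(lo.supported for lo in self.loci)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(TRUTH_COLUMNS) + "\n")
            for lo in self.loci:
                parts = ";".join(f"{s}:{a}-{b}" for s, a, b in lo.parts)
                fh.write(
                    f"{lo.locus_id}\t{parts}\t{','.join(lo.prediction_ids)}\t"
                    f"{','.join(lo.transcript_ids)}\t{int(lo.supported)}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "TruthTable":
        loci = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != TRUTH_COLUMNS:
                raise ValueError(f"unexpected truth table header {header}")
            for line in fh:
                locus_id, parts_s, preds_s, txs_s, _sup = line.rstrip("\n").split("\t")
                parts = []
                for token in parts_s.split(";"):
                    scaf, span = token.rsplit(":", 1)
                    a, b = span.split("-")
                    parts.append((scaf, int(a), int(b)))
                loci.append(
                    TruthLocus(
                        locus_id=locus_id,
                        parts=parts,
                        prediction_ids=[p for p in preds_s.split(",") if p],
                        transcript_ids=[t for t in txs_s.split(",") if t],
                    )
                )
        return cls(loci)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _spacer_seq(unit: str, length: int) -> str:
    reps = unit * (length // len(unit) + 1)
    return reps[:length]


def _intron_seq(rng: np.random.Generator, length: int) -> str:
    # low-complexity core flanked by random sequence, echoing repeat-rich introns
    if length < 60:
        return _random_seq(rng, length)
    core_len = length // 3
    unit = _REPEAT_UNITS[int(rng.integers(0, len(_REPEAT_UNITS)))]
    flank = length - core_len
    left = flank // 2
    return _random_seq(rng, left) + _spacer_seq(unit, core_len) + _random_seq(
        rng, flank - left
    )


@dataclass
class _Gene:
    index: int
    gene_id: str
    strand: str
    exon_seqs: list[str]
    intron_lengths: list[int]
    scaffold: str = ""
    exons: list[tuple[int, int]] = field(default_factory=list)  # original coords
    introns: list[tuple[int, int]] = field(default_factory=list)
    cut_intron: int = -1  # index of intron hosting a scaffold cut, -1 = none
    pred_split_intron: int = -1
    supported: bool = False
    n_copies: int = 0

    @property
    def transcript_seq(self) -> str:
        return "".join(self.exon_seqs)


def generate(
    params: SimulationParams, outdir: str | os.PathLike, overwrite: bool = False
) -> TruthTable:
    """Generate a synthetic dataset under ``outdir`` and return its truth.

    Writes genome.fasta, predictions.gff3, transcripts.fasta,
    alignments.psl, domains.tsv, truth.tsv and params.json. Fully
    deterministic under ``params.seed``.
    """
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    # ---- gene structures -------------------------------------------------
    log_mu = math.log(params.intron_length_log_median)
    genes: list[_Gene] = []
    for i in range(params.n_true_loci):
        n_introns = int(rng.poisson(params.introns_per_gene_mean))
        exon_lens = [
            max(
                params.min_exon_bp,
                int(round(rng.normal(params.exon_length_mean, params.exon_length_mean / 3))),
            )
            for _ in range(n_introns + 1)
        ]
        intron_lens = [
            max(
                params.min_intron_bp,
                int(round(rng.lognormal(log_mu, params.intron_length_log_sigma))),
            )
            for _ in range(n_introns)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            _Gene(
                index=i,
                gene_id=f"g{i:04d}",
                strand=strand,
                exon_seqs=[_random_seq(rng, L) for L in exon_lens],
                intron_lengths=intron_lens,
            )
        )

    # ---- scaffold layout -------------------------------------------------
    scaffold_seqs: dict[str, str] = {}
    scaffold_genes: dict[str, list[_Gene]] = {}
    n_groups = (len(genes) + params.genes_per_scaffold - 1) // params.genes_per_scaffold
    spacer_i = 0
    for grp in range(n_groups):
        name = f"scf{grp:04d}"
        chunk = genes[grp * params.genes_per_scaffold : (grp + 1) * params.genes_per_scaffold]
        pieces: list[str] = []
        pos = 0

        def _add_spacer() -> None:
            nonlocal pos, spacer_i
            unit = _REPEAT_UNITS[spacer_i % 2]  # alternate di-/tri-nucleotide runs
            spacer_i += 1
            pieces.append(_spacer_seq(unit, params.spacer_length))
            pos += params.spacer_length

        _add_spacer()
        for gene in chunk:
            gene.scaffold = name
            for j, exon_seq in enumerate(gene.exon_seqs):
                gene.exons.append((pos, pos + len(exon_seq)))
                pieces.append(exon_seq)
                pos += len(exon_seq)
                if j < len(gene.intron_lengths):
                    ilen = gene.intron_lengths[j]
                    gene.introns.append((pos, pos + ilen))
                    pieces.append(_intron_seq(rng, ilen))
                    pos += ilen
            _add_spacer()
        scaffold_seqs[name] = "".join(pieces)
        scaffold_genes[name] = chunk

    # ---- scaffold fragmentation at a random internal intron -------------
    for gene in genes:
        if gene.introns and rng.random() < params.scaffold_split_rate:
            gene.cut_intron = int(rng.integers(0, len(gene.introns)))

    genome: dict[str, str] = {}
    # part map: original scaffold -> list of (part_name, orig_start, orig_end)
    part_map: dict[str, list[tuple[str, int, int]]] = {}
    for name, seq in scaffold_seqs.items():
        cuts = sorted(
            (g.introns[g.cut_intron][0] + g.introns[g.cut_intron][1]) // 2
            for g in scaffold_genes[name]
            if g.cut_intron >= 0
        )
        if not cuts:
            part_map[name] = [(name, 0, len(seq))]
            genome[name] = seq
            continue
        bounds = [0] + cuts + [len(seq)]
        parts = []
        for k, (a, b) in enumerate(zip(bounds, bounds[1:])):
            pname = f"{name}_p{k}"
            parts.append((pname, a, b))
            genome[pname] = seq[a:b]
        part_map[name] = parts

    def _map_interval(scaffold: str, s: int, e: int) -> tuple[str, int, int]:
        for pname, a, b in part_map[scaffold]:
            if a <= s and e <= b:
                return (pname, s - a, e - a)
        raise AssertionError(f"interval [{s},{e}) straddles a cut on {scaffold}")

    # ---- per-gene parts: exons grouped by scaffold piece -----------------
    for gene in genes:
        mapped = [_map_interval(gene.scaffold, s, e) for s, e in gene.exons]
        gene.mapped_exons = mapped  # type: ignore[attr-defined]
        part_names = []
        for pname, _, _ in mapped:
            if pname not in part_names:
                part_names.append(pname)
        gene.part_names = part_names  # type: ignore[attr-defined]

    # ---- support and prediction splitting --------------------------------
    for gene in genes:
        gene.supported = rng.random() < params.transcript_support_fraction
        gene.n_copies = max(1, int(rng.poisson(params.redundancy))) if gene.supported else 0
        if (
            gene.cut_intron < 0
            and gene.introns
            and rng.random() < params.prediction_split_rate
        ):
            gene.pred_split_intron = int(rng.integers(0, len(gene.introns)))

    # ---- predictions -----------------------------------------------------
    predictions: list[GenePrediction] = []
    truth_loci: list[TruthLocus] = []
    domain_pool = [f"SYN{k:04d}" for k in range(40)]
    domain_rows: list[tuple[str, str]] = []

    for gene in genes:
        mapped = gene.mapped_exons  # type: ignore[attr-defined]
        groups: list[list[tuple[str, int, int]]] = []
        if gene.cut_intron >= 0:
            for pname in gene.part_names:  # type: ignore[attr-defined]
                groups.append([m for m in mapped if m[0] == pname])
        elif gene.pred_split_intron >= 0:
            j = gene.pred_split_intron
            groups = [mapped[: j + 1], mapped[j + 1 :]]
        else:
            groups = [mapped]
        pred_ids = []
        for k, grp_exons in enumerate(groups):
            pid = gene.gene_id if len(groups) == 1 else f"{gene.gene_id}.p{k}"
            pred_ids.append(pid)
            predictions.append(
                GenePrediction(
                    gene_id=pid,
                    exons=[
                        GenomicInterval(pn, s, e, gene.strand) for pn, s, e in grp_exons
                    ],
                )
            )
        # domain annotation: 0-3 synthetic domains per gene, carried by its
        # first prediction (InterProScan-style gene-level hits)
        for _ in range(int(rng.integers(0, 4))):
            domain_rows.append(
                (pred_ids[0], domain_pool[int(rng.integers(0, len(domain_pool)))])
            )

        # truth spans per scaffold piece
        parts: list[tuple[str, int, int]] = []
        for pname in gene.part_names:  # type: ignore[attr-defined]
            exs = [m for m in mapped if m[0] == pname]
            parts.append((pname, min(s for _, s, _ in exs), max(e for _, _, e in exs)))
        truth_loci.append(
            TruthLocus(
                locus_id=f"true_{gene.index:04d}",
                parts=parts,
                prediction_ids=pred_ids,
                transcript_ids=[f"t{gene.index:04d}_{c}" for c in range(gene.n_copies)],
            )
        )

    # ---- transcripts and alignments --------------------------------------
    transcripts: dict[str, str] = {}
    alignments: list[TranscriptAlignment] = []
    for gene in genes:
        if not gene.supported:
            continue
        base = gene.transcript_seq
        mapped = gene.mapped_exons  # type: ignore[attr-defined]
        # query offsets of each exon in the (forward-concatenated) transcript
        offsets = []
        q = 0
        for seq in gene.exon_seqs:
            offsets.append(q)
            q += len(seq)
        for c in range(gene.n_copies):
            tid = f"t{gene.index:04d}_{c}"
            if c == 0:
                seq, mut_idx, trim = base, np.empty(0, dtype=int), 0
            else:
                arr = np.frombuffer(base.encode(), dtype=np.uint8).copy()
                mut_mask = rng.random(len(arr)) < params.divergence
                mut_idx = np.flatnonzero(mut_mask)
                for pos in mut_idx:
                    choices = [b for b in b"ACGT" if b != arr[pos]]
                    arr[pos] = choices[int(rng.integers(0, 3))]
                # 1-3 bp end-trim keeps the undiverged original strictly longest
                # without pushing global identity below the clustering threshold
                trim = int(rng.integers(1, 4))
                trim = min(trim, max(1, len(base) // 5))
                seq = arr.tobytes().decode()[: len(base) - trim]
            transcripts[tid] = seq
            qlen = len(seq)
            # one PSL row per scaffold piece the gene's exons land on
            for pname in gene.part_names:  # type: ignore[attr-defined]
                blocks: list[GenomicInterval] = []
                matches = 0
                for (pn, s, e), off in zip(mapped, offsets):
                    if pn != pname:
                        continue
                    q_start, q_end = off, off + (e - s)
                    if q_start >= qlen:
                        continue  # exon fully trimmed away (cannot happen: trim < min exon)
                    q_end_eff = min(q_end, qlen)
                    e_eff = s + (q_end_eff - q_start)
                    n_mut = int(
                        np.searchsorted(mut_idx, q_end_eff) - np.searchsorted(mut_idx, q_start)
                    )
                    blocks.append(GenomicInterval(pname, s, e_eff, gene.strand))
                    matches += (q_end_eff - q_start) - n_mut
                if blocks:
                    alignments.append(
                        TranscriptAlignment(
                            transcript_id=tid,
                            scaffold_id=pname,
                            blocks=blocks,
                            query_length=qlen,
                            matches=max(1, matches),
                            strand=gene.strand,
                        )
                    )

    # ---- emit -------------------------------------------------------------
    write_fasta(genome, out / "genome.fasta")
    write_gff3(predictions, out / "predictions.gff3")
    write_fasta(transcripts, out / "transcripts.fasta")
    write_psl(alignments, out / "alignments.psl")
    with open(out / "domains.tsv", "w") as fh:
        fh.write("gene_id\tdomain_id\n")
        for gid, dom in domain_rows:
            fh.write(f"{gid}\t{dom}\n")
    truth = TruthTable(truth_loci)
    truth.write_tsv(out / "truth.tsv")
    with open(out / "params.json", "w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


def resample_support(truth: TruthTable, fraction: float, seed: int) -> TruthTable:
    """A truth variant with a random transcript subset withheld.

    Transcripts are enumerated in sorted-id order and kept where a single
    uniform draw from ``numpy.random.default_rng(seed)`` falls below
    ``fraction``; deterministic under the seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    all_txs = truth.all_transcript_ids()
    rng = np.random.default_rng(seed)
    keep_mask = rng.random(len(all_txs)) < fraction
    kept = {t for t, k in zip(all_txs, keep_mask) if k}
    return TruthTable(
        [
            TruthLocus(
                locus_id=lo.locus_id,
                parts=list(lo.parts),
                prediction_ids=list(lo.prediction_ids),
                transcript_ids=[t for t in lo.transcript_ids if t in kept],
            )
            for lo in truth.loci
        ]
    )


def recovery_fraction(
    truth: TruthTable,
    loci: list[GeneLocus],
    transcript_subset: set[str] | None = None,
) -> float:
    """Fraction of truth loci recovered exactly: some called locus has
    precisely the truth locus's predictions and transcripts as members.

    ``transcript_subset`` restricts the expected transcript members (e.g.
    to cluster representatives when the pipeline maps only those). A truth
    locus fragmented across scaffolds can never match a single called
    locus and counts as missed — the documented limitation of a method
    that never joins loci across scaffold gaps.
    """
    called = {
        (frozenset(lo.prediction_ids), frozenset(lo.transcript_ids)) for lo in loci
    }
    n_hit = 0
    for lo in truth.loci:
        txs = set(lo.transcript_ids)
        if transcript_subset is not None:
            txs &= transcript_subset
        if (frozenset(lo.prediction_ids), frozenset(txs)) in called:
            n_hit += 1
    return n_hit / len(truth.loci) if truth.loci else float("nan")


def random_domain_table(
    genome_id: str,
    n_genes: int,
    rng: np.random.Generator,
    pool: list[str] | None = None,
    mean_domains_per_gene: float = 1.5,
    domain_dropout: float = 0.0,
) -> DomainTable:
    """A synthetic per-genome domain table for census exercises.

    ``domain_dropout`` removes a random subset of the pool entirely from
    this genome, creating shared-but-absent structure between genomes.
    """
    if pool is None:
        pool = [f"SYN{k:04d}" for k in range(40)]
    kept_pool = [d for d in pool if rng.random() >= domain_dropout]
    if not kept_pool:
        kept_pool = [pool[0]]
    hits = []
    for i in range(n_genes):
        for _ in range(int(rng.poisson(mean_domains_per_gene))):
            hits.append((f"{genome_id}_g{i:04d}", kept_pool[int(rng.integers(0, len(kept_pool)))]))
    return DomainTable(genome_id=genome_id, hits=hits)
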