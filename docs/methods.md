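# Methods

## Problem setting

Fragmented assemblies of repeat-rich genomes (the motivating case is a
slime-mould genome whose scaffolds are interrupted by long di-/tri-/
tetranucleotide repeat runs) defeat ab initio gene prediction in a
characteristic way: contiguity breaks inside genes, and one real gene is
emitted as several partial models. Transcript evidence corrects this: a
transcript whose spliced alignment spans two partial predictions
demonstrates they belong to one transcription unit. `locusfuse` makes that
consolidation explicit and testable. The package is organised as a library
(`src/locusfuse/`) with numbered analysis drivers (`analysis/`) and a CLI
on top; all computation lives in the library so tests and the acceptance
script exercise the same code paths.

## Coordinate model

All intervals are 0-based half-open on named scaffolds. GFF3 (1-based
closed) is converted at the I/O boundary (start−1 on read, +1 on write);
PSL is natively 0-based half-open and passes through unchanged. The gap
between two intervals is the count of bases strictly between them (0 for
overlapping or abutting intervals); "within 50 bases" is the strict
comparison `gap < 50`. Strand is carried everywhere but ignored by the
fusion rules by default — the consolidation rules are positional, and
requiring strand agreement would be a stronger assumption than the method
needs; a strand-aware mode restricts edges to compatible strands for users
who want it.

## Reference-transcriptome clustering

Greedy centroid clustering: transcripts sorted by descending length (ties
on ascending id); each joins the first existing cluster whose
*representative* reaches the identity threshold, else founds a cluster.
Because processing is longest-first, every representative is its cluster's
longest member by construction. Identity is computed from a global
Needleman–Wunsch alignment (match +1, mismatch −1, linear gap −2,
configurable) as matched columns / total columns, with `N` matching
nothing; the argument order is canonicalized before aligning so the metric
is exactly symmetric even when co-optimal alignments differ. The default
threshold is 0.97, a standard transcript-collapse setting; no published
value exists for this step, so it is a config knob and the tests sweep it.

Two prefilters skip alignments without changing the partition: a length
ratio bound (identity can never exceed min/max length) and, only at
thresholds ≥ 0.95, a shared-12-mer requirement (an alignment at ≥ 95%
identity over ≥ 24 nt forces a conserved 12-mer run). Both are safe
optimizations, not approximations.

## Locus fusion

A per-scaffold graph with four edge rules:

1. *covers*: any alignment block of transcript T overlaps prediction P's
   span by ≥ `min_cover_bp` (default 1 — "covered or partially covered"
   is read as any overlap, not containment);
2. *transcript overlap*: two transcript spans overlap ≥ 1 bp (overlapping
   reference transcripts define one locus);
3. *prediction vicinity*: gap(P, Q) < 50 and at least one of P, Q has a
   rule-1 edge — uncovered prediction pairs never fuse by proximity alone;
4. *transcript vicinity*: 0 < gap(P, T) < 50. This rule is the negation
   of the independence condition ("no transcript coverage **and** no
   transcript in the near vicinity"): a prediction with a transcript
   within 50 bp is by that wording not independent, so it joins the
   transcript's component. Because it is inferred rather than stated as a
   fusion rule, it is prominently toggleable (`transcript_vicinity_rule`).

Connected components (union–find via networkx) are the gene loci; isolated
predictions become singleton unsupported loci, isolated transcripts
singleton supported loci. Components are sorted by (scaffold, span start,
span end) and numbered, making locus ids deterministic and locus calling
permutation-invariant. Loci never span scaffolds: no coordinate system
joins scaffold parts in a fragmented assembly, so a gene cut by an
assembly gap yields one locus per part (a documented limitation, mirrored
by the generator). Protein length for the "longer than 40 aa" accounting
is `coding_length_nt // 3`, ignoring stop codons — the filter needs only
an approximate length. The unsupported count is reported both unfiltered
and with the > 40 aa filter, since both accountings are in common use.

## Intron confirmation

Inter-block gaps of spliced alignments ≥ `min_intron_bp` (default 20 bp,
separating introns from alignment indels; the upstream aligner's gap
handling is not specified, so this is a knob) are the aligned intron set,
deduplicated on coordinates. A predicted intron is confirmed iff an
aligned intron matches exactly; a `slack_bp` option (default 0) tolerates
boundary wobble for noisy alignments. Exact matching is the strongest
reading of "confirmed by transcript data" and makes confirmation monotone
in evidence. Per-locus intron rates are reported with both denominators
(all loci / supported loci); medians use the lower-median convention for
even counts.

## Domain census

Per-genome hit tables are multisets of (gene, domain). The census reports
total hits and distinct domains per genome; shared-but-absent sets
(domains(A) ∩ domains(B)) \ domains(C); and enrichment of a focal genome:
`count_focal / (1 + max other count) ≥ fold_threshold` (default 3). The
+1 pseudocount keeps domains absent elsewhere finite; no published fold
threshold exists for this comparison, so 3× is the package's documented
choice. Domain→locus queries map gene-level hits to loci through locus
membership, counting each locus once however many member genes carry the
domain.

## Synthetic data

The generator emits a genome FASTA, predictions GFF3, transcripts FASTA,
alignments PSL, a domain table and a truth TSV, deterministically under a
seed. Defaults are the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| `transcript_support_fraction` | 0.5 | half the loci carry transcript evidence |
| `intron_length_log_median` | 231 bp | reported confirmed-intron median; log-normal, σ = 0.75 |
| `introns_per_gene_mean` | 9 | Poisson; supported-gene intron rate well above 9 motivates the high default |
| `exon_length_mean` | 126 nt | ~10 exons × 126 nt ≈ 1.26 kb mean transcript, the reference-transcriptome scale |
| `redundancy` / `divergence` | 2 / 0.01 | redundant, slightly divergent copies so clustering is exercised; the undiverged original is kept 1–3 nt longer than its copies so the longest-member rule picks it |
| `prediction_split_rate` | 0.05 | moderate over-splitting; an unsupported split is *by design* unrecoverable (the method only rejoins with evidence), so the default split level is what a mostly-recoverable demo presumes |
| `scaffold_split_rate` | 0.01 | occasional mid-gene assembly breaks; split genes land on renamed scaffold parts and can never be rejoined (see limitation above) |
| `spacer_length` | 150 bp | tandem di-/tri-nucleotide runs ("ATAT…", "CAGCAG…") between genes, echoing the repeat classes that fragment the real assembly |

Alignments are emitted from truth rather than recomputed by an aligner:
the method under study begins downstream of the mapping step, and emitting
truth keeps runs fast, download-free and byte-deterministic. Intron cores
are low-complexity tandem runs, echoing repeat-rich introns. A note on the
intron location parameter: the source material quotes both a ~100 bp mean
and a 231 bp median for introns (mutually inconsistent for any right-skewed
law); the generator exposes the median and σ separately rather than
resolving that discrepancy.

What the generator does **not** model: realistic base composition,
sequencing error, alternative splicing, genes on both strands of the same
interval, chimeric transcripts, and alignment noise (block boundaries are
exact). Passing tests therefore demonstrate the *logic* of consolidation —
rule correctness, determinism, monotonicity, exact truth recovery in the
zero-noise limit — not robustness to aligner artefacts on real data.

Scale choices: routine tests use 40–100-locus genomes and the acceptance
checks 100–200 loci with 400–1000 randomized oracle instances; these sizes
give stable statistics (binomial noise on the support fraction ≈ ±0.035 at
n = 200) while keeping any run to seconds.

## Numerical / degenerate-input choices

Empty inputs yield empty graphs and empty locus lists, not errors; empty
intron sets report `None` medians; mean lengths of an empty support class
are NaN. Ties everywhere break lexicographically (cluster founders on id,
locus ids on coordinates, best-alignment selection on matches then target
name and start). `best_alignment_only` (default on) keeps one PSL row per
transcript — each reference transcript maps to the genome once — which for
scaffold-split genes drops the smaller part's alignment, leaving that
fragment unsupported; this mirrors the real pipeline's behaviour at
assembly gaps.

## Known limitations

* Loci are never merged across scaffolds, even when one transcript aligns
  to both parts; the demo's residual (~2–3%) recovery loss is exactly
  these fragments plus unsupported over-splits.
* Greedy clustering is order-dependent by design (longest-first); it
  emulates centroid clustering behaviour but is not a reimplementation of
  any specific tool.
* The enrichment fold and identity threshold are package choices where
  the upstream methodology left the value unstated; both are config knobs.
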