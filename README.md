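# locusfuse

Consolidating ab initio gene predictions with transcript evidence into
**gene loci**, for fragmented, repeat-rich genome assemblies.

Ab initio gene finders over-predict on fragmented assemblies: simple-repeat
runs interrupt scaffolds mid-gene, and a single real gene comes out as two
or more partial models. When a transcriptome is available, the transcripts
are the arbiter — a transcript spanning two partial predictions shows they
are one gene. `locusfuse` implements that consolidation as a tested,
reusable pipeline, together with the statistics built on it (transcript
confirmation of introns, locus accounting, a comparative protein-domain
census) and a synthetic-genome generator with known truth, so every rule
can be validated against ground truth and against brute-force oracles.

## The method

1. **Reference transcriptome.** Raw transcripts are collapsed by greedy
   centroid clustering: processed longest-first, each transcript joins the
   first cluster whose representative aligns at global identity ≥ *t*
   (default 0.97), else founds a new cluster; each cluster is represented
   by its longest member.
2. **Locus fusion.** Predictions and mapped reference transcripts (PSL
   spliced alignments) form a graph, per scaffold: a transcript is linked
   to every prediction any of its aligned blocks touches ("covered or
   partially covered"); overlapping transcripts are linked; two
   predictions less than 50 bases apart are linked if at least one of them
   is covered; a prediction less than 50 bases from a transcript it does
   not touch is linked to it. Connected components are the gene loci.
   Predictions with no coverage and nothing in the vicinity remain
   independent (unsupported) loci.
3. **Intron confirmation.** A predicted intron (gap between consecutive
   exons) is *confirmed* when a gap between consecutive alignment blocks
   matches its genomic coordinates exactly; inter-block gaps under 20 bp
   are treated as alignment indels.
4. **Domain census.** Per-genome (gene, domain) hit tables are compared as
   multisets: totals, distinct-domain counts, domains shared by two
   genomes but absent from a third, enrichment at ≥3× with a +1
   pseudocount, and domain→locus queries (e.g. "how many loci carry a
   kinesin motor domain").

## Worked example

The numbered scripts under `analysis/` run the study end-to-end on a
200-locus synthetic genome (deterministic, seed 0), writing tables under
`results/`:

```sh
python analysis/01_simulate.py
python analysis/02_cluster_transcripts.py
python analysis/03_build_loci.py
python analysis/04_intron_stats.py
python analysis/05_domain_census.py
```

which prints, among other lines:

```
simulated 200 true loci -> results/simulated
  103 supported by >=1 transcript (52%; target 50%)
  209 ab initio predictions (9 surplus from over-splitting)
clustered 199 transcripts into 103 clusters (mean representative length 1317 nt)
fused 209 predictions + 103 reference-transcript alignments into 204 gene loci
  supported: 103; unsupported: 101 (101 longer than 40 aa)
  exact truth-locus recovery: 98.0% of 200
958 of 1847 predicted introns confirmed by transcript data (median confirmed length 221 bp)
  confirmed introns per locus: 4.70 over all 204 loci, 9.30 over the 103 supported loci
```

Reading: redundant transcript copies collapse onto exactly one
representative per supported truth locus (199 → 103); fusion rejoins
over-split predictions wherever a transcript spans the break (209
predictions → 204 loci, 98% of truth loci recovered exactly); and because
only supported loci can have confirmed introns, the per-locus confirmation
rate roughly doubles when the denominator is restricted to supported loci
(4.70 → 9.30).

The same pipeline is available as a CLI (`locusfuse simulate | cluster |
build-loci | intron-stats | domain-census | report | demo`); `locusfuse
demo out/ --seed 42` reproduces a self-contained run with a JSON report.

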