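"""Fusion of gene predictions and mapped reference transcripts into gene loci.

The fusion graph has one node per prediction and per transcript alignment,
per scaffold, with four edge kinds:

  covers          transcript block overlaps a prediction span (>= min_cover_bp)
  tx_overlap      two transcript spans overlap (overlapping reference
                  transcripts define one gene locus)
  pred_vicinity   two predictions < vicinity_bp apart, at least one of
                  them covered by some transcript
  tx_vicinity     a prediction < vicinity_bp from a transcript it does not
                  overlap (a prediction with a transcript in near vicinity
                  is, by the independence rule, not an independent locus)

Connected components of the graph are the gene loci; isolated predictions
are singleton unsupported loci, isolated transcripts singleton supported
loci. Strand is ignored unless strand-aware mode is on; loci never span
scaffolds.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import networkx as nx

from .model import (
    GeneLocus,
    GenePrediction,
    GenomicInterval,
    TranscriptAlignment,
    interval_gap,
    span_hull,
)

log = logging.getLogger(__name__)

DEFAULT_VICINITY_BP = 50
DEFAULT_MIN_PROTEIN_AA = 40

PRED = "pred"
TX = "tx"


def _strand_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def build_fusion_graph(
    predictions: list[GenePrediction],
    alignments: list[TranscriptAlignment],
    vicinity_bp: int = DEFAULT_VICINITY_BP,
    min_cover_bp: int = 1,
    strand_aware: bool = False,
    transcript_vicinity_rule: bool = True,
) -> nx.Graph:
    """Build the typed fusion graph over predictions and transcripts.

    Edge rules (same scaffold only):
      (i)   covers: any transcript block overlaps the prediction span by
            >= min_cover_bp (partial coverage suffices);
      (ii)  tx_overlap: transcript spans overlap by >= 1 bp;
      (iii) pred_vicinity: interval_gap < vicinity_bp AND at least one of
            the two predictions has a covers edge;
      (iv)  tx_vicinity: 0 < interval_gap(prediction, transcript) <
            vicinity_bp (off by default via transcript_vicinity_rule=False).
    """
    if vicinity_bp < 0:
        raise ValueError("vicinity_bp must be >= 0")
    g = nx.Graph()
    for p in predictions:
        g.add_node((PRED, p.gene_id), obj=p)
    for a in alignments:
        g.add_node((TX, a.transcript_id), obj=a)

    preds_by_scaffold: dict[str, list[GenePrediction]] = defaultdict(list)
    txs_by_scaffold: dict[str, list[TranscriptAlignment]] = defaultdict(list)
    for p in predictions:
        preds_by_scaffold[p.scaffold_id].append(p)
    for a in alignments:
        txs_by_scaffold[a.scaffold_id].append(a)

    n_cover = n_txov = n_pvic = n_tvic = 0
    for scaffold in sorted(set(preds_by_scaffold) | set(txs_by_scaffold)):
        preds = sorted(preds_by_scaffold[scaffold], key=lambda p: (p.span.start, p.span.end))
        txs = sorted(txs_by_scaffold[scaffold], key=lambda a: (a.span.start, a.span.end))

        # (i) covers: transcript block vs prediction span
        covered: set[str] = set()
        for a in txs:
            for p in preds:
                if strand_aware and not _strand_compatible(p.strand, a.strand):
                    continue
                if p.span.start >= a.span.end or a.span.start >= p.span.end:
                    continue
                if any(b.overlap_length(p.span) >= min_cover_bp for b in a.blocks):
                    g.add_edge((TX, a.transcript_id), (PRED, p.gene_id), kind="covers")
                    covered.add(p.gene_id)
                    n_cover += 1

        # (ii) transcript-transcript span overlap (sweep over sorted spans)
        for i, a in enumerate(txs):
            for b in txs[i + 1 :]:
                if b.span.start >= a.span.end:
                    break
                if strand_aware and not _strand_compatible(a.strand, b.strand):
                    continue
                g.add_edge((TX, a.transcript_id), (TX, b.transcript_id), kind="tx_overlap")
                n_txov += 1

        # (iii) prediction-prediction vicinity, guarded by coverage
        for i, p in enumerate(preds):
            for q in preds[i + 1 :]:
                if q.span.start >= p.span.end + vicinity_bp:
                    break
                if strand_aware and not _strand_compatible(p.strand, q.strand):
                    continue
                if interval_gap(p.span, q.span) < vicinity_bp and (
                    p.gene_id in covered or q.gene_id in covered
                ):
                    g.add_edge((PRED, p.gene_id), (PRED, q.gene_id), kind="pred_vicinity")
                    n_pvic += 1

        # (iv) prediction near (but not overlapping) a transcript
        if transcript_vicinity_rule:
            for p in preds:
                for a in txs:
                    if strand_aware and not _strand_compatible(p.strand, a.strand):
                        continue
                    gap = interval_gap(p.span, a.span)
                    if 0 < gap < vicinity_bp:
                        g.add_edge(
                            (PRED, p.gene_id), (TX, a.transcript_id), kind="tx_vicinity"
                        )
                        n_tvic += 1

    log.info(
        "fusion graph: %d predictions, %d transcripts; edges: %d covers, "
        "%d tx-overlap, %d pred-vicinity, %d tx-vicinity",
        len(predictions), len(alignments), n_cover, n_txov, n_pvic, n_tvic,
    )
    return g


def call_loci(graph: nx.Graph) -> list[GeneLocus]:
    """One gene locus per connected component of the fusion graph.

    Components are ordered by (scaffold, span start, span end) and assigned
    deterministic ids. Predictions with no transcript coverage and nothing
    in the vicinity come out as singleton unsupported loci.
    """
    components = []
    for comp in nx.connected_components(graph):
        preds: list[GenePrediction] = []
        txs: list[TranscriptAlignment] = []
        for node in comp:
            obj = graph.nodes[node]["obj"]
            if node[0] == PRED:
                preds.append(obj)
            else:
                txs.append(obj)
        intervals: list[GenomicInterval] = [p.span for p in preds] + [a.span for a in txs]
        scaffolds = {iv.scaffold_id for iv in intervals}
        if len(scaffolds) != 1:  # edges are same-scaffold only
            raise AssertionError(f"component spans scaffolds {sorted(scaffolds)}")
        span = span_hull([GenomicInterval(iv.scaffold_id, iv.start, iv.end) for iv in intervals])
        components.append((span, preds, txs))

    components.sort(key=lambda c: (c[0].scaffold_id, c[0].start, c[0].end))
    loci = []
    for i, (span, preds, txs) in enumerate(components):
        loci.append(
            GeneLocus(
                locus_id=f"locus_{i:06d}",
                scaffold_id=span.scaffold_id,
                span=span,
                prediction_ids=sorted(p.gene_id for p in preds),
                transcript_ids=sorted(a.transcript_id for a in txs),
                max_coding_length_aa=max((p.coding_length_aa for p in preds), default=0),
            )
        )
    log.info("called %d loci (%d supported)", len(loci), sum(lo.supported for lo in loci))
    return loci


def build_loci(
    predictions: list[GenePrediction],
    alignments: list[TranscriptAlignment],
    vicinity_bp: int = DEFAULT_VICINITY_BP,
    min_cover_bp: int = 1,
    strand_aware: bool = False,
    transcript_vicinity_rule: bool = True,
) -> list[GeneLocus]:
    """Convenience composition of build_fusion_graph and call_loci."""
    graph = build_fusion_graph(
        predictions,
        alignments,
        vicinity_bp=vicinity_bp,
        min_cover_bp=min_cover_bp,
        strand_aware=strand_aware,
        transcript_vicinity_rule=transcript_vicinity_rule,
    )
    return call_loci(graph)


def support_summary(
    loci: list[GeneLocus], min_protein_aa: int = DEFAULT_MIN_PROTEIN_AA
) -> dict:
    """Locus accounting: totals, support split, and mean span lengths.

    ``n_unsupported_min_aa`` counts unsupported loci whose longest member
    prediction exceeds min_protein_aa amino acids (strictly longer-than,
    the "longer than 40 aa" convention).
    """
    supported = [lo for lo in loci if lo.supported]
    unsupported = [lo for lo in loci if not lo.supported]

    def _mean_len(group: list[GeneLocus]) -> float:
        return sum(lo.length for lo in group) / len(group) if group else float("nan")

    return {
        "n_loci_total": len(loci),
        "n_supported": len(supported),
        "n_unsupported_all": len(unsupported),
        "n_unsupported_min_aa": sum(
            1 for lo in unsupported if lo.max_coding_length_aa > min_protein_aa
        ),
        "mean_length_supported": _mean_len(supported),
        "mean_length_unsupported": _mean_len(unsupported),
    }
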