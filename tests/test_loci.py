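"""Fusion-graph construction and locus calling against brute-force oracles
and the generator's truth tables."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locusfuse import io_formats as iof
from locusfuse.loci import build_fusion_graph, build_loci, call_loci, support_summary
from locusfuse.model import (
    GenePrediction,
    GenomicInterval,
    TranscriptAlignment,
    interval_gap,
)
from locusfuse.synthetic import recovery_fraction, resample_support
from conftest import consolidate
from oracles import brute_force_components, positional_gap, random_fusion_instance


def _pred(gene_id, scaf, start, end, strand="."):
    return GenePrediction(gene_id=gene_id, exons=[GenomicInterval(scaf, start, end, strand)])


def _tx(tx_id, scaf, blocks, strand="+"):
    ivs = [GenomicInterval(scaf, s, e, strand) for s, e in blocks]
    total = sum(e - s for s, e in blocks)
    return TranscriptAlignment(
        transcript_id=tx_id, scaffold_id=scaf, blocks=ivs,
        query_length=total, matches=total, strand=strand,
    )


def _memberships(loci):
    return {frozenset([("pred", p) for p in lo.prediction_ids] + [("tx", t) for t in lo.transcript_ids]) for lo in loci}


class TestIntervalGap:
    def test_abutting_is_zero(self):
        assert interval_gap(GenomicInterval("s", 0, 100), GenomicInterval("s", 100, 200)) == 0

    def test_forty_nine_bases_between(self):
        assert interval_gap(GenomicInterval("s", 0, 100), GenomicInterval("s", 149, 200)) == 49

    def test_overlap_is_zero(self):
        assert interval_gap(GenomicInterval("s", 0, 100), GenomicInterval("s", 50, 200)) == 0

    def test_different_scaffolds_raise(self):
        with pytest.raises(ValueError, match="scaffold"):
            interval_gap(GenomicInterval("a", 0, 10), GenomicInterval("b", 0, 10))

    def test_matches_positional_counting_on_random_pairs(self):
        rng = np.random.default_rng(100)
        for _ in range(1000):
            a0, b0 = rng.integers(0, 500, size=2)
            a = GenomicInterval("s", int(a0), int(a0) + int(rng.integers(1, 120)))
            b = GenomicInterval("s", int(b0), int(b0) + int(rng.integers(1, 120)))
            assert interval_gap(a, b) == positional_gap(a.start, a.end, b.start, b.end)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 300), st.integers(1, 80), st.integers(0, 300), st.integers(1, 80))
    def test_symmetric_and_nonnegative(self, s1, l1, s2, l2):
        a = GenomicInterval("s", s1, s1 + l1)
        b = GenomicInterval("s", s2, s2 + l2)
        assert interval_gap(a, b) == interval_gap(b, a) >= 0


class TestFusionRules:
    def test_shared_transcript_fuses_two_predictions(self):
        preds = [_pred("p1", "s", 100, 200), _pred("p2", "s", 500, 600)]
        txs = [_tx("t1", "s", [(150, 180), (520, 580)])]
        loci = build_loci(preds, txs)
        assert len(loci) == 1
        assert loci[0].prediction_ids == ["p1", "p2"]
        assert loci[0].supported

    def test_uncovered_near_predictions_stay_apart(self):
        # 10 bp apart but neither covered: the vicinity rule requires coverage
        preds = [_pred("p1", "s", 100, 200), _pred("p2", "s", 210, 300)]
        loci = build_loci(preds, [])
        assert len(loci) == 2
        assert not any(lo.supported for lo in loci)

    def test_covered_near_predictions_fuse(self):
        preds = [_pred("p1", "s", 100, 200), _pred("p2", "s", 210, 300)]
        txs = [_tx("t1", "s", [(120, 190)])]  # covers p1 only
        loci = build_loci(preds, txs)
        assert len(loci) == 1

    def test_vicinity_threshold_is_strict(self):
        txs = [_tx("t1", "s", [(120, 190)])]
        near = [_pred("p1", "s", 100, 200), _pred("p2", "s", 249, 300)]  # gap 49
        far = [_pred("p1", "s", 100, 200), _pred("p2", "s", 250, 300)]  # gap 50
        assert len(build_loci(near, txs)) == 1
        assert len(build_loci(far, txs)) == 2

    def test_overlapping_transcripts_define_one_locus(self):
        txs = [_tx("t1", "s", [(100, 300)]), _tx("t2", "s", [(250, 500)])]
        loci = build_loci([], txs)
        assert len(loci) == 1 and loci[0].supported

    def test_isolated_transcript_is_singleton_supported_locus(self):
        loci = build_loci([], [_tx("t1", "s", [(0, 100)])])
        assert len(loci) == 1 and loci[0].supported and not loci[0].prediction_ids

    def test_isolated_prediction_is_singleton_unsupported_locus(self):
        loci = build_loci([_pred("p1", "s", 0, 90)], [])
        assert len(loci) == 1 and not loci[0].supported

    def test_empty_inputs_give_empty_graph(self):
        assert call_loci(build_fusion_graph([], [])) == []

    def test_transcript_vicinity_rule_toggles(self):
        # prediction 30 bp downstream of a transcript it does not touch
        preds = [_pred("p1", "s", 530, 700)]
        txs = [_tx("t1", "s", [(100, 500)])]
        assert len(build_loci(preds, txs, transcript_vicinity_rule=True)) == 1
        assert len(build_loci(preds, txs, transcript_vicinity_rule=False)) == 2

    def test_prediction_inside_transcript_intron_not_fused_by_vicinity(self):
        # span overlap but no block overlap and gap 0: neither rule fires
        preds = [_pred("p1", "s", 200, 280)]
        txs = [_tx("t1", "s", [(100, 150), (400, 500)])]
        assert len(build_loci(preds, txs)) == 2

    def test_strand_aware_mode_blocks_opposite_strands(self):
        preds = [_pred("p1", "s", 100, 200, strand="-")]
        txs = [_tx("t1", "s", [(150, 180)], strand="+")]
        assert len(build_loci(preds, txs, strand_aware=False)) == 1
        assert len(build_loci(preds, txs, strand_aware=True)) == 2

    def test_loci_never_span_scaffolds(self):
        preds = [_pred("p1", "sA", 100, 200), _pred("p2", "sB", 100, 200)]
        txs = [_tx("t1", "sA", [(150, 180)])]
        loci = build_loci(preds, txs)
        assert len(loci) == 2


class TestOracleEquivalence:
    def test_components_match_brute_force(self):
        rng = np.random.default_rng(2024)
        for trial in range(150):
            preds, txs = random_fusion_instance(rng)
            graph = build_fusion_graph(preds, txs)
            got = {frozenset(c) for c in nx.connected_components(graph)}
            want = brute_force_components(preds, txs)
            assert got == want, f"trial {trial}"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(77)
        preds, txs = random_fusion_instance(rng, max_preds=30, max_txs=20)
        base = _memberships(build_loci(preds, txs))
        for _ in range(5):
            p2 = list(preds)
            t2 = list(txs)
            rng.shuffle(p2)
            rng.shuffle(t2)
            assert _memberships(build_loci(p2, t2)) == base

    def test_every_input_in_exactly_one_locus(self):
        rng = np.random.default_rng(55)
        preds, txs = random_fusion_instance(rng)
        loci = build_loci(preds, txs)
        all_preds = [p for lo in loci for p in lo.prediction_ids]
        all_txs = [t for lo in loci for t in lo.transcript_ids]
        assert sorted(all_preds) == sorted(p.gene_id for p in preds)
        assert sorted(all_txs) == sorted(a.transcript_id for a in txs)


class TestTruthRecovery:
    def test_zero_noise_recovers_truth_exactly(self, clean_dataset, clean_consolidation):
        _, truth, _ = clean_dataset
        _, _, loci, reps = clean_consolidation
        assert len(loci) == len(truth.loci)
        assert recovery_fraction(truth, loci, transcript_subset=reps) == 1.0

    def test_forced_splitting_with_full_support_rejoins(self, tmp_path):
        from locusfuse.synthetic import SimulationParams, generate

        params = SimulationParams(
            n_true_loci=30, seed=3, prediction_split_rate=1.0,
            scaffold_split_rate=0.0, transcript_support_fraction=1.0,
            redundancy=1.0, divergence=0.0,
        )
        truth = generate(params, tmp_path / "sim")
        preds, alns, loci, reps = consolidate(tmp_path / "sim")
        # every multi-intron gene yielded >= 2 predictions on one truth locus
        multi = [lo for lo in truth.loci if len(lo.prediction_ids) >= 2]
        assert multi
        assert len(preds) > len(truth.loci)
        # and the shared transcript fuses them back into one locus each
        assert len(loci) == len(truth.loci)
        assert recovery_fraction(truth, loci, transcript_subset=reps) == 1.0


class TestMonotonicity:
    def test_removing_transcripts_never_merges_or_supports(self, default_dataset):
        outdir, truth, _ = default_dataset
        preds = iof.read_gff3(outdir / "predictions.gff3")
        alns = iof.read_psl(outdir / "alignments.psl")
        prev_count = None
        prev_supported_sets = None
        for fraction in (1.0, 0.7, 0.4, 0.0):
            sub = resample_support(truth, fraction, seed=9)
            kept = set(sub.all_transcript_ids())
            loci = build_loci(preds, [a for a in alns if a.transcript_id in kept])
            supported_preds = {
                p for lo in loci if lo.supported for p in lo.prediction_ids
            }
            if prev_count is not None:
                assert len(loci) >= prev_count
                assert supported_preds <= prev_supported_sets
            prev_count = len(loci)
            prev_supported_sets = supported_preds

    def test_vicinity_sweep_monotone(self, default_dataset):
        outdir, _, _ = default_dataset
        preds = iof.read_gff3(outdir / "predictions.gff3")
        alns = iof.read_psl(outdir / "alignments.psl")
        counts = [
            len(build_loci(preds, alns, vicinity_bp=v)) for v in (0, 50, 500, 5000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSupportSummary:
    def test_threshold_boundary(self):
        supported = build_loci(
            [_pred("p1", "s", 0, 300)], [_tx("t1", "s", [(0, 300)])]
        )
        short = GenePrediction(
            gene_id="p2", exons=[GenomicInterval("s2", 0, 117)]
        )  # 117 nt -> 39 aa
        loci = supported + build_loci([short], [])
        summary = support_summary(loci, min_protein_aa=40)
        assert summary["n_unsupported_all"] == 1
        assert summary["n_unsupported_min_aa"] == 0

    def test_partition_identity(self, default_consolidation):
        _, _, loci, _ = default_consolidation
        s = support_summary(loci)
        assert s["n_supported"] + s["n_unsupported_all"] == s["n_loci_total"]

    def test_empty_groups_give_nan_means(self):
        loci = build_loci([_pred("p1", "s", 0, 90)], [])
        s = support_summary(loci)
        assert math.isnan(s["mean_length_supported"])

    def test_oversplit_unsupported_loci_are_shorter(self, tmp_path):
        """Unsupported loci are prediction fragments while supported loci
        are rejoined to full gene extent, so their mean lengths separate."""
        from locusfuse.synthetic import SimulationParams, generate

        params = SimulationParams(
            n_true_loci=60, seed=13, prediction_split_rate=0.8,
            transcript_support_fraction=0.5, scaffold_split_rate=0.0,
        )
        generate(params, tmp_path / "sim")
        _, _, loci, _ = consolidate(tmp_path / "sim")
        s = support_summary(loci)
        assert s["mean_length_unsupported"] < s["mean_length_supported"]
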