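"""Synthetic-data generators: determinism, planted truth, parameter validation."""

import numpy as np
import pandas as pd
import pytest

from mircargo.diffexpr import differential_expression, filter_low_tpm
from mircargo.enrich import ora
from mircargo.qpcr import call_expressed, call_highly_expressed
from mircargo.simulate import (
    gen_ct_card,
    gen_expression_matrix,
    gen_genesets,
    gen_survival,
    gen_target_dbs,
    gen_transcript_gene_map,
)
from mircargo.targets import TargetPredictionSet, consensus_targets


class TestGenExpressionMatrix:
    def test_shapes_and_truth_counts_follow_parameters(self):
        matrix, truth = gen_expression_matrix(1000, 3, 0.1, 2.0, 0.3, seed=1)
        assert matrix.tpm.shape == (1000, 6)
        assert len(truth.de_transcripts) == 100
        assert set(truth.de_direction.values()) <= {"up", "down"}
        assert (matrix.tpm.to_numpy() > 0).all()
        assert sorted(matrix.groups.unique()) == ["control", "treated"]

    def test_same_seed_is_bit_identical(self):
        a, ta = gen_expression_matrix(200, 3, 0.1, 1.0, 0.3, seed=9)
        b, tb = gen_expression_matrix(200, 3, 0.1, 1.0, 0.3, seed=9)
        pd.testing.assert_frame_equal(a.tpm, b.tpm)
        assert ta.de_transcripts == tb.de_transcripts
        c, _ = gen_expression_matrix(200, 3, 0.1, 1.0, 0.3, seed=10)
        assert not a.tpm.equals(c.tpm)

    def test_low_fraction_feeds_the_filter(self):
        matrix, _ = gen_expression_matrix(1000, 3, 0.0, 0.0, 0.3, seed=2,
                                          low_fraction=0.4)
        kept, removed = filter_low_tpm(matrix)
        assert 300 <= len(removed) <= 500  # ~40% planted low

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_expression_matrix(100, 1, 0.1, 1.0, 0.3, seed=0)
        with pytest.raises(ValueError):
            gen_expression_matrix(100, 3, 0.1, float("nan"), 0.3, seed=0)
        with pytest.raises(ValueError):
            gen_expression_matrix(100, 3, 1.5, 1.0, 0.3, seed=0)


class TestGenCtCard:
    def test_calling_recovers_exactly_the_planted_expressed_set(self):
        ids = [f"m{i}" for i in range(20)]
        ev, md, truth = gen_ct_card(ids, 3, 0.5, 23.8, 6.0, 0.3, seed=7)
        assert len(truth.true_expressed_mirnas) == 10
        calls = call_expressed(ev, md)
        called = set(calls.loc[calls["expressed"], "target_id"])
        assert called == set(truth.true_expressed_mirnas)

    def test_high_abundance_planting_matches_the_ct_cutoff(self):
        ids = [f"m{i}" for i in range(30)]
        ev, md, truth = gen_ct_card(ids, 3, 0.6, 23.8, 6.0, 0.1, seed=3,
                                    high_fraction=0.5)
        calls = call_highly_expressed(call_expressed(ev, md), 27.5)
        high = set(calls.loc[calls["highly_expressed"], "target_id"])
        assert high == set(truth.true_high_mirnas)

    def test_near_noiseless_limit_is_clean(self):
        ids = [f"m{i}" for i in range(12)]
        ev, md, truth = gen_ct_card(ids, 3, 0.5, 24.0, 8.0, 1e-6, seed=5)
        calls = call_expressed(ev, md)
        called = set(calls.loc[calls["expressed"], "target_id"])
        assert called == set(truth.true_expressed_mirnas)

    def test_spike_row_present_on_both_cards_at_the_requested_scale(self):
        ev, md, _ = gen_ct_card(["a", "b"], 3, 0.5, 23.852, 6.0, 0.3, seed=1)
        spike_ev = ev.data[ev.data["is_spike_in"] & ~ev.data["is_ntc"]]["ct"]
        assert len(spike_ev) == 3
        assert spike_ev.mean() == pytest.approx(23.852, abs=0.2)
        assert md.data["is_spike_in"].any()

    def test_determinism_and_validation(self):
        a = gen_ct_card(["x", "y"], 2, 0.5, 24.0, 6.0, 0.3, seed=4)[0]
        b = gen_ct_card(["x", "y"], 2, 0.5, 24.0, 6.0, 0.3, seed=4)[0]
        pd.testing.assert_frame_equal(a.data, b.data)
        with pytest.raises(ValueError, match="non-empty"):
            gen_ct_card([], 3, 0.5, 24.0, 6.0, 0.3, seed=0)


class TestGenTargetDbs:
    def test_consensus_equals_planted_pairs_exactly(self):
        genes = [f"G{i}" for i in range(200)]
        mirnas = [f"m{i}" for i in range(8)]
        table, truth = gen_target_dbs(mirnas, genes, 0.05, 0.4, n_dbs=3, seed=6)
        preds = TargetPredictionSet.from_frame(table, ("db1", "db2", "db3"))
        cons = consensus_targets(preds, 2)
        for m in mirnas:
            assert cons[m] == truth.planted_consensus_targets[m]

    def test_zero_overlap_means_empty_consensus(self):
        genes = [f"G{i}" for i in range(100)]
        table, truth = gen_target_dbs(["m1", "m2"], genes, 0.1, 0.0, seed=2)
        preds = TargetPredictionSet.from_frame(table, ("db1", "db2", "db3"))
        cons = consensus_targets(preds, 2)
        assert all(not s for s in cons.values())
        assert all(not s for s in truth.planted_consensus_targets.values())

    def test_zero_density_gives_empty_tables(self):
        table, _ = gen_target_dbs(["m"], ["G1", "G2"], 0.0, 0.0, seed=1)
        assert table.empty

    def test_determinism_and_validation(self):
        genes = [f"G{i}" for i in range(50)]
        a, _ = gen_target_dbs(["m"], genes, 0.1, 0.5, seed=8)
        b, _ = gen_target_dbs(["m"], genes, 0.1, 0.5, seed=8)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            gen_target_dbs(["m"], genes, 0.1, 0.5, n_dbs=1, seed=0)
        with pytest.raises(ValueError):
            gen_target_dbs(["m"], [], 0.1, 0.5, seed=0)


class TestGenGenesets:
    def test_fixed_size_range_forces_every_size(self):
        genes = [f"G{i}" for i in range(50)]
        col, _ = gen_genesets(genes, 10, (5, 5), seed=1)
        assert all(len(s) == 5 for s in col.sets.values())

    def test_planted_sets_are_enriched_for_the_planted_list(self):
        genes = [f"G{i}" for i in range(500)]
        planted = genes[:50]
        col, truth = gen_genesets(genes, 20, (25, 25), planted_list=planted,
                                  n_planted_sets=3, seed=2)
        res = ora(planted, col, genes).set_index("set_name")
        for name in truth.enriched_pathways:
            assert res.loc[name, "p_value"] < 0.05

    def test_stray_planted_genes_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gen_genesets(["a", "b", "c"], 2, (1, 2), planted_list=["zz"],
                         n_planted_sets=1, seed=0)


class TestGenSurvival:
    def test_no_censoring_means_every_event_observed(self):
        cohort, _ = gen_survival(30, 2.0, 0.0, seed=1)
        assert (cohort["event"] == 1).all()

    def test_full_censoring_means_no_events(self):
        cohort, _ = gen_survival(30, 2.0, 1.0, seed=1)
        assert (cohort["event"] == 0).all()

    def test_high_expression_group_fails_faster_on_average(self):
        cohort, _ = gen_survival(400, 4.0, 0.0, seed=3)
        med = cohort["expression"].median()
        high = cohort[cohort["expression"] > med]["time"].mean()
        low = cohort[cohort["expression"] <= med]["time"].mean()
        assert high < low

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError, match=">= 16"):
            gen_survival(10, 1.0, 0.0, seed=0)


class TestGenMapping:
    def test_mapping_covers_most_transcripts_deterministically(self):
        ids = [f"tx{i}" for i in range(200)]
        a = gen_transcript_gene_map(ids, seed=4, unmapped_fraction=0.1)
        b = gen_transcript_gene_map(ids, seed=4, unmapped_fraction=0.1)
        pd.testing.assert_frame_equal(a, b)
        assert 150 <= len(a) <= 200
        assert a["gene_symbol"].str.startswith("GENE").all()


class TestNullCalibration:
    def test_null_generator_gives_nominal_false_positive_rate(self):
        # effect 0: the fraction of p < 0.01 over pooled null matrices
        # should be near the nominal level (Welch at n=3 runs conservative)
        fp = tot = 0
        for s in range(3):
            m, _ = gen_expression_matrix(4000, 3, 0.0, 0.0, 0.3, seed=50 + s,
                                         low_fraction=0.0)
            deg = differential_expression(m)
            fp += int((deg["p_value"] < 0.01).sum())
            tot += len(deg)
        assert 0.002 <= fp / tot <= 0.02
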