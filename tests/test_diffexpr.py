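"""Low-TPM filtering, Welch differential expression, DRG calling, gene collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircargo.diffexpr import (
    classify_drgs,
    collapse_to_genes,
    differential_expression,
    filter_low_tpm,
)
from mircargo.simulate import gen_expression_matrix

from conftest import make_matrix


class TestFilterLowTpm:
    def test_transcript_above_floor_everywhere_is_retained(self):
        m = make_matrix([[12, 15, 20, 11, 13, 14]])
        result = filter_low_tpm(m)
        assert list(result.matrix.tpm.index) == ["tx0"]
        assert len(result.removed) == 0

    def test_group_scope_controls_removal_of_one_sided_dropout(self):
        # all-zero in controls only: excluded under either_group, kept under both
        m = make_matrix([[0, 0, 0, 50, 60, 70]])
        assert len(filter_low_tpm(m, scope="either_group").matrix.tpm) == 0
        assert len(filter_low_tpm(m, scope="both_groups").matrix.tpm) == 1

    def test_threshold_is_strict(self):
        # exactly 10 does not count as low
        m = make_matrix([[10, 10, 10, 10, 10, 10]])
        assert len(filter_low_tpm(m, threshold=10).matrix.tpm) == 1

    @pytest.mark.parametrize("scope", ["either_group", "both_groups"])
    def test_matches_row_by_row_oracle(self, rng, scope):
        vals = rng.gamma(2.0, 10.0, size=(100, 6))
        m = make_matrix(vals)
        kept = set(filter_low_tpm(m, scope=scope).matrix.tpm.index)
        expected = set()
        for i, row in enumerate(vals):
            low_c = sum(v < 10 for v in row[:3]) >= 2
            low_t = sum(v < 10 for v in row[3:]) >= 2
            remove = (low_c or low_t) if scope == "either_group" else (low_c and low_t)
            if not remove:
                expected.add(f"tx{i}")
        assert kept == expected

    def test_idempotent(self, rng):
        m = make_matrix(rng.gamma(2.0, 10.0, size=(50, 6)))
        once = filter_low_tpm(m).matrix
        twice = filter_low_tpm(once).matrix
        pd.testing.assert_frame_equal(once.tpm, twice.tpm)

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError, match="scope"):
            filter_low_tpm(make_matrix([[1] * 6]), scope="any_group")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            filter_low_tpm(make_matrix([[1, 2]]), min_low_samples=2)


class TestDifferentialExpression:
    def test_identical_groups_are_null(self):
        m = make_matrix([[5, 7, 9, 5, 7, 9], [100, 200, 300, 100, 200, 300]])
        deg = differential_expression(m)
        assert np.allclose(deg["log_fc"], 0)
        calls = classify_drgs(deg)
        assert (calls.table["call"] == "ns").all()

    def test_zero_variance_in_both_groups_yields_p_one(self):
        m = make_matrix([[4, 4, 4, 8, 8, 8]])
        deg = differential_expression(m)
        assert deg["p_value"].iloc[0] == 1.0
        assert deg["log_fc"].iloc[0] != 0  # fold change still reported

    def test_log_fc_is_log2_of_fold_change(self, rng):
        m = make_matrix(rng.gamma(3.0, 30.0, size=(40, 6)))
        deg = differential_expression(m)
        assert np.allclose(deg["log_fc"], np.log2(deg["fold_change"]), atol=1e-9)

    def test_group_swap_negates_log_fc_and_keeps_p(self, rng):
        vals = rng.gamma(3.0, 30.0, size=(30, 6))
        fwd = differential_expression(make_matrix(vals))
        swapped = np.concatenate([vals[:, 3:], vals[:, :3]], axis=1)
        rev = differential_expression(make_matrix(swapped))
        assert np.allclose(fwd["log_fc"], -rev["log_fc"], atol=1e-12)
        assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_invariant_to_permuting_samples_within_groups(self, rng):
        vals = rng.gamma(3.0, 30.0, size=(30, 6))
        base = differential_expression(make_matrix(vals))
        perm = vals[:, [2, 0, 1, 4, 5, 3]]
        same = differential_expression(make_matrix(perm))
        pd.testing.assert_frame_equal(base, same)


class TestClassifyDrgs:
    def test_boundary_log_fc_is_not_called(self):
        rec = pd.DataFrame(
            {"fold_change": [2 ** -0.5], "log_fc": [-0.5], "p_value": [0.001]},
            index=["tx0"],
        )
        assert classify_drgs(rec).table["call"].iloc[0] == "ns"

    def test_published_extreme_rows_classify_by_sign(self):
        # strongly regulated transcripts from the EV-treated osteosarcoma profile
        rec = pd.DataFrame(
            {
                "fold_change": [1.62e-2, 3.16e10],
                "log_fc": np.log2([1.62e-2, 3.16e10]),
                "p_value": [1.39e-3, 1.42e-12],
            },
            index=["NCOR2", "RNY1"],
        )
        calls = classify_drgs(rec)
        assert calls.table.loc["NCOR2", "call"] == "down"
        assert abs(calls.table.loc["NCOR2", "log_fc"] - (-5.95)) < 0.01
        assert calls.table.loc["RNY1", "call"] == "up"

    def test_down_list_sorted_by_ascending_p(self, rng):
        n = 50
        rec = pd.DataFrame(
            {
                "fold_change": np.full(n, 0.1),
                "log_fc": np.full(n, np.log2(0.1)),
                "p_value": rng.uniform(0, 0.009, n),
            },
            index=[f"tx{i}" for i in range(n)],
        )
        down = classify_drgs(rec).down
        assert (down["p_value"].diff().dropna() >= 0).all()

    def test_planted_effects_are_recovered(self):
        matrix, truth = gen_expression_matrix(2000, 3, 0.1, 2.0, 0.3, seed=5)
        filtered, _ = filter_low_tpm(matrix)
        calls = classify_drgs(differential_expression(filtered))
        called = set(calls.up.index) | set(calls.down.index)
        tp = called & truth.de_transcripts
        sensitivity = len(tp) / len(truth.de_transcripts)
        fdr = (len(called) - len(tp)) / max(len(called), 1)
        assert sensitivity > 0.6
        assert fdr < 0.1
        # directions agree with the planted truth
        for t in calls.up.index.intersection(list(truth.de_transcripts)):
            assert truth.de_direction[t] == "up"
        for t in calls.down.index.intersection(list(truth.de_transcripts)):
            assert truth.de_direction[t] == "down"


class TestCollapseToGenes:
    def test_opposite_transcripts_average_to_zero(self):
        rec = pd.DataFrame(
            {"fold_change": [2.0, 0.5], "log_fc": [1.0, -1.0], "p_value": [0.5, 0.5]},
            index=["tx0", "tx1"],
        )
        mapping = pd.DataFrame(
            {"transcript_id": ["tx0", "tx1"], "gene_symbol": ["G", "G"]}
        )
        ranked = collapse_to_genes(rec, mapping)
        assert len(ranked) == 1 and ranked["score"].iloc[0] == 0.0

    def test_one_to_one_mapping_preserves_order(self, rng):
        n = 20
        rec = pd.DataFrame(
            {"fold_change": np.ones(n), "log_fc": rng.normal(size=n),
             "p_value": np.full(n, 0.5)},
            index=[f"tx{i}" for i in range(n)],
        )
        mapping = pd.DataFrame(
            {"transcript_id": rec.index, "gene_symbol": [f"G{i}" for i in range(n)]}
        )
        ranked = collapse_to_genes(rec, mapping)
        by_lfc = rec.sort_values("log_fc", ascending=False)["log_fc"].to_numpy()
        assert np.allclose(ranked["score"], by_lfc)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(2, 40), st.integers(1, 8), st.integers(0, 10_000))
    def test_many_to_one_matches_group_mean_oracle(self, n_tx, n_genes, seed):
        rng = np.random.default_rng(seed)
        lfc = rng.normal(size=n_tx)
        genes = [f"G{rng.integers(n_genes)}" for _ in range(n_tx)]
        rec = pd.DataFrame(
            {"fold_change": np.exp2(lfc), "log_fc": lfc, "p_value": np.full(n_tx, 0.5)},
            index=[f"tx{i}" for i in range(n_tx)],
        )
        mapping = pd.DataFrame({"transcript_id": rec.index, "gene_symbol": genes})
        ranked = collapse_to_genes(rec, mapping).set_index("gene")["score"]
        oracle: dict[str, list[float]] = {}
        for g, v in zip(genes, lfc):
            oracle.setdefault(g, []).append(v)
        for g, vals in oracle.items():
            assert ranked[g] == pytest.approx(sum(vals) / len(vals))

    def test_unmapped_transcripts_dropped_and_empty_rejected(self):
        rec = pd.DataFrame(
            {"fold_change": [2.0], "log_fc": [1.0], "p_value": [0.5]}, index=["tx0"]
        )
        mapping = pd.DataFrame({"transcript_id": ["other"], "gene_symbol": ["G"]})
        with pytest.raises(ValueError, match="mapping"):
            collapse_to_genes(rec, mapping)
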