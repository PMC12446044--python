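"""Weighted Z-score index: stage semantics, oracle equivalence, symmetries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpeai.activity import (
    MethanogenesisActivityIndex,
    compute_mpeai,
    compute_raw_activity,
    compute_weights,
    filter_expressed_genes,
    normalize_activity,
    standardize_genes,
)
from mpeai.io import ExpressionMatrix, ModuleCatalog


def mpeai_oracle(values, tpm_threshold=1.0, sample_fraction=0.10, epsilon=1e-6):
    """Literal nested-loop transcription of the four index formulas.

    Pure-Python reference, independent of the vectorized implementation:
    expression filter, per-gene Z-scores (ddof=1), inverse-variance
    weights, weighted average, cross-sample normalization.
    """
    G, S = len(values), len(values[0])
    kept = []
    for g in range(G):
        n_pass = sum(1 for s in range(S) if values[g][s] > tpm_threshold)
        if n_pass / S >= sample_fraction:
            kept.append(g)
    mu, sigma, z, w = {}, {}, {}, {}
    for g in list(kept):
        m = sum(values[g][s] for s in range(S)) / S
        var = sum((values[g][s] - m) ** 2 for s in range(S)) / (S - 1)
        sd = math.sqrt(var)
        if sd == 0:
            kept.remove(g)
            continue
        mu[g], sigma[g] = m, sd
        z[g] = [(values[g][s] - m) / sd for s in range(S)]
        w[g] = 1.0 / (var + epsilon)
    if not kept:
        raise ValueError("no genes")
    wsum = sum(w[g] for g in kept)
    A = [sum(z[g][s] * w[g] for g in kept) / wsum for s in range(S)]
    muA = sum(A) / S
    sdA = math.sqrt(sum((a - muA) ** 2 for a in A) / (S - 1))
    return [(a - muA) / sdA for a in A]


def _expr(values, layer="MT"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        layer,
    )


class TestFilter:
    def test_boundary_fraction_retained(self):
        # TPM > 1 in exactly 1 of 10 samples meets the 10% floor
        row = np.ones((1, 10))
        row[0, 0] = 5.0
        assert filter_expressed_genes(_expr(row)) == ["g0"]

    def test_tpm_exactly_one_everywhere_dropped(self):
        assert filter_expressed_genes(_expr(np.ones((1, 10)))) == []

    def test_four_of_fortyeight_dropped(self):
        # 4/48 ~ 0.083 < 0.10: direct count against the retention rule
        row = np.zeros((1, 48))
        row[0, :4] = 10.0
        assert filter_expressed_genes(_expr(row)) == []
        row[0, 4] = 10.0  # 5/48 ~ 0.104 >= 0.10
        assert filter_expressed_genes(_expr(row)) == ["g0"]

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError, match="empty sample set"):
            filter_expressed_genes(_expr(np.zeros((1, 0))))


class TestStandardize:
    def test_simple_row(self):
        std = standardize_genes(_expr([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(std.z[0], [-1, 0, 1])
        assert std.mu[0] == 2.0 and std.sigma[0] == 1.0

    def test_constant_row_dropped_and_reported(self):
        std = standardize_genes(_expr([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert std.dropped_zero_variance == ["g0"]
        assert std.gene_ids == ["g1"]

    def test_rows_mean0_sd1_by_elementwise_loop(self):
        rng = np.random.default_rng(11)
        std = standardize_genes(_expr(rng.gamma(2.0, 5.0, size=(4, 6))))
        for i in range(4):
            row = std.z[i]
            mean = sum(row) / len(row)
            sd = math.sqrt(sum((v - mean) ** 2 for v in row) / (len(row) - 1))
            assert abs(mean) < 1e-9 and abs(sd - 1) < 1e-9

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            standardize_genes(_expr([[1.0]]))


class TestWeightsAndActivity:
    def test_unit_variance_weight(self):
        std = standardize_genes(_expr([[1.0, 2.0, 3.0]]))  # sigma = 1
        w = compute_weights(std)
        assert w.w[0] == pytest.approx(1 / (1 + 1e-6), abs=0, rel=1e-12)

    def test_weight_ratio_tracks_variance(self):
        std = standardize_genes(_expr([[1.0, 2.0, 3.0], [0.0, 2.0, 4.0]]))  # var 1, 4
        w = compute_weights(std)
        assert w.w[0] / w.w[1] == pytest.approx((4 + 1e-6) / (1 + 1e-6), rel=1e-12)

    def test_nonpositive_epsilon_rejected(self):
        std = standardize_genes(_expr([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError):
            compute_weights(std, epsilon=0.0)

    def test_equal_weights_cancel(self):
        std = standardize_genes(_expr([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        w = compute_weights(std)
        raw = compute_raw_activity(std, w)
        np.testing.assert_allclose(raw, [0, 0, 0], atol=1e-12)

    def test_single_gene_activity_is_its_zscore(self):
        std = standardize_genes(_expr([[2.0, 4.0, 9.0]]))
        raw = compute_raw_activity(std, compute_weights(std))
        np.testing.assert_allclose(raw, std.z[0], atol=1e-15)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        std = standardize_genes(_expr(rng.gamma(2.0, 10.0, size=(5, 4))))
        w = compute_weights(std)
        raw = compute_raw_activity(std, w)
        for s in range(4):
            expected = sum(std.z[g][s] * w.w[g] for g in range(5)) / sum(w.w)
            assert raw[s] == pytest.approx(expected, abs=1e-12)

    def test_mismatched_gene_sets_rejected(self):
        std = standardize_genes(_expr([[1.0, 2.0, 3.0]]))
        w = compute_weights(std)
        w.gene_ids = ["other"]
        with pytest.raises(ValueError, match="mismatched"):
            compute_raw_activity(std, w)


class TestNormalize:
    def test_affine_map(self):
        normalized, mu, sd = normalize_activity(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(normalized, [-1, 0, 1])
        assert mu == 2.0 and sd == 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            normalize_activity(np.array([2.0, 2.0, 2.0]))


class TestComputeMpeai:
    def test_hand_worked_toy(self, toy_expr, toy_catalog):
        # both gene rows standardize to (-1, 0, 1); any positive weights
        # leave the weighted mean proportional, and normalization restores
        # exactly (-1, 0, 1)
        profile = compute_mpeai(toy_expr, toy_catalog)
        np.testing.assert_allclose(profile.normalized, [-1, 0, 1], atol=1e-12)
        assert profile.gene_count == 2

    def test_unknown_module_errors(self, toy_expr, toy_catalog):
        with pytest.raises(ValueError, match="no pathway genes"):
            compute_mpeai(toy_expr, toy_catalog, modules={"M00999"})

    def test_sample_permutation_equivariance(self, toy_expr, toy_catalog):
        profile = compute_mpeai(toy_expr, toy_catalog)
        perm = [2, 0, 1]
        shuffled = ExpressionMatrix(
            toy_expr.gene_ids,
            [toy_expr.sample_ids[i] for i in perm],
            toy_expr.values[:, perm],
            "MT",
        )
        profile2 = compute_mpeai(shuffled, toy_catalog)
        np.testing.assert_allclose(profile2.normalized, profile.normalized[perm], atol=1e-12)

    def test_gene_row_order_invariance(self):
        rng = np.random.default_rng(9)
        values = rng.gamma(3.0, 8.0, size=(12, 7))
        a = compute_mpeai(_expr(values)).normalized
        perm = rng.permutation(12)
        expr2 = ExpressionMatrix(
            [f"g{i}" for i in perm], [f"s{j}" for j in range(7)], values[perm], "MT"
        )
        b = compute_mpeai(expr2).normalized
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_records_parameters(self, toy_expr, toy_catalog):
        profile = compute_mpeai(toy_expr, toy_catalog, tpm_threshold=0.5)
        assert profile.params["tpm_threshold"] == 0.5
        assert profile.params["modules"] == ["M00356"]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_single_gene_index_scale_invariant(self, scale, seed):
        """Rescaling the only gene's TPM row leaves the index unchanged:
        the Z-row is scale-free and the weight cancels in the ratio."""
        rng = np.random.default_rng(seed)
        row = rng.gamma(3.0, 10.0, size=(1, 6)) + 1.5
        a = compute_mpeai(_expr(row)).normalized
        b = compute_mpeai(_expr(row * scale), tpm_threshold=0.0).normalized
        np.testing.assert_allclose(a, b, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n_genes=st.integers(min_value=1, max_value=50),
        n_samples=st.integers(min_value=3, max_value=20),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_oracle_equivalence_random_matrices(self, n_genes, n_samples, seed):
        """Pipeline output equals the nested-loop formula transcription."""
        rng = np.random.default_rng(seed)
        values = rng.gamma(2.0, 5.0, size=(n_genes, n_samples))
        try:
            expected = mpeai_oracle(values.tolist())
        except (ValueError, ZeroDivisionError):
            with pytest.raises(ValueError):
                compute_mpeai(_expr(values))
            return
        got = compute_mpeai(_expr(values)).normalized
        np.testing.assert_allclose(got, expected, atol=1e-10)
        assert abs(got.mean()) < 1e-9
        assert abs(got.std(ddof=1) - 1) < 1e-9

    def test_determinism(self):
        rng = np.random.default_rng(21)
        values = rng.gamma(2.0, 5.0, size=(20, 10))
        a = compute_mpeai(_expr(values)).normalized
        b = compute_mpeai(_expr(values.copy())).normalized
        assert np.array_equal(a, b)


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = MethanogenesisActivityIndex(tpm_threshold=0.5, epsilon=1e-5)
        cloned = clone(est)
        assert cloned.get_params()["tpm_threshold"] == 0.5
        assert cloned.get_params()["epsilon"] == 1e-5

    def test_fitted_attributes_and_transform_shape(self):
        rng = np.random.default_rng(2)
        X = rng.gamma(2.0, 5.0, size=(8, 15))  # samples x genes
        est = MethanogenesisActivityIndex().fit(X)
        assert len(est.gene_ids_) == len(est.weights_)
        assert est.sigma_A_ > 0
        out = est.transform(X)
        assert out.shape == (8, 1)
        assert abs(out.mean()) < 1e-9

    def test_out_of_sample_scoring_uses_fitted_scale(self):
        rng = np.random.default_rng(7)
        X = rng.gamma(2.0, 5.0, size=(30, 10))
        est = MethanogenesisActivityIndex().fit(X[:20])
        held_out = est.transform(X[20:])
        # held-out scores live on the training scale, not re-normalized
        assert abs(held_out.mean()) > 1e-9

    def test_module_restriction(self, toy_catalog):
        rng = np.random.default_rng(3)
        import pandas as pd

        X = pd.DataFrame(
            rng.gamma(2.0, 5.0, size=(6, 3)), columns=["g1", "g2", "other"]
        )
        est = MethanogenesisActivityIndex(catalog=toy_catalog).fit(X)
        assert set(est.gene_ids_) <= {"g1", "g2"}
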