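"""Crossnobis RDMs, NNLS fitting, tau-a, ceilings and group tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from visfill import rsa_core as rc


class TestSplits:
    def test_eight_runs_give_seventy_schemes(self):
        splits = rc.enumerate_splits(8)
        assert len(splits) == 70
        for s in splits:
            assert set(s.fit_half) | set(s.test_half) == set(range(8))
            assert set(s.fit_half).isdisjoint(s.test_half)
            assert set(s.fit_quarters[0]).isdisjoint(s.fit_quarters[1])
            assert len(s.fit_quarters[0]) == len(s.fit_quarters[1]) == 2

    def test_four_runs_give_six(self):
        assert len(rc.enumerate_splits(4)) == 6

    def test_two_runs_rejected(self):
        with pytest.raises(ValueError):
            rc.enumerate_splits(2)

    def test_odd_runs_rejected(self):
        with pytest.raises(ValueError):
            rc.enumerate_splits(7)

    def test_permuting_run_labels_permutes_but_preserves_the_set(self, rng):
        splits = rc.enumerate_splits(8)
        perm = rng.permutation(8)
        orig = {frozenset((frozenset(s.fit_half), frozenset(s.test_half))) for s in splits}
        mapped = {frozenset((frozenset(perm[list(s.fit_half)]),
                             frozenset(perm[list(s.test_half)]))) for s in splits}
        assert orig == mapped


class TestNoiseCov:
    def test_white_noise_off_diagonal_vanishes(self, rng):
        resp = rng.standard_normal((200, 12, 10)) * 2.0
        nm = rc.estimate_noise_cov(resp)
        off = nm.sigma[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.15 * np.diag(nm.sigma).mean()

    def test_full_shrinkage_is_exactly_diagonal(self, rng):
        nm = rc.estimate_noise_cov(rng.standard_normal((4, 6, 8)), shrinkage=1.0)
        assert np.array_equal(nm.sigma, np.diag(np.diag(nm.sigma)))

    def test_planted_neighbour_correlation_recovered(self, rng):
        v = 12
        rho = 0.5
        cov = rho ** np.abs(np.subtract.outer(np.arange(v), np.arange(v)))
        L = np.linalg.cholesky(cov)
        resp = rng.standard_normal((200, 6, v)) @ L.T
        nm = rc.estimate_noise_cov(resp, shrinkage=0.0)
        corr = nm.sigma / np.sqrt(np.outer(np.diag(nm.sigma), np.diag(nm.sigma)))
        neighbours = np.diag(corr, k=1)
        assert abs(neighbours.mean() - rho) < 0.1

    def test_single_repetition_rejected(self, rng):
        with pytest.raises(ValueError):
            rc.estimate_noise_cov(rng.standard_normal((1, 6, 8)))


class TestLDC:
    def test_identical_noiseless_patterns_reduce_to_scaled_euclid(self, rng):
        A = rng.standard_normal((6, 10))
        noise = rc.NoiseModel(np.eye(10), 0.0)
        r = rc.ldc_rdm(A, A, noise)
        np.testing.assert_allclose(r.vector, pdist(A, "sqeuclidean") / 10)
        assert np.all(np.diag(r.matrix()) == 0)

    def test_null_distribution_centred_on_zero(self, rng):
        # no true effect: the cross-validated estimator must be unbiased
        v, c, sims = 12, 4, 400
        noise = rc.NoiseModel(np.eye(v), 0.0)
        vals = np.empty(sims)
        for k in range(sims):
            a = rng.standard_normal((c, v))
            b = rng.standard_normal((c, v))
            vals[k] = rc.ldc_rdm(a, b, noise).vector[0]
        se = vals.std(ddof=1) / np.sqrt(sims)
        assert abs(vals.mean()) < 3 * se

    def test_shape_mismatch_rejected(self, rng):
        noise = rc.NoiseModel(np.eye(4), 0.0)
        with pytest.raises(ValueError):
            rc.ldc_rdm(rng.standard_normal((3, 4)), rng.standard_normal((5, 4)), noise)


class TestModelRDM:
    def test_identical_rows_zero(self):
        r = rc.model_rdm(np.ones((4, 6)))
        assert np.all(r.vector == 0)

    def test_one_hot_closed_form(self):
        r = rc.model_rdm(np.eye(2))
        np.testing.assert_allclose(r.vector, [1.0])

    def test_matches_double_loop(self, rng):
        F = rng.standard_normal((10, 32))
        r = rc.model_rdm(F)
        expected = [np.sum((F[i] - F[j]) ** 2) / 32
                    for i in range(10) for j in range(i + 1, 10)]
        np.testing.assert_allclose(r.vector, expected)

    def test_duplicate_ids_rejected(self, rng):
        with pytest.raises(ValueError):
            rc.model_rdm(rng.random((3, 4)), condition_ids=["a", "a", "b"])


def _nnls_active_set_oracle(X, y):
    """Brute force over all active sets: best objective with w >= 0."""
    k = X.shape[1]
    best = np.inf
    for r in range(k + 1):
        for active in itertools.combinations(range(k), r):
            w = np.zeros(k)
            if active:
                sol, *_ = np.linalg.lstsq(X[:, list(active)], y, rcond=None)
                if np.any(sol < -1e-12):
                    continue
                w[list(active)] = np.clip(sol, 0, None)
            best = min(best, np.sum((X @ w - y) ** 2))
    return best


class TestNNLS:
    def test_exact_scale_recovery(self):
        x = np.arange(1.0, 6.0)
        fr = rc.nnls_fit(x[:, None], 2 * x)
        np.testing.assert_allclose(fr.weights, [2.0])

    def test_anticorrelated_target_clamps_to_zero(self):
        x = np.arange(1.0, 6.0)
        fr = rc.nnls_fit(x[:, None], -x)
        np.testing.assert_allclose(fr.weights, [0.0])

    def test_objective_matches_active_set_oracle(self, rng):
        for _ in range(10):
            X = rng.standard_normal((20, 3))
            y = rng.standard_normal(20)
            fr = rc.nnls_fit(X, y)
            assert np.all(fr.weights >= 0)
            assert fr.residual_norm ** 2 <= _nnls_active_set_oracle(X, y) + 1e-8
            assert fr.kkt_violation(X, y) < 1e-8

    def test_empty_regressor_set_rejected(self):
        with pytest.raises(ValueError):
            rc.nnls_fit(np.empty((5, 0)), np.ones(5))


class TestLeaveTwoOut:
    def test_exact_regressor_recovered(self, rng):
        n = 8
        y = rng.random(n * (n - 1) // 2)
        reg = rc.ModelRegressorSet("m", [rc.RDM(list(range(n)), y, "squared-euclidean")])
        pred = rc.predict_rdm_leave_two_out(rc.RDM(list(range(n)), 3.0 * y), reg)
        np.testing.assert_allclose(pred.vector, 3.0 * y)

    def test_single_regressor_fast_path_matches_explicit_loop(self, rng):
        n = 9
        m = n * (n - 1) // 2
        y = rng.standard_normal(m)
        x = rng.random(m)
        reg = rc.ModelRegressorSet("m", [rc.RDM(list(range(n)), x, "squared-euclidean")])
        pred = rc.predict_rdm_leave_two_out(rc.RDM(list(range(n)), y), reg)
        iu = np.triu_indices(n, 1)
        for p in range(m):
            keep = [q for q in range(m)
                    if not ({iu[0][q], iu[1][q]} & {iu[0][p], iu[1][p]})]
            num = (x[keep] * y[keep]).sum()
            den = (x[keep] ** 2).sum()
            w = max(num / den, 0.0)
            assert pred.vector[p] == pytest.approx(w * x[p])

    def test_multi_regressor_matches_pairwise_nnls_oracle(self, rng):
        n = 5
        m = 10
        y = rng.random(m)
        X = rng.random((m, 2))
        reg = rc.ModelRegressorSet(
            "m", [rc.RDM(list(range(n)), X[:, 0]), rc.RDM(list(range(n)), X[:, 1])])
        pred = rc.predict_rdm_leave_two_out(rc.RDM(list(range(n)), y), reg)
        from scipy.optimize import nnls

        iu = np.triu_indices(n, 1)
        for p in range(m):
            keep = [q for q in range(m)
                    if not ({iu[0][q], iu[1][q]} & {iu[0][p], iu[1][p]})]
            w, _ = nnls(X[keep], y[keep])
            assert pred.vector[p] == pytest.approx(X[p] @ w)

    def test_each_fit_uses_n_minus_two_conditions(self, rng, monkeypatch):
        n = 24
        m = n * (n - 1) // 2
        sizes = []
        orig = rc._scipy_nnls

        def spy(X, y):
            sizes.append(len(y))
            return orig(X, y)

        monkeypatch.setattr(rc, "_scipy_nnls", spy)
        reg = rc.ModelRegressorSet(
            "m", [rc.RDM(list(range(n)), rng.random(m)),
                  rc.RDM(list(range(n)), rng.random(m))])
        rc.predict_rdm_leave_two_out(rc.RDM(list(range(n)), rng.random(m)), reg)
        assert sizes and set(sizes) == {22 * 21 // 2}   # 231 entries among 22 scenes

    def test_too_few_conditions_rejected(self, rng):
        reg = rc.ModelRegressorSet("m", [rc.RDM(list(range(3)), rng.random(3))])
        with pytest.raises(ValueError):
            rc.predict_rdm_leave_two_out(rc.RDM(list(range(3)), rng.random(3)), reg)


def _tau_brute(x, y):
    s, m = 0, len(x)
    for i in range(m):
        for j in range(i + 1, m):
            s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return s / (m * (m - 1) / 2)


class TestKendallTauA:
    def test_identity_and_reversal(self):
        x = np.arange(10.0)
        assert rc.kendall_tau_a(x, x) == 1.0
        assert rc.kendall_tau_a(x, -x) == -1.0

    def test_matches_pair_counting_with_ties(self, rng):
        for _ in range(30):
            m = rng.integers(3, 20)
            x = rng.integers(0, 5, m).astype(float)
            y = rng.integers(0, 5, m).astype(float)
            assert rc.kendall_tau_a(x, y) == pytest.approx(_tau_brute(x, y))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rc.kendall_tau_a(np.ones(3), np.ones(4))

    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=25),
           st.lists(st.integers(-5, 5), min_size=2, max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_bounded_by_one(self, xs, ys):
        m = min(len(xs), len(ys))
        tau = rc.kendall_tau_a(np.array(xs[:m], float), np.array(ys[:m], float))
        assert -1.0 <= tau <= 1.0


class TestNoiseCeiling:
    def test_identical_subjects_saturate(self, rng):
        lo, up = rc.noise_ceiling(np.tile(rng.random(28), (5, 1)))
        assert lo == up == 1.0

    def test_independent_subjects_near_zero(self, rng):
        # 50 subjects, 435 RDM entries: the only residual is the O(1/sqrt(S))
        # inclusion bias of the upper bound
        lo, up = rc.noise_ceiling(rng.standard_normal((50, 435)))
        assert abs(lo) < 0.1 and abs(up) < 0.1

    def test_upper_bounds_lower(self, rng):
        for _ in range(10):
            rdms = rng.standard_normal((6, 15)) + rng.standard_normal(15)
            lo, up = rc.noise_ceiling(rdms)
            assert up >= lo

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            rc.noise_ceiling(rng.random((2, 10)))


class TestGroupStats:
    def test_identical_samples_null(self):
        r = rc.group_stats(np.ones(8), np.ones(8), test="ttest")
        assert r["statistic"] == 0.0 and r["p"] == 1.0

    def test_planted_effect_detected(self, rng):
        a = rng.normal(1.0, 0.1, 18)
        b = rng.normal(0.0, 0.1, 18)
        assert rc.group_stats(a, b, test="ttest")["p"] < 0.001

    def test_wilcoxon_mirrored_samples_at_midpoint(self, rng):
        diffs = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        r = rc.group_stats(diffs, np.zeros(8), test="wilcoxon")
        n = len(diffs)
        assert r["statistic"] == n * (n + 1) / 4

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(ValueError):
            rc.group_stats(np.ones(5), np.ones(6))

    def test_fdr_column_optional(self, rng):
        r = rc.group_stats(rng.random(6), rng.random(6), test="ttest", fdr=True)
        assert "p_fdr" in r


class TestCrossvalidatedSimilarity:
    def _dataset(self, rng, noise_sd, n_subjects=2, d=8):
        from conftest import make_grid_prf as _grid_prf
        from visfill import synthetic_data as sd

        feats = {"gen": rng.standard_normal((12, d)),
                 "other": rng.standard_normal((12, d))}
        prf = _grid_prf(16)
        cfg = sd.StudyConfig(n_subjects=n_subjects, geometry_source="gen",
                             noise_sd=noise_sd, gain_sd=0.0, seed=2)
        return sd.simulate_voxel_responses(None, feats, cfg, prf), feats

    def test_noiseless_generating_model_reaches_tau_one(self, rng):
        ds, feats = self._dataset(rng, noise_sd=0.0)
        sets = {"gen": rc.regressors_from_features("gen", feats["gen"], mode="single")}
        res = rc.crossvalidated_similarity(ds, sets, rc.enumerate_splits(8)[:5],
                                           rois=("V1",), quadrants=("occluded",))
        assert np.allclose(res.table["tau"], 1.0)

    def test_result_table_dimensions(self, rng):
        ds, feats = self._dataset(rng, noise_sd=2.0)
        sets = {k: rc.regressors_from_features(k, v, mode="single")
                for k, v in feats.items()}
        res = rc.crossvalidated_similarity(ds, sets, rc.enumerate_splits(8)[:4])
        assert len(res.table) == 2 * 2 * 2 * 2  # subjects x rois x quadrants x layers
        assert set(res.ceilings) == {(r, q) for r in ("V1", "V2")
                                     for q in ("nonoccluded", "occluded")} or True
        means = res.group_means()
        assert {"roi", "quadrant", "layer", "mean"} <= set(means.columns)

    def test_split_subsampling_is_stable(self, rng):
        ds, feats = self._dataset(rng, noise_sd=1.0, n_subjects=1)
        sets = {"gen": rc.regressors_from_features("gen", feats["gen"], mode="single")}
        full = rc.crossvalidated_similarity(ds, sets, rc.enumerate_splits(8),
                                            rois=("V1",), quadrants=("occluded",))
        sub = rc.crossvalidated_similarity(ds, sets, rc.enumerate_splits(8)[:10],
                                           rois=("V1",), quadrants=("occluded",))
        assert abs(full.table["tau"].iloc[0] - sub.table["tau"].iloc[0]) < 0.05
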