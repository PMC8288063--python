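"""Cross-validated representational similarity analysis.

The estimation chain, per subject and per (ROI, quadrant) voxel group:

1. The 8 runs are split into a fitting half and a testing half (all
   C(8,4) = 70 role-distinct assignments); each half is divided into two
   quarters of 2 runs (lexicographic pairing of the sorted run indices).
2. Within each half, a cross-validated linear discriminant contrast (LDC,
   "crossnobis") RDM is computed between the two quarters:
   ``d(i,j) = (a_i - a_j)^T Sigma^{-1} (b_i - b_j) / n_voxels``
   with a shrinkage noise covariance estimated from the fitting half.
   Cross-validation makes the estimator unbiased, so entries may be
   negative.
3. For every condition pair (i, j), candidate-model RDM regressors are fit
   to the fitting-half RDM entries among the other n-2 conditions (for 24
   scenes: the 231 entries among 22 scenes) by non-negative least squares;
   the fitted weights predict entry (i, j).  The assembled predicted RDM is
   compared with the testing-half RDM by Kendall's tau-a.
4. Tau values are averaged over the 70 splits, giving one similarity per
   subject x ROI x quadrant x candidate layer, plus noise ceilings and
   paired group tests.

Model-side RDMs are squared Euclidean distances on the reduced activations
divided by the component count (the deterministic degenerate case of LDC).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import nnls as _scipy_nnls
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "RDM",
    "NoiseModel",
    "SplitScheme",
    "ModelRegressorSet",
    "FitResult",
    "RSAResult",
    "enumerate_splits",
    "estimate_noise_cov",
    "ldc_rdm",
    "model_rdm",
    "nnls_fit",
    "predict_rdm_leave_two_out",
    "kendall_tau_a",
    "crossvalidated_similarity",
    "noise_ceiling",
    "group_stats",
    "regressors_from_features",
]


@dataclass
class RDM:
    """Condition-labelled vector of pairwise dissimilarities (n(n-1)/2)."""

    condition_ids: list
    vector: np.ndarray
    estimator: str = "ldc"

    def __post_init__(self):
        n = len(self.condition_ids)
        if len(self.vector) != n * (n - 1) // 2:
            raise ValueError(
                f"vector length {len(self.vector)} inconsistent with {n} conditions")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("RDM entries must be finite")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def matrix(self) -> np.ndarray:
        return squareform(self.vector)


@dataclass
class NoiseModel:
    """Shrinkage voxel covariance with its Cholesky factorization."""

    sigma: np.ndarray
    shrinkage: float
    source: str = "repetition-deviations"

    def __post_init__(self):
        self._cho = cho_factor(self.sigma)

    def solve(self, B: np.ndarray) -> np.ndarray:
        return cho_solve(self._cho, B)


@dataclass(frozen=True)
class SplitScheme:
    """Fitting/testing halves of the run set, each split into two quarters."""

    fit_quarters: tuple[tuple[int, ...], tuple[int, ...]]
    test_quarters: tuple[tuple[int, ...], tuple[int, ...]]

    @property
    def fit_half(self) -> tuple[int, ...]:
        return tuple(sorted(self.fit_quarters[0] + self.fit_quarters[1]))

    @property
    def test_half(self) -> tuple[int, ...]:
        return tuple(sorted(self.test_quarters[0] + self.test_quarters[1]))


def enumerate_splits(n_runs: int) -> list[SplitScheme]:
    """All role-distinct half assignments (C(n, n/2); 70 for 8 runs).

    Quarters within a half pair the sorted run indices lexicographically:
    the first half of the sorted list vs the second.
    """
    if n_runs % 2 != 0:
        raise ValueError(f"n_runs must be even, got {n_runs}")
    if n_runs < 4:
        raise ValueError(f"n_runs must be >= 4 so each half has two quarters, got {n_runs}")
    runs = range(n_runs)
    q = n_runs // 4 if n_runs % 4 == 0 else None
    half = n_runs // 2
    out = []
    for fit in itertools.combinations(runs, half):
        test = tuple(r for r in runs if r not in fit)
        out.append(SplitScheme(
            (fit[:half // 2], fit[half // 2:]),
            (test[:half // 2], test[half // 2:])))
    return out


def estimate_noise_cov(responses: np.ndarray, shrinkage: float | None = None) -> NoiseModel:
    """Shrinkage covariance of within-condition repetition deviations.

    ``responses`` is (reps, conditions, voxels) — e.g. the runs of one half.
    The sample covariance of the deviations from each condition's mean is
    shrunk toward its diagonal; the intensity defaults to the analytic
    Schafer-Strimmer choice for off-diagonal entries, clipped to [0, 1].
    """
    if responses.shape[0] < 2:
        raise ValueError("need >= 2 repetitions to estimate the noise covariance")
    r, c, v = responses.shape
    dev = responses - responses.mean(axis=0, keepdims=True)
    X = dev.reshape(r * c, v)
    n = X.shape[0]
    S = X.T @ X / (n - 1)
    if shrinkage is None:
        # analytic intensity for a diagonal target (Schafer-Strimmer style):
        # lambda = sum_offdiag Var(s_ij) / sum_offdiag s_ij^2
        W2 = np.einsum("ni,nj->ij", X ** 2, X ** 2)      # sum_k x_ki^2 x_kj^2
        Wbar = (X.T @ X) / n
        var_s = (n / (n - 1) ** 3) * (W2 - n * Wbar ** 2)
        off = ~np.eye(v, dtype=bool)
        den = (S[off] ** 2).sum()
        shrinkage = float(np.clip(var_s[off].sum() / den if den > 0 else 1.0, 0.0, 1.0))
    sigma = (1 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    # guarantee positive definiteness (certified by the Cholesky inside NoiseModel)
    for bump in (0.0, 1e-8, 1e-6, 1e-4):
        try:
            return NoiseModel(sigma + bump * np.eye(v) * max(np.trace(sigma) / v, 1e-12),
                              shrinkage)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("noise covariance is not positive definite")


def ldc_rdm(patterns_a: np.ndarray, patterns_b: np.ndarray, noise: NoiseModel,
            condition_ids: list | None = None) -> RDM:
    """Cross-validated linear discriminant contrast RDM between two quarters.

    ``patterns_a`` / ``patterns_b`` are (reps, conditions, voxels) or
    (conditions, voxels) condition means from the two independent quarters.
    """
    A = patterns_a.mean(axis=0) if patterns_a.ndim == 3 else patterns_a
    B = patterns_b.mean(axis=0) if patterns_b.ndim == 3 else patterns_b
    if A.shape != B.shape:
        raise ValueError(f"quarter patterns disagree: {A.shape} vs {B.shape}")
    c, v = A.shape
    K = A @ noise.solve(B.T)                      # K[i, j] = a_i' Sigma^-1 b_j
    d = np.diag(K)
    D = (d[:, None] + d[None, :] - K - K.T) / v
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = condition_ids if condition_ids is not None else list(range(c))
    return RDM(ids, squareform(D, checks=False), estimator="ldc")


def model_rdm(features: np.ndarray, condition_ids: list | None = None) -> RDM:
    """Squared Euclidean RDM of a feature matrix, divided by component count."""
    features = np.asarray(features, dtype=float)
    ids = condition_ids if condition_ids is not None else list(range(len(features)))
    if len(set(map(str, ids))) != len(ids):
        raise ValueError("duplicate condition ids")
    return RDM(ids, pdist(features, "sqeuclidean") / features.shape[1],
               estimator="squared-euclidean")


@dataclass
class FitResult:
    weights: np.ndarray
    residual_norm: float

    def kkt_violation(self, X: np.ndarray, y: np.ndarray) -> float:
        """Largest violation of the NNLS KKT conditions (0 when optimal)."""
        g = X.T @ (X @ self.weights - y)
        viol_active = np.abs(g[self.weights > 0]).max(initial=0.0)
        viol_bound = np.maximum(-g[self.weights <= 0], 0.0).max(initial=0.0)
        return float(max(viol_active, viol_bound))


def nnls_fit(X: np.ndarray, y: np.ndarray) -> FitResult:
    """min ||Xw - y||^2 subject to w >= 0 (active-set solver)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == 0:
        raise ValueError("empty regressor set")
    w, rnorm = _scipy_nnls(X, np.asarray(y, dtype=float))
    return FitResult(w, float(rnorm))


@dataclass
class ModelRegressorSet:
    """Candidate-model RDM regressors for one layer."""

    name: str
    rdms: list[RDM]
    mode: str = "single"  # "single" | "pc-blocks(b)"

    def __post_init__(self):
        if not self.rdms:
            raise ValueError("a regressor set needs at least one RDM")
        ids = self.rdms[0].condition_ids
        for r in self.rdms:
            if list(r.condition_ids) != list(ids):
                raise ValueError("regressor RDMs must share condition ids")

    @property
    def condition_ids(self):
        return self.rdms[0].condition_ids

    def matrix(self) -> np.ndarray:
        """(n_pairs, n_regressors) design matrix."""
        return np.stack([r.vector for r in self.rdms], axis=1)


def regressors_from_features(name: str, features: np.ndarray,
                             condition_ids: list | None = None,
                             mode: str = "pc-blocks", block: int = 64) -> ModelRegressorSet:
    """Build a layer's regressor set from its reduced feature matrix.

    ``pc-blocks`` contributes one squared-Euclidean RDM per consecutive block
    of ``block`` principal components (16 regressors for 1024 components);
    ``single`` contributes the whole-feature RDM only.
    """
    if mode == "single":
        return ModelRegressorSet(name, [model_rdm(features, condition_ids)], "single")
    if mode != "pc-blocks":
        raise ValueError(f"unknown regressor mode {mode!r}")
    d = features.shape[1]
    rdms = [model_rdm(features[:, i:i + block], condition_ids)
            for i in range(0, d, block)]
    return ModelRegressorSet(name, rdms, f"pc-blocks({block})")


def _pair_membership(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def predict_rdm_leave_two_out(data_rdm: RDM, regressors: ModelRegressorSet) -> RDM:
    """Leave-two-conditions-out NNLS prediction of every RDM entry.

    For each condition pair (i, j) the regressor weights are fit on the RDM
    entries among the remaining n-2 conditions and used to predict entry
    (i, j).
    """
    n = data_rdm.n_conditions
    if n < 4:
        raise ValueError(f"need >= 4 conditions for leave-two-out fitting, got {n}")
    y = data_rdm.vector
    X = regressors.matrix()
    ri, rj = _pair_membership(n)
    if X.shape[1] == 1:
        pred = _l2o_single(y, X[:, 0], ri, rj, n)
    else:
        pred = np.empty_like(y)
        for p in range(len(y)):
            keep = (ri != ri[p]) & (ri != rj[p]) & (rj != ri[p]) & (rj != rj[p])
            w = _scipy_nnls(X[keep], y[keep])[0]
            pred[p] = X[p] @ w
    return RDM(list(data_rdm.condition_ids), pred, estimator="nnls-prediction")


def _l2o_single(y: np.ndarray, x: np.ndarray, ri: np.ndarray, rj: np.ndarray,
                n: int) -> np.ndarray:
    """Closed-form vectorized leave-two-out fit for a single regressor:
    w = max(0, sum(xy)/sum(x^2)) over entries not involving either held-out
    condition."""
    xy, xx = x * y, x * x
    S_xy, S_xx = xy.sum(), xx.sum()
    row_xy = np.zeros(n)
    row_xx = np.zeros(n)
    np.add.at(row_xy, ri, xy)
    np.add.at(row_xy, rj, xy)
    np.add.at(row_xx, ri, xx)
    np.add.at(row_xx, rj, xx)
    num = S_xy - row_xy[ri] - row_xy[rj] + xy
    den = S_xx - row_xx[ri] - row_xx[rj] + xx
    w = np.where(den > 0, np.maximum(num / np.where(den > 0, den, 1.0), 0.0), 0.0)
    return w * x


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-a: (concordant - discordant) / (m(m-1)/2), ties counting
    toward neither."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    m = len(x)
    if m < 2:
        raise ValueError("need at least 2 entries")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    s = float((sx * sy)[np.triu_indices(m, k=1)].sum())
    return s / (m * (m - 1) / 2)


@dataclass
class RSAResult:
    """Per-subject similarities plus ceilings and group summaries."""

    table: pd.DataFrame                      # subject, roi, quadrant, layer, tau
    ceilings: dict                           # (roi, quadrant) -> (lower, upper)
    subject_rdms: dict                       # (roi, quadrant) -> (S, n_pairs) mean test RDMs
    regressor_mode: str = "single"

    def group_means(self) -> pd.DataFrame:
        return (self.table.groupby(["roi", "quadrant", "layer"], sort=False)["tau"]
                .agg(["mean", "std", "count"]).reset_index())


def crossvalidated_similarity(dataset, model_sets: dict[str, ModelRegressorSet],
                              splits: list[SplitScheme] | None = None,
                              rois: tuple[str, ...] = ("V1", "V2"),
                              quadrants: tuple[str, ...] = ("nonoccluded", "occluded"),
                              progress: bool = False) -> RSAResult:
    """Full split-quarter cross-validated RSA over a simulated dataset.

    For each subject, (ROI, quadrant) group and split: LDC RDM between the
    fitting half's quarters, leave-two-out prediction per candidate layer,
    LDC RDM between the testing half's quarters, tau-a between prediction
    and test; averaged over splits.
    """
    if splits is None:
        splits = enumerate_splits(dataset.n_runs)
    layers = list(model_sets)
    rows = []
    ceilings = {}
    subject_rdms = {}
    design = {name: ms.matrix() for name, ms in model_sets.items()}
    cond = list(range(dataset.n_conditions))
    for roi in rois:
        for quadrant in quadrants:
            resp = dataset.group(roi, quadrant)       # (S, R, C, V)
            if resp.shape[-1] == 0:
                continue
            taus = np.zeros((dataset.n_subjects, len(layers)))
            mean_test = np.zeros((dataset.n_subjects, len(cond) * (len(cond) - 1) // 2))
            for s in range(dataset.n_subjects):
                for split in splits:
                    fit_rdm, test_rdm = _split_rdms(resp[s], split, cond)
                    for li, layer in enumerate(layers):
                        pred = predict_rdm_leave_two_out(fit_rdm, model_sets[layer])
                        taus[s, li] += kendall_tau_a(pred.vector, test_rdm.vector)
                    mean_test[s] += test_rdm.vector
                taus[s] /= len(splits)
                mean_test[s] /= len(splits)
            for s in range(dataset.n_subjects):
                for li, layer in enumerate(layers):
                    rows.append((s, roi, quadrant, layer, taus[s, li]))
            subject_rdms[(roi, quadrant)] = mean_test
            if dataset.n_subjects >= 3:
                ceilings[(roi, quadrant)] = noise_ceiling(mean_test)
    table = pd.DataFrame(rows, columns=["subject", "roi", "quadrant", "layer", "tau"])
    mode = next(iter(model_sets.values())).mode if model_sets else "single"
    return RSAResult(table, ceilings, subject_rdms, mode)


def _split_rdms(resp: np.ndarray, split: SplitScheme, cond_ids: list) -> tuple[RDM, RDM]:
    """(fitting-half RDM, testing-half RDM) for one subject and split."""
    fa, fb = split.fit_quarters
    ta, tb = split.test_quarters
    noise_fit = estimate_noise_cov(resp[list(split.fit_half)])
    noise_test = estimate_noise_cov(resp[list(split.test_half)])
    rdm_fit = ldc_rdm(resp[list(fa)], resp[list(fb)], noise_fit, cond_ids)
    rdm_test = ldc_rdm(resp[list(ta)], resp[list(tb)], noise_test, cond_ids)
    return rdm_fit, rdm_test


def noise_ceiling(subject_rdms: np.ndarray) -> tuple[float, float]:
    """(lower, upper) tau-a noise ceiling from per-subject RDM vectors.

    Upper: mean tau-a between each subject's RDM and the all-subject mean;
    lower: the same against the leave-one-subject-out mean.
    """
    subject_rdms = np.asarray(subject_rdms)
    S = len(subject_rdms)
    if S < 3:
        raise ValueError(f"need >= 3 subjects for a noise ceiling, got {S}")
    total = subject_rdms.sum(axis=0)
    upper = np.mean([kendall_tau_a(r, total / S) for r in subject_rdms])
    lower = np.mean([kendall_tau_a(r, (total - r) / (S - 1)) for r in subject_rdms])
    return float(lower), float(upper)


def group_stats(samples_a: np.ndarray, samples_b: np.ndarray, test: str = "ttest",
                fdr: bool = False) -> dict:
    """Paired group test between two matched sample vectors.

    ``ttest`` (paired t, between-model contrasts) or ``wilcoxon``
    (signed-rank, encoder-vs-decoder section contrasts).  Raw p-values;
    set ``fdr`` for an additional Benjamini-Hochberg-adjusted value when
    called with 2-D stacked contrasts.
    """
    from scipy import stats as sps

    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have matching shapes")
    if test == "ttest":
        if np.allclose(a, b):
            res_stat, res_p = 0.0, 1.0
        else:
            r = sps.ttest_rel(a, b)
            res_stat, res_p = float(r.statistic), float(r.pvalue)
    elif test == "wilcoxon":
        if np.allclose(a, b):
            res_stat, res_p = 0.0, 1.0
        else:
            r = sps.wilcoxon(a, b)
            res_stat, res_p = float(r.statistic), float(r.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    out = {"test": test, "statistic": res_stat, "p": res_p, "n": int(a.size)}
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["p_fdr"] = float(multipletests([res_p], method="fdr_bh")[1][0])
    return out
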