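"""Association statistics between ROI-level DN parameters and receptor maps.

All statistics operate on ROI tables and use the ROI weight (mean cvR2) so
that well-modelled regions count more: the weighted correlation coefficient
(wCC), a two-sided Fisher permutation test (permute the independent
variable, keep the dependent variable and weights in place), cross-validated
one-/two-receptor weighted GLMs with a surrogate-receptor permutation test,
and a PCA of the receptor set with an equivariance threshold of
1/(number of receptors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .aggregation import ROITable

__all__ = [
    "WeightedSample",
    "PermutationResult",
    "PCAResult",
    "weighted_pearson",
    "permutation_test",
    "fit_weighted_glm",
    "crossval_glm",
    "surrogate_pair_test",
    "pca_receptors",
    "component_parameter_scan",
]

_TIE_TOL = 1e-12


class UndefinedCorrelationError(ValueError):
    """Weighted variance of x or y is zero; correlation undefined."""


class SingularDesignError(ValueError):
    """GLM design is collinear or constant."""


@dataclass
class WeightedSample:
    """Paired ROI values with non-negative weights (mean cvR2 per ROI).

    Weights are renormalized to mean 1 on construction; this leaves every
    statistic unchanged but stabilizes reporting.
    """

    x: np.ndarray
    y: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        n = self.x.size
        if self.y.size != n or self.w.size != n:
            raise ValueError("x, y, w must have equal length")
        if n < 3:
            raise ValueError("at least three ROIs are required")
        if np.unique(self.x).size < 2 or np.unique(self.y).size < 2:
            raise ValueError("x and y must each take at least two distinct values")
        if np.any(self.w < 0) or self.w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        self.w = self.w / self.w.mean()

    @property
    def n(self) -> int:
        return self.x.size


def _wmean(v: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * v) / np.sum(w))


def weighted_pearson(x, y, weights=None) -> float:
    """Weighted Pearson correlation of x and y.

    Weighted covariance about the weighted means divided by the product of
    weighted standard deviations.  Unit weights reduce to the classical
    correlation coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    mx = np.sum(w * x) / wsum
    my = np.sum(w * y) / wsum
    cov = np.sum(w * (x - mx) * (y - my)) / wsum
    vx = np.sum(w * (x - mx) ** 2) / wsum
    vy = np.sum(w * (y - my) ** 2) / wsum
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError("zero weighted variance in x or y")
    return float(cov / np.sqrt(vx * vy))


def _weighted_pearson_rows(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """wCC of each row of X against y (vectorized over permutations)."""
    wsum = w.sum()
    mx = (X * w).sum(axis=1) / wsum
    my = np.sum(w * y) / wsum
    xc = X - mx[:, None]
    yc = y - my
    cov = (w * xc * yc).sum(axis=1)
    vx = (w * xc * xc).sum(axis=1)
    vy = np.sum(w * yc * yc)
    denom = np.sqrt(vx * vy)
    denom[denom == 0] = np.inf
    return cov / denom


@dataclass
class PermutationResult:
    """Outcome of a two-sided Fisher permutation test.

    ``p`` is the exceedance fraction; when no permutation reaches the
    observed magnitude, ``p`` is floored at ``1/n_permutations`` and
    ``floored`` is set (report as "p < 1/n_perm").
    """

    statistic: float
    n_permutations: int
    n_exceed: int
    p: float
    floored: bool = False
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.floored and self.p < 1.0 / self.n_permutations:
            raise ValueError("floored p cannot go below 1/n_permutations")

    def __str__(self) -> str:
        rel = "<" if self.floored else "="
        return f"wCC={self.statistic:.3f}, p {rel} {self.p:.3g}"


def _p_from_count(count: int, n_perm: int) -> tuple[float, bool]:
    if count == 0:
        return 1.0 / n_perm, True
    return count / n_perm, False


def _permutation_matrix(n: int, n_perm: int, rng: np.random.Generator, exhaustive: bool):
    if exhaustive:
        return np.array(list(iter_permutations(range(n))), dtype=int)
    idx = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(idx, axis=1)


def permutation_test(
    x, y, weights=None, n_perm: int = 10_000, seed=None
) -> PermutationResult:
    """Two-sided Fisher permutation test of the weighted correlation.

    The independent variable ``x`` is permuted while ``y`` and the weights
    stay in place; the p value is the fraction of permutations whose wCC
    magnitude reaches the observed one.  Exhaustive enumeration replaces
    random sampling whenever ``n! <= n_perm``.
    """
    sample = WeightedSample(x, y, np.ones(len(np.asarray(x))) if weights is None else weights)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    observed = weighted_pearson(sample.x, sample.y, sample.w)
    rng = np.random.default_rng(seed)
    exhaustive = math.factorial(sample.n) <= n_perm
    n_total = math.factorial(sample.n) if exhaustive else n_perm

    count = 0
    chunk = 100_000
    done = 0
    if exhaustive:
        perms = _permutation_matrix(sample.n, n_total, rng, True)
        r = _weighted_pearson_rows(sample.x[perms], sample.y, sample.w)
        count = int(np.sum(np.abs(r) >= abs(observed) - _TIE_TOL))
    else:
        while done < n_total:
            m = min(chunk, n_total - done)
            perms = _permutation_matrix(sample.n, m, rng, False)
            r = _weighted_pearson_rows(sample.x[perms], sample.y, sample.w)
            count += int(np.sum(np.abs(r) >= abs(observed) - _TIE_TOL))
            done += m
    p, floored = _p_from_count(count, n_total)
    return PermutationResult(
        statistic=observed, n_permutations=n_total, n_exceed=count,
        p=p, floored=floored, exhaustive=exhaustive,
    )


@dataclass
class GLMFit:
    """Weighted least-squares fit of a one- or two-receptor GLM."""

    coef: np.ndarray
    intercept: float

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coef.size:
            X = X.T
        return X @ self.coef + self.intercept


def fit_weighted_glm(predictors, y, weights=None) -> GLMFit:
    """Weighted least squares of y on one or two predictors plus intercept."""
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    if X.shape[1] not in (1, 2):
        raise ValueError("one or two predictors are supported")
    if np.any(np.ptp(X, axis=0) == 0):
        raise SingularDesignError("constant predictor column")
    if X.shape[1] == 2 and abs(np.corrcoef(X[:, 0], X[:, 1])[0, 1]) > 1 - 1e-10:
        raise SingularDesignError("collinear predictor pair")
    fit = sm.WLS(y, sm.add_constant(X), weights=w).fit()
    return GLMFit(coef=np.asarray(fit.params[1:]), intercept=float(fit.params[0]))


def crossval_glm(
    predictors_a, y_a, w_a, predictors_b, y_b, w_b
) -> float:
    """Cross-validated weighted correlation of a receptor GLM.

    The GLM is fit on ROI table A (one participant half) and its prediction
    is correlated, with B's weights, against the held-out values from table
    B.  For one-receptor models the value carries the sign of the fitted
    slope, so anticorrelated receptors report negative wCC(cv).
    """
    fit = fit_weighted_glm(predictors_a, y_a, w_a)
    pred = fit.predict(predictors_b)
    r = weighted_pearson(pred, np.asarray(y_b, dtype=float), w_b)
    if fit.coef.size == 1:
        return float(np.sign(fit.coef[0]) * abs(r))
    return float(r)


def _batched_wls_fit_corr(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """wCC(fitted prediction, y) for a batch of 2-predictor designs.

    ``X`` is (batch, n, 2); solves the weighted normal equations in closed
    form for every design at once.
    """
    batch, n, _ = X.shape
    D = np.concatenate([np.ones((batch, n, 1)), X], axis=2)  # (batch, n, 3)
    Dw = D * w[None, :, None]
    A = np.einsum("bni,bnj->bij", Dw, D)
    rhs = np.einsum("bni,n->bi", Dw, y * 1.0)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    pred = np.einsum("bni,bi->bn", D, beta)
    return _weighted_pearson_rows(pred, y, w)


@dataclass
class SurrogatePairResult:
    """Surrogate-receptor permutation test of a two-receptor GLM."""

    observed: float
    p: dict = field(default_factory=dict)
    floored: dict = field(default_factory=dict)
    n_permutations: int = 0


def surrogate_pair_test(
    r1, r2, y, weights=None, n_perm: int = 10_000, seed=None,
    names: tuple[str, str] = ("r1", "r2"),
) -> SurrogatePairResult:
    """Permutation test of each receptor's contribution to a two-receptor GLM.

    For each receptor in turn: permute its values (keeping the other
    receptor, the DN constant and the weights in place), refit the
    two-predictor GLM, and record the weighted correlation of its fit.  The
    p value is the fraction of surrogate fits whose correlation magnitude
    reaches the true pair's.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.mean()
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")

    fit = fit_weighted_glm(np.column_stack([r1, r2]), y, w)
    observed = weighted_pearson(fit.predict(np.column_stack([r1, r2])), y, w)

    rng = np.random.default_rng(seed)
    exhaustive = math.factorial(n) <= n_perm
    n_total = math.factorial(n) if exhaustive else n_perm

    result = SurrogatePairResult(observed=observed, n_permutations=n_total)
    for name, permuted, fixed, order in (
        (names[0], r1, r2, (0, 1)),
        (names[1], r2, r1, (1, 0)),
    ):
        perms = _permutation_matrix(n, n_total, rng, exhaustive)
        count = 0
        chunk = 20_000
        for start in range(0, perms.shape[0], chunk):
            block = perms[start : start + chunk]
            cols = [None, None]
            cols[order[0]] = permuted[block]
            cols[order[1]] = np.broadcast_to(fixed, (block.shape[0], n))
            X = np.stack(cols, axis=2)
            r = _batched_wls_fit_corr(X, y, w)
            count += int(np.sum(np.abs(r) >= abs(observed) - _TIE_TOL))
        p, floored = _p_from_count(count, n_total)
        result.p[name] = p
        result.floored[name] = floored
    return result


@dataclass
class PCAResult:
    """Principal components of the receptor set.

    ``loadings`` is (receptor x component); ``scores`` (ROI x component);
    components above ``threshold = 1/n_receptors`` explain more variance
    than an even split.  Each component is oriented so its largest-magnitude
    loading is positive.
    """

    loadings: pd.DataFrame
    variance_ratio: np.ndarray
    scores: np.ndarray
    threshold: float

    @property
    def n_above_threshold(self) -> int:
        return int(np.sum(self.variance_ratio > self.threshold))


def pca_receptors(
    receptor_table: pd.DataFrame | np.ndarray, standardize: bool = True
) -> PCAResult:
    """PCA of an (ROI x receptor) density matrix.

    Receptor maps live on different density scales, so columns are z-scored
    by default; pass ``standardize=False`` for a raw-covariance PCA.
    """
    if isinstance(receptor_table, pd.DataFrame):
        names = list(receptor_table.columns)
        X = receptor_table.to_numpy(dtype=float)
    else:
        X = np.asarray(receptor_table, dtype=float)
        names = [f"receptor_{i}" for i in range(X.shape[1])]
    n_roi, n_rec = X.shape
    if n_rec < 2 or n_roi < 3:
        raise ValueError("PCA needs at least 2 receptors and 3 ROIs")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant receptor column cannot be standardized")
        X = (X - X.mean(axis=0)) / sd

    pca = PCA(n_components=n_rec)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # (receptor, component)
    ratio = pca.explained_variance_ratio_.copy()
    # orient each component so its dominant loading is positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=names, columns=cols),
        variance_ratio=ratio,
        scores=scores,
        threshold=1.0 / n_rec,
    )


def component_parameter_scan(
    pca: PCAResult,
    roi_table: ROITable,
    parameters=None,
    n_perm: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Correlate each supra-threshold component with each DN parameter.

    Component ROI scores act as the independent (receptor-derived) variable
    in a weighted correlation + permutation test against every DN parameter
    profile, with the usual ROI weights.  Returns the full scan table.
    """
    if parameters is None:
        parameters = roi_table.param_columns
    w = roi_table.weights
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(pca.scores.shape[1]):
        if pca.variance_ratio[j] <= pca.threshold:
            continue
        comp = pca.scores[:, j]
        for p in parameters:
            y = roi_table.table[p].to_numpy(float)
            if np.unique(y).size < 2:
                # e.g. the normalization constant in the reduced d=1 form
                continue
            res = permutation_test(
                comp, y, w, n_perm=n_perm,
                seed=rng.integers(0, 2**31 - 1),
            )
            rows.append(
                dict(component=f"PC{j + 1}", parameter=p, wcc=res.statistic,
                     p=res.p, p_floored=res.floored)
            )
    return pd.DataFrame(rows)
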