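"""Two-stage (grid then iterative) fitting of Gaussian and DN pRF models.

Fitting follows the standard pRF pipeline: the linear Gaussian model is fit
first (coarse grid search over position and size, then bounded nonlinear
least squares), and its estimates seed the DN model fit (grid search over the
extra constants ``b, d, c`` and the ``sigma2/sigma1`` ratio with position and
size frozen, then an iterative fit over all parameters plus the HRF
derivative weight).  Data are mean-centred per vertex before fitting and all
model predictions are compared after removing their own mean, so the fit is
insensitive to the arbitrary BOLD baseline.

Cross-validated variance explained (cvR2) is computed by fitting each run
separately and evaluating the regenerated prediction -- not refitted
amplitudes -- on the other run, averaging the two directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import least_squares

from .model import DNParams, HRFSpec, _gaussian_flat, hrf_kernel
from .stimulus import StimulusDesign

__all__ = [
    "GridSpec",
    "ParticipantFit",
    "variance_explained",
    "fit_gaussian",
    "fit_dn",
    "crossvalidate_fit",
    "fit_participant",
    "add_derived_columns",
]

FLAG_OK = 0
FLAG_BAD_DATA = 1
FLAG_NO_CONVERGENCE = 2

GAUSS_COLUMNS = ["x0", "y0", "sigma1", "amplitude", "offset", "hrf_weight", "r2", "flag"]
DN_COLUMNS = [
    "x0", "y0", "sigma1", "sigma2", "a", "b", "c", "d",
    "hrf_weight", "offset", "r2", "flag",
]


@dataclass
class GridSpec:
    """Search grids and bounds for the two-stage fit.

    Position candidates form a polar grid (eccentricities x angles); the DN
    grid stage scans ``(b, d, sigma2/sigma1 ratio, c)`` with position and
    size frozen to the Gaussian estimates.  Bounds apply to the iterative
    stages and respect the DN parameter invariants.
    """

    eccentricities: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.1, 8.0, 12)
    )
    polar_angles: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 2 * np.pi, 16, endpoint=False)
    )
    sigmas: np.ndarray = field(default_factory=lambda: np.geomspace(0.2, 6.0, 8))
    b_values: np.ndarray = field(default_factory=lambda: np.geomspace(0.01, 100.0, 6))
    d_values: np.ndarray = field(default_factory=lambda: np.geomspace(0.01, 100.0, 6))
    sigma_ratios: np.ndarray = field(default_factory=lambda: np.array([1.5, 3.0, 6.0]))
    c_values: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-3, 10.0, 5)
    )
    bounds: dict = field(
        default_factory=lambda: {
            "x0": (-10.0, 10.0),
            "y0": (-10.0, 10.0),
            "sigma1": (0.1, 10.0),
            "sigma2": (0.1, 40.0),
            "amplitude": (-1e4, 1e4),
            "a": (1e-6, 1e3),
            "b": (0.0, 1e3),
            "c": (0.0, 1e3),
            "d": (1e-3, 1e3),
            "hrf_weight": (-2.0, 2.0),
        }
    )
    ftol: float = 1e-6
    max_nfev: int = 500
    n_starts: int = 3  # iterative DN restarts from the best grid candidates
    fix_d: bool = False

    def __post_init__(self) -> None:
        for name in ("eccentricities", "polar_angles", "sigmas", "b_values",
                     "d_values", "sigma_ratios", "c_values"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 0:
                raise ValueError(f"grid '{name}' must be non-empty")
            setattr(self, name, arr)

    @classmethod
    def for_extent(cls, extent: float, **kwargs) -> "GridSpec":
        """Default grids scaled to a stimulus extent in degrees."""
        spec = cls(**kwargs)
        spec.eccentricities = np.geomspace(0.1, extent, 12)
        spec.sigmas = np.geomspace(0.025 * extent, 0.75 * extent, 8)
        spec.bounds = dict(spec.bounds)
        spec.bounds["x0"] = (-1.25 * extent, 1.25 * extent)
        spec.bounds["y0"] = (-1.25 * extent, 1.25 * extent)
        return spec


@dataclass
class ParticipantFit:
    """Per-vertex DN fits for one participant (two-run protocol).

    ``table`` has one row per vertex: DN parameters + HRF weight from the fit
    to the run average, training R2 (average fit and each single-run fit),
    cvR2, a status flag, and derived canonical ratios.  Vertices with
    cvR2 <= 0 keep their parameters but are non-contributing downstream.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if np.any(self.table["cv_r2"].to_numpy() > 1 + 1e-12):
            raise ValueError("cvR2 cannot exceed 1")

    @property
    def n_vertices(self) -> int:
        return len(self.table)

    @property
    def cv_r2(self) -> np.ndarray:
        return self.table["cv_r2"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="vertex")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParticipantFit":
        return cls(pd.read_csv(path, sep="\t", index_col="vertex"))


def variance_explained(data: np.ndarray, prediction: np.ndarray) -> float:
    """R2 = 1 - SS_residual / SS_total, SS_total about the data mean.

    May be negative for predictions worse than the mean.
    """
    data = np.asarray(data, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if data.shape != prediction.shape:
        raise ValueError("data and prediction must have equal length")
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("variance explained undefined for constant data")
    ss_res = float(np.sum((data - prediction) ** 2))
    return 1.0 - ss_res / ss_tot


def _center(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return x - x.mean(axis=axis, keepdims=True)


def _convolve_rows(neural: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve each row with the kernel, truncated to the row length."""
    n_t = neural.shape[-1]
    full = signal.fftconvolve(neural, kernel[None, :], axes=-1)
    return full[..., :n_t]


def _gaussian_node_predictions(
    design: StimulusDesign, grid: GridSpec, kernel: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All (position, sigma) node predictions, centred. Returns (nodes, preds)."""
    ecc, ang = np.meshgrid(grid.eccentricities, grid.polar_angles, indexing="ij")
    x0 = (ecc * np.cos(ang)).ravel()
    y0 = (ecc * np.sin(ang)).ravel()
    nodes = []
    preds = []
    fm_t = design.frame_matrix.T  # (npix, T)
    for sig in grid.sigmas:
        dx = design.grid.pixel_x[:, None] - x0[None, :]
        dy = design.grid.pixel_y[:, None] - y0[None, :]
        fields = np.exp(-(dx * dx + dy * dy) / (2.0 * sig * sig))  # (npix, P)
        drives = fields.T @ fm_t  # (P, T)
        preds.append(_convolve_rows(drives, kernel))
        nodes.append(np.column_stack([x0, y0, np.full(x0.size, sig)]))
    nodes = np.concatenate(nodes)
    preds = _center(np.concatenate(preds))
    return nodes, preds


def _gauss_pred(design, kernels, x0, y0, sig, w):
    drive = design.frame_matrix @ _gaussian_flat(x0, y0, sig, design.grid)
    return _convolve_rows(drive[None, :], kernels(w))[0]


class _KernelCache:
    """HRF kernels are cheap but evaluated thousands of times; memoize."""

    def __init__(self, dt: float, duration: float = 32.0):
        self.dt = dt
        self.duration = duration
        self._cache: dict[float, np.ndarray] = {}

    def __call__(self, w: float) -> np.ndarray:
        key = round(float(w), 12)
        if key not in self._cache:
            if len(self._cache) > 4096:
                self._cache.clear()
            self._cache[key] = hrf_kernel(
                HRFSpec(deriv_weight=key, dt=self.dt, duration=self.duration)
            )
        return self._cache[key]


def _prepare_data(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    means = data.mean(axis=1)
    centred = data - means[:, None]
    bad = np.ptp(data, axis=1) == 0
    return centred, means, bad


def fit_gaussian(
    data: np.ndarray,
    design: StimulusDesign,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Fit the linear Gaussian pRF model to each vertex (grid + iterative).

    ``data`` is (vertices, time).  Returns a DataFrame with columns
    ``x0, y0, sigma1, amplitude, offset, hrf_weight, r2, flag``.
    Constant/all-zero vertices are flagged, not dropped.
    """
    if grid is None:
        grid = GridSpec.for_extent(design.grid.extent)
    kernels = _KernelCache(design.frame_duration)
    centred, means, bad = _prepare_data(data)
    if centred.shape[1] != design.n_frames:
        raise ValueError("data length must equal the design frame count")
    n_v = centred.shape[0]

    nodes, node_preds = _gaussian_node_predictions(design, grid, kernels(0.0))
    node_norms = np.linalg.norm(node_preds, axis=1)
    node_norms[node_norms == 0] = np.inf
    data_norms = np.linalg.norm(centred, axis=1)
    safe_dnorm = np.where(data_norms == 0, np.inf, data_norms)

    # localization by magnitude: a suppression-dominated time course can
    # anticorrelate with its own positive Gaussian prediction, but position
    # information is in |corr|; the signed amplitude is kept for the DN seed
    corr = (centred / safe_dnorm[:, None]) @ (node_preds / node_norms[:, None]).T
    best = np.argmax(np.abs(corr), axis=1)

    lb = [grid.bounds[k][0] for k in ("x0", "y0", "sigma1", "amplitude", "hrf_weight")]
    ub = [grid.bounds[k][1] for k in ("x0", "y0", "sigma1", "amplitude", "hrf_weight")]

    out = np.full((n_v, len(GAUSS_COLUMNS)), np.nan)
    for v in range(n_v):
        if bad[v]:
            out[v, -1] = FLAG_BAD_DATA
            continue
        dc = centred[v]
        j = best[v]
        x0, y0, sig = nodes[j]
        amp = corr[v, j] * data_norms[v] / node_norms[j]
        if abs(amp) < 1e-5:
            amp = 1e-5
        if amp < 0:
            # suppression-dominated vertex: the dips localize the pRF (the
            # negated signal resembles a Gaussian of the normalization-pool
            # width), but refining a negative Gaussian drifts off-centre.
            # Keep the grid node; the DN stage refines all parameters.
            out[v] = [x0, y0, sig, amp, means[v], 0.0, corr[v, j] ** 2, FLAG_OK]
            continue
        p0 = np.clip([x0, y0, sig, amp, 0.0], np.array(lb) + 1e-9, np.array(ub) - 1e-9)

        def resid(p):
            pred = _gauss_pred(design, kernels, p[0], p[1], p[2], p[4])
            return dc - p[3] * (pred - pred.mean())

        res = least_squares(
            resid, p0, bounds=(lb, ub), method="trf",
            ftol=grid.ftol, max_nfev=grid.max_nfev,
            x_scale=[1.0, 1.0, 0.5, max(abs(amp), 0.1), 0.25],
        )
        ss_tot = data_norms[v] ** 2
        r2 = 1.0 - float(np.sum(res.fun**2)) / ss_tot
        flag = FLAG_OK if res.status > 0 else FLAG_NO_CONVERGENCE
        # offset stores the removed per-vertex data mean
        out[v] = [*res.x[:4], means[v], res.x[4], r2, flag]
    df = pd.DataFrame(out, columns=GAUSS_COLUMNS)
    df["flag"] = df["flag"].fillna(FLAG_BAD_DATA).astype(int)
    return df


def _dn_pred_centred(design, kernels, x0, y0, s1, s2, a, b, c, d, w):
    fm = design.frame_matrix
    d1 = fm @ _gaussian_flat(x0, y0, s1, design.grid)
    d2 = fm @ _gaussian_flat(x0, y0, s2, design.grid)
    neural = (a * d1 + b) / (c * d2 + d) - b / d
    pred = _convolve_rows(neural[None, :], kernels(w))[0]
    return pred - pred.mean()


def _dn_grid_stage(dc, design, kernels, x0, y0, s1, w, grid, n_starts=2,
                   inverted=False):
    """Scan (sigma1 scaling, b, d, ratio, c) with position frozen.

    The Gaussian-stage size is biased low under divisive-normalization data
    (the suppressive surround mimics a narrow pRF), so candidate starts also
    inflate sigma1.  For suppression-dominated vertices (``inverted``) the
    Gaussian stage instead localized the normalization-pool width, so the
    candidates deflate sigma1 by the ratio grid.  Returns the ``n_starts``
    best-correlating candidates from distinct (sigma1, ratio) cells.
    """
    fm = design.frame_matrix
    b = grid.b_values[:, None, None, None]
    d = np.array([1.0]) if grid.fix_d else grid.d_values
    d_b = d[None, :, None, None]
    c_b = grid.c_values[None, None, :, None]
    kernel = kernels(w)
    dc_norm = np.linalg.norm(dc)

    if inverted:
        ladder = tuple(s1 / r for r in grid.sigma_ratios)
    else:
        ladder = (s1, 2.0 * s1, 4.0 * s1)
    candidates = []
    for s1_cand in ladder:
        d1 = fm @ _gaussian_flat(x0, y0, s1_cand, design.grid)
        for ratio in grid.sigma_ratios:
            d2 = fm @ _gaussian_flat(x0, y0, ratio * s1_cand, design.grid)
            neural = (d1[None, None, None, :] + b) / (
                c_b * d2[None, None, None, :] + d_b
            )
            neural = neural - (b / d_b)
            shape = neural.shape[:3]
            preds = _center(_convolve_rows(neural.reshape(-1, neural.shape[-1]), kernel))
            norms = np.linalg.norm(preds, axis=1)
            norms[norms == 0] = np.inf
            corr = (preds / norms[:, None]) @ (dc / dc_norm)
            j = int(np.argmax(corr))
            ib, id_, ic = np.unravel_index(j, shape)
            gain = max(corr[j] * dc_norm / norms[j], 1e-5)
            candidates.append(
                (
                    float(corr[j]),
                    dict(
                        sigma1=s1_cand,
                        a=gain,
                        b=gain * grid.b_values[ib],
                        c=grid.c_values[ic],
                        d=float(d[id_]),
                        sigma2=ratio * s1_cand,
                    ),
                )
            )
    candidates.sort(key=lambda t: -t[0])
    return [c[1] for c in candidates[:n_starts]]


def fit_dn(
    data: np.ndarray,
    design: StimulusDesign,
    grid: GridSpec | None = None,
    gaussian_fit: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit the DN model per vertex, seeded by Gaussian estimates.

    Grid stage scans the DN constants with position/size frozen to the
    Gaussian fit; the iterative stage refines all eight DN parameters plus
    the HRF derivative weight.  The DN model nests the Gaussian model, so a
    Gaussian-equivalent start is retried whenever the refined fit would fall
    below the Gaussian R2.
    """
    if grid is None:
        grid = GridSpec.for_extent(design.grid.extent)
    if gaussian_fit is None:
        gaussian_fit = fit_gaussian(data, design, grid)
    kernels = _KernelCache(design.frame_duration)
    centred, means, bad = _prepare_data(data)
    n_v = centred.shape[0]

    names = ["x0", "y0", "sigma1", "sigma2", "a", "b", "c", "d", "hrf_weight"]
    if grid.fix_d:
        names = names[:7] + ["hrf_weight"]
    lb = np.array([grid.bounds[n][0] for n in names])
    ub = np.array([grid.bounds[n][1] for n in names])

    out = np.full((n_v, len(DN_COLUMNS)), np.nan)
    for v in range(n_v):
        g = gaussian_fit.iloc[v]
        if bad[v] or g["flag"] == FLAG_BAD_DATA or not np.isfinite(g["x0"]):
            out[v, -1] = FLAG_BAD_DATA
            continue
        dc = centred[v]
        ss_tot = float(np.sum(dc**2))
        grid_starts = _dn_grid_stage(
            dc, design, kernels, g["x0"], g["y0"], g["sigma1"], g["hrf_weight"],
            grid, n_starts=grid.n_starts, inverted=g["amplitude"] < 0,
        )
        starts = [
            [g["x0"], g["y0"], s["sigma1"], s["sigma2"], s["a"],
             s["b"], s["c"], s["d"], g["hrf_weight"]]
            for s in grid_starts
        ]
        if g["amplitude"] >= 0:
            # Gaussian-equivalent start (b=c=0, d=1): guarantees nesting.
            starts.append(
                [g["x0"], g["y0"], g["sigma1"], 1.5 * g["sigma1"], g["amplitude"],
                 0.0, 0.0, 1.0, g["hrf_weight"]]
            )
        else:
            # inverted-Gaussian equivalent: with a -> 0 and c*D2 << d the DN
            # response tends to -(b*c/d^2) * D2, i.e. a negative-going
            # Gaussian drive of width sigma2; pick c so c*D2 stays small
            s_g = g["sigma1"]
            full_drive = 2.0 * np.pi * s_g**2 / design.grid.spacing**2
            c0 = min(0.05 / full_drive, 1.0)
            starts.append(
                [g["x0"], g["y0"], s_g, s_g, 1e-5,
                 -g["amplitude"] / c0, c0, 1.0, g["hrf_weight"]]
            )

        def resid(p):
            if grid.fix_d:
                x0, y0, s1, s2, a, b, c, w = p
                d = 1.0
            else:
                x0, y0, s1, s2, a, b, c, d, w = p
            return dc - _dn_pred_centred(design, kernels, x0, y0, s1, s2, a, b, c, d, w)

        best_res, best_cost = None, np.inf
        gauss_r2 = float(g["r2"])
        for k, p_full in enumerate(starts):
            p0 = p_full[:7] + [p_full[8]] if grid.fix_d else p_full
            p0 = np.clip(np.asarray(p0, float), lb + 1e-9 * (ub - lb), ub - 1e-9 * (ub - lb))
            scale = np.maximum(np.abs(p0), [0.5, 0.5, 0.2, 0.5, 0.05, 0.02, 0.02, 0.02, 0.25][: p0.size])
            res = least_squares(
                resid, p0, bounds=(lb, ub), method="trf",
                ftol=grid.ftol, max_nfev=grid.max_nfev, x_scale=scale,
            )
            if res.cost < best_cost:
                best_res, best_cost = res, res.cost
            # the Gaussian fallback start only matters if nesting is violated
            if k == len(starts) - 2 and 1.0 - 2 * best_cost / ss_tot >= gauss_r2 - 1e-6:
                break
        res = best_res
        r2 = 1.0 - float(np.sum(res.fun**2)) / ss_tot
        if grid.fix_d:
            x0, y0, s1, s2, a, b, c, w = res.x
            d = 1.0
        else:
            x0, y0, s1, s2, a, b, c, d, w = res.x
        flag = FLAG_OK if res.status > 0 else FLAG_NO_CONVERGENCE
        out[v] = [x0, y0, s1, s2, a, b, c, d, w, means[v], r2, flag]
    df = pd.DataFrame(out, columns=DN_COLUMNS)
    df["flag"] = df["flag"].fillna(FLAG_BAD_DATA).astype(int)
    return df


def _dn_predictions(fit: pd.DataFrame, design: StimulusDesign) -> np.ndarray:
    """Centred predictions regenerated from fitted parameters."""
    kernels = _KernelCache(design.frame_duration)
    preds = np.zeros((len(fit), design.n_frames))
    for i, (_, row) in enumerate(fit.iterrows()):
        if row["flag"] == FLAG_BAD_DATA or not np.isfinite(row["x0"]):
            continue
        preds[i] = _dn_pred_centred(
            design, kernels, row["x0"], row["y0"], row["sigma1"], row["sigma2"],
            row["a"], row["b"], row["c"], row["d"], row["hrf_weight"],
        )
    return preds


def _r2_rows(data_centred: np.ndarray, preds: np.ndarray) -> np.ndarray:
    ss_tot = np.sum(data_centred**2, axis=1)
    ss_tot[ss_tot == 0] = np.nan
    return 1.0 - np.sum((data_centred - preds) ** 2, axis=1) / ss_tot


def crossvalidate_fit(
    run1: np.ndarray,
    run2: np.ndarray,
    design: StimulusDesign,
    grid: GridSpec | None = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Per-vertex cvR2: fit each run, evaluate on the other, average.

    Returns ``(cv_r2, fit_run1, fit_run2)``.  Predictions are regenerated
    from the fitted parameter vectors (including the HRF weight).
    """
    run1 = np.atleast_2d(np.asarray(run1, float))
    run2 = np.atleast_2d(np.asarray(run2, float))
    if run1.shape != run2.shape:
        raise ValueError("runs must share vertex set and length")
    fit1 = fit_dn(run1, design, grid)
    fit2 = fit_dn(run2, design, grid)
    r2_21 = _r2_rows(_center(run2), _dn_predictions(fit1, design))
    r2_12 = _r2_rows(_center(run1), _dn_predictions(fit2, design))
    cv = 0.5 * (r2_21 + r2_12)
    return cv, fit1, fit2


def fit_participant(
    run1: np.ndarray,
    run2: np.ndarray,
    design: StimulusDesign,
    grid: GridSpec | None = None,
) -> ParticipantFit:
    """Full two-run protocol for one participant.

    Parameters come from the fit to the run average (best SNR); cvR2 from
    separate single-run fits evaluated out of sample.
    """
    run1 = np.atleast_2d(np.asarray(run1, float))
    run2 = np.atleast_2d(np.asarray(run2, float))
    if run1.shape != run2.shape:
        raise ValueError("exactly two runs sharing vertex set and length required")
    if grid is None:
        grid = GridSpec.for_extent(design.grid.extent)
    mean_run = 0.5 * (run1 + run2)
    dn = fit_dn(mean_run, design, grid)
    cv, fit1, fit2 = crossvalidate_fit(run1, run2, design, grid)
    table = dn.rename(columns={"r2": "r2_train"}).copy()
    table["r2_run1"] = fit1["r2"].to_numpy()
    table["r2_run2"] = fit2["r2"].to_numpy()
    table["cv_r2"] = cv
    table = add_derived_columns(table)
    return ParticipantFit(table=table)


def add_derived_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Attach canonical ratios and retinotopic coordinates.

    Ratios (b/d, a/d, c/d) are the scale-invariant quantities used for all
    downstream comparisons.
    """
    table = table.copy()
    table["bd"] = table["b"] / table["d"]
    table["ad"] = table["a"] / table["d"]
    table["cd"] = table["c"] / table["d"]
    table["ecc"] = np.hypot(table["x0"], table["y0"])
    table["polar"] = np.arctan2(table["y0"], table["x0"])
    return table
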