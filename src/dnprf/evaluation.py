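"""Study-level evaluation benchmarks.

Self-contained, seeded routines that measure the package's end-to-end
behaviour on synthetic studies with planted ground truth: forward-model
algebra, parameter recovery, cross-validation contracts, statistical
calibration, and full-chain sign recovery.  Each returns a flat dict of
scalar measurements plus the problem size used.
"""

from __future__ import annotations

import math
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

from .aggregation import group_parameter_map, li_threshold, roi_summaries
from .fitting import GridSpec, crossvalidate_fit, fit_dn, fit_gaussian
from .model import DNParams, HRFSpec, drive_timecourse, gaussian_field, hrf_kernel, predict_bold
from .stats import (
    crossval_glm,
    pca_receptors,
    permutation_test,
    surrogate_pair_test,
    weighted_pearson,
)
from .stimulus import make_bar_sequence, make_grid
from .synth import (
    TruthSpec,
    latent_factor_receptor_set,
    make_truth,
    planted_receptor_set,
    simulate_participant_estimates,
    simulate_participants,
    simulate_receptors,
)

__all__ = [
    "forward_model_algebra",
    "gaussian_limit_deviation",
    "parameter_recovery",
    "crossvalidation_contract",
    "weighted_correlation_oracle",
    "permutation_calibration",
    "two_receptor_logic",
    "li_threshold_oracle",
    "pca_recovery",
    "end_to_end_sign_recovery",
]


def _small_design(n_pixels=21, steps=6, blanks=1):
    return make_bar_sequence(
        make_grid(8.0, n_pixels), steps_per_pass=steps, blank_frames=blanks
    )


def forward_model_algebra(seed: int, n_draws: int = 1000) -> dict:
    """Scale invariance and d=1 reduction of the DN prediction.

    Maximum absolute prediction deviation over random parameter draws and
    scale factors in {0.1, 1, 10}, on a compact bar design.
    """
    rng = np.random.default_rng(seed)
    design = _small_design()
    max_scale = 0.0
    max_reduced = 0.0
    for _ in range(n_draws):
        p = DNParams(
            x0=rng.uniform(-5, 5), y0=rng.uniform(-5, 5),
            sigma1=rng.uniform(0.3, 3.0), sigma2=rng.uniform(0.5, 8.0),
            a=rng.lognormal(0, 1), b=rng.lognormal(0, 1) * rng.integers(0, 2),
            c=rng.lognormal(-3, 1), d=rng.lognormal(0, 1),
        )
        hrf = HRFSpec(deriv_weight=rng.uniform(-0.5, 1.0), dt=design.frame_duration)
        base = predict_bold(p, design, hrf)
        scale = np.abs(base).max() or 1.0
        lam = float(rng.choice([0.1, 1.0, 10.0]))
        max_scale = max(
            max_scale, np.abs(base - predict_bold(p.scaled(lam), design, hrf)).max() / scale
        )
        max_reduced = max(
            max_reduced, np.abs(base - predict_bold(p.reduced(), design, hrf)).max() / scale
        )
    return {
        "scale_invariance_max_abs_dev": max_scale,
        "reduced_d1_max_abs_dev": max_reduced,
        "n": n_draws,
    }


def gaussian_limit_deviation(seed: int, n_draws: int = 200) -> dict:
    """With b=0, c=0, d=1 the DN prediction equals the linear Gaussian one."""
    from scipy.signal import convolve

    rng = np.random.default_rng(seed)
    design = _small_design()
    kernel = hrf_kernel(HRFSpec(dt=design.frame_duration))
    worst = 0.0
    for _ in range(n_draws):
        x0, y0 = rng.uniform(-5, 5, 2)
        s1 = rng.uniform(0.3, 3.0)
        a = rng.lognormal(0, 1)
        dn = predict_bold(
            DNParams(x0, y0, s1, 2 * s1, a=a, b=0.0, c=0.0, d=1.0), design
        )
        drive = drive_timecourse(gaussian_field(x0, y0, s1, design.grid), design)
        linear = a * convolve(drive, kernel)[: design.n_frames]
        scale = np.abs(linear).max() or 1.0
        worst = max(worst, np.abs(dn - linear).max() / scale)
    return {"gaussian_limit_max_abs_dev": worst, "n": n_draws}


def parameter_recovery(
    seed: int, n_rois: int = 8, vertices_per_roi: int = 25, snr: float = 3.0
) -> dict:
    """Simulate-then-fit recovery of DN parameters at the study noise level.

    Two runs per vertex; parameters fitted on the run average.  Reports
    median absolute errors: positions in degrees, sigma1 and the canonical
    ratios b/d, a/d in percent.
    """
    design = make_bar_sequence(make_grid(8.0, 50))
    spec = TruthSpec(n_rois=n_rois, vertices_per_roi=vertices_per_roi,
                     jitter_sd=0.1, seed=seed)
    truth = make_truth(spec)
    part = simulate_participants(
        truth, design, 1, snr=snr, seed=seed + 1, hrf_weight=0.25
    )[0]
    data = 0.5 * (part.run1 + part.run2)
    tt = part.params
    gfit = fit_gaussian(data, design)
    fit = fit_dn(data, design, gaussian_fit=gfit)
    return {
        "recovery_median_x0_err_deg": float((fit.x0 - tt.x0).abs().median()),
        "recovery_median_y0_err_deg": float((fit.y0 - tt.y0).abs().median()),
        "recovery_median_sigma1_err_pct": float(
            (100 * (fit.sigma1 / tt.sigma1 - 1).abs()).median()
        ),
        "recovery_median_bd_err_pct": float(
            (100 * ((fit.b / fit.d) / (tt.b / tt.d) - 1).abs()).median()
        ),
        "recovery_median_ad_err_pct": float(
            (100 * ((fit.a / fit.d) / (tt.a / tt.d) - 1).abs()).median()
        ),
        "n": n_rois * vertices_per_roi,
    }


def crossvalidation_contract(
    seed: int, n_signal: int = 24, n_noise: int = 16, snr: float = 3.0
) -> dict:
    """cvR2 versus training R2 on two-run data; pure noise goes non-positive."""
    design = make_bar_sequence(make_grid(8.0, 40), steps_per_pass=12, blank_frames=2)
    spec = TruthSpec(
        n_rois=4, vertices_per_roi=n_signal // 4, jitter_sd=0.1, seed=seed,
        design_pixels=40,
    )
    truth = make_truth(spec)
    part = simulate_participants(truth, design, 1, snr=snr, seed=seed + 1)[0]
    cv, fit1, fit2 = crossvalidate_fit(part.run1, part.run2, design)
    train = 0.5 * (fit1.r2.to_numpy() + fit2.r2.to_numpy())

    rng = np.random.default_rng(seed + 2)
    noise1 = rng.normal(size=(n_noise, design.n_frames))
    noise2 = rng.normal(size=(n_noise, design.n_frames))
    cv_noise, _, _ = crossvalidate_fit(noise1, noise2, design)
    return {
        "cv_minus_train_mean": float(np.nanmean(cv) - np.nanmean(train)),
        "cv_mean_signal": float(np.nanmean(cv)),
        "train_mean_signal": float(np.nanmean(train)),
        "cv_mean_pure_noise": float(np.nanmean(cv_noise)),
        "n": n_signal + n_noise,
    }


def weighted_correlation_oracle(seed: int, n_samples: int = 200) -> dict:
    """Unit-weight equivalence with the classical correlation + the worked
    three-point weighted example."""
    from scipy.stats import pearsonr

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_samples):
        x, y = rng.normal(size=(2, 12))
        worst = max(worst, abs(weighted_pearson(x, y) - pearsonr(x, y)[0]))
    example = weighted_pearson([1, 2, 3], [1, 2, 2], [1, 1, 2])
    return {
        "unit_weight_max_abs_dev": worst,
        "weighted_example_wcc": float(example),
        "n": n_samples,
    }


def permutation_calibration(
    seed: int, n_datasets: int = 1000, n_perm: int = 1000, n_rois: int = 20
) -> dict:
    """False-positive calibration under an independent-receptor null, plus
    exhaustive-mode equality with explicit enumeration at n=5."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for k in range(n_datasets):
        x, y = rng.normal(size=(2, n_rois))
        w = rng.uniform(0.1, 1.0, n_rois)
        res = permutation_test(x, y, w, n_perm=n_perm, seed=int(rng.integers(2**31)))
        if res.p < 0.05:
            rejections += 1

    x, y = rng.normal(size=(2, 5))
    w = rng.uniform(0.2, 1.0, 5)
    res = permutation_test(x, y, w, n_perm=10**4, seed=0)
    obs = abs(weighted_pearson(x, y, w))
    count = sum(
        abs(weighted_pearson(x[list(p)], y, w)) >= obs - 1e-12
        for p in iter_permutations(range(5))
    )
    return {
        "perm_rejection_rate_alpha05": rejections / n_datasets,
        "perm_exhaustive_abs_dev": abs(res.p - count / 120),
        "n": n_datasets,
    }


def two_receptor_logic(
    seed: int, n_replicates: int = 200, n_rois: int = 20, noise_sd: float = 0.4
) -> dict:
    """Planted two-receptor generative model: the cross-validated two-receptor
    GLM beats both one-receptor models, and surrogate-pair permutation tests
    flag both true receptors."""
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_replicates):
        r1, r2 = rng.normal(size=(2, n_rois))
        w_a = rng.uniform(0.2, 0.8, n_rois)
        w_b = rng.uniform(0.2, 0.8, n_rois)
        y_a = r1 - r2 + noise_sd * rng.normal(size=n_rois)
        y_b = r1 - r2 + noise_sd * rng.normal(size=n_rois)
        X = np.column_stack([r1, r2])
        two = crossval_glm(X, y_a, w_a, X, y_b, w_b)
        one = max(
            abs(crossval_glm(r1, y_a, w_a, r1, y_b, w_b)),
            abs(crossval_glm(r2, y_a, w_a, r2, y_b, w_b)),
        )
        if two > one:
            wins += 1

    r1, r2 = rng.normal(size=(2, n_rois))
    y = r1 - r2 + 0.2 * rng.normal(size=n_rois)
    surro = surrogate_pair_test(r1, r2, y, n_perm=10**4, seed=int(rng.integers(2**31)),
                                names=("r1", "r2"))
    return {
        "two_receptor_gain_rate": wins / n_replicates,
        "surrogate_p_r1": surro.p["r1"],
        "surrogate_p_r2": surro.p["r2"],
        "n": n_replicates,
    }


def li_threshold_oracle(seed: int, n_histograms: int = 100) -> dict:
    """Agreement of the Li threshold with a naive brute-force candidate scan."""
    rng = np.random.default_rng(seed)
    agree = 0
    tested = 0
    while tested < n_histograms:
        lo = rng.integers(0, 8)
        hi = rng.integers(15, 60)
        counts = np.concatenate([
            rng.poisson(lo, rng.integers(30, 120)),
            rng.poisson(hi, rng.integers(30, 120)),
        ]).astype(float)
        if np.unique(counts).size < 2:
            continue
        tested += 1
        th = li_threshold(counts)
        uniq = np.unique(counts)
        best_cut, best_ce = None, np.inf
        for cut in 0.5 * (uniq[:-1] + uniq[1:]):
            low, high = counts[counts <= cut], counts[counts > cut]
            ce = 0.0
            for part in (low, high):
                if part.size and part.mean() > 0:
                    ce -= part.sum() * np.log(part.mean())
            if ce < best_ce:
                best_cut, best_ce = cut, ce
        agree += th == best_cut
    return {"li_oracle_agreement_rate": agree / n_histograms, "n": n_histograms}


def pca_recovery(seed: int, n_replicates: int = 50, n_rois: int = 20) -> dict:
    """Two-latent-factor receptor construction: exactly the top two principal
    components exceed the 1/6 equivariance threshold."""
    rng = np.random.default_rng(seed)
    exact_two = 0
    worst_sum_dev = 0.0
    for _ in range(n_replicates):
        truth = make_truth(TruthSpec(n_rois=n_rois, vertices_per_roi=1,
                                     seed=int(rng.integers(2**31))))
        rec = simulate_receptors(
            truth, latent_factor_receptor_set(), within_roi_sd=0.0,
            seed=int(rng.integers(2**31)),
        )
        res = pca_receptors(rec)
        exact_two += res.n_above_threshold == 2
        worst_sum_dev = max(worst_sum_dev, abs(res.variance_ratio.sum() - 1.0))
    return {
        "pca_exact_two_components_rate": exact_two / n_replicates,
        "pca_variance_sum_max_abs_dev": worst_sum_dev,
        "n": n_replicates,
    }


_PLANTED_PAIRS = [("bd", "GABA", +1), ("bd", "5HT1A", -1),
                  ("d", "5HT1B", +1), ("d", "5HT2A", -1)]


def end_to_end_sign_recovery(
    seed: int, n_replicates: int = 20, rho: float = 0.65,
    n_rois: int = 20, vertices_per_roi: int = 25, n_participants: int = 40,
) -> dict:
    """Default synthetic study through the aggregation/statistics chain.

    Participant parameter estimates are aggregated into cvR2-weighted group
    maps with the Li inclusion mask, summarized per ROI, and correlated with
    the planted receptor maps.  Reports the rate at which all four planted
    correlation signs are recovered, and the mean recovered magnitude for
    the planted |wCC| = rho.
    """
    rng = np.random.default_rng(seed)
    all_signs = 0
    wccs = []
    for _ in range(n_replicates):
        truth = make_truth(TruthSpec(n_rois=n_rois, vertices_per_roi=vertices_per_roi,
                                     seed=int(rng.integers(2**31))))
        fits = simulate_participant_estimates(
            truth, n_participants, seed=int(rng.integers(2**31))
        )
        receptors = simulate_receptors(
            truth, planted_receptor_set(rho), seed=int(rng.integers(2**31))
        )
        gm = group_parameter_map(fits)
        roi = roi_summaries(gm, truth.roi.to_numpy(), receptors)
        ok = True
        for param, receptor, sign in _PLANTED_PAIRS:
            r = weighted_pearson(
                roi.table[receptor].to_numpy(float),
                roi.table[param].to_numpy(float),
                roi.weights,
            )
            wccs.append(abs(r))
            ok &= np.sign(r) == sign
        all_signs += ok
    return {
        "sign_pattern_recovery_rate": all_signs / n_replicates,
        "mean_recovered_abs_wcc": float(np.mean(wccs)),
        "planted_wcc": rho,
        "n": n_replicates,
    }
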