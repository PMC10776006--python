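"""Synthetic studies with planted ground truth.

Generates everything the pipeline consumes without any download: a
visual-hierarchy-like sequence of ROIs with monotone across-ROI gradients in
the DN constants (activation ratio b/d and normalization constant d both
decreasing from early to late ROIs, emulating the early->late
suppression/compression gradient), per-vertex parameter jitter, participant
perturbations, two-run BOLD time courses from the forward model plus noise,
and receptor density maps built as linear functions of the planted DN
quantities (or of two latent factors, for PCA tests) plus noise.

Two participant models are available: ``"bold"`` simulates and expects full
time-course fitting; ``"estimates"`` draws per-participant parameter
estimates (truth + participant effect + estimation noise) together with a
plausible cvR2 map, so the aggregation/statistics chain can be exercised at
study scale without hours of nonlinear fitting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import ParticipantFit, add_derived_columns
from .model import DNParams, HRFSpec, predict_bold
from .stimulus import StimulusDesign, make_bar_sequence, make_grid, save_design

__all__ = [
    "TruthSpec",
    "ReceptorSpec",
    "StudyConfig",
    "make_truth",
    "simulate_participants",
    "simulate_participant_estimates",
    "simulate_receptors",
    "planted_receptor_set",
    "latent_factor_receptor_set",
    "make_dataset",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class TruthSpec:
    """Ground-truth layout of a synthetic study.

    ROI-level gradients are geometric sequences from the first to the last
    ROI; vertices add multiplicative log-normal jitter (sd ``jitter_sd``, in
    log units) on positive parameters and Gaussian jitter on positions.
    """

    n_rois: int = 20
    vertices_per_roi: int = 25
    extent: float = 8.0
    bd_range: tuple[float, float] = (2.0, 0.1)
    d_range: tuple[float, float] = (3.0, 0.3)
    sigma1_range: tuple[float, float] = (0.5, 3.0)
    sigma_ratio: float = 2.5
    a: float = 1.0
    # normalization-pool drive at full field, as a multiple of d: the
    # amplitude c is set per vertex so that c * (full-field sigma2 drive)
    # ~= norm_drive_ratio * d, keeping the normalization constant visible
    # in the response (neither negligible nor saturated)
    norm_drive_ratio: float = 3.0
    design_pixels: int = 50
    bar_width: float = 2.0
    ecc_range: tuple[float, float] = (1.0, 6.0)
    jitter_sd: float = 0.1
    position_jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("jitter_sd", "position_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def make_truth(spec: TruthSpec) -> pd.DataFrame:
    """Per-vertex ground-truth DN parameters with ROI labels.

    ROI centres sit at log-spaced eccentricities rotating by the golden
    angle; b/d, d and sigma1 follow geometric across-ROI gradients.  Jittered
    positions are projected back inside 0.9 x extent so every pRF is driven
    by the stimulus.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rois * spec.vertices_per_roi
    roi = np.repeat(np.arange(1, spec.n_rois + 1), spec.vertices_per_roi)

    bd_roi = np.geomspace(*spec.bd_range, spec.n_rois)
    d_roi = np.geomspace(*spec.d_range, spec.n_rois)
    s1_roi = np.geomspace(*spec.sigma1_range, spec.n_rois)
    ecc_roi = np.geomspace(*spec.ecc_range, spec.n_rois)
    ang_roi = GOLDEN_ANGLE * np.arange(spec.n_rois)

    def jitter_pos(base: np.ndarray) -> np.ndarray:
        if spec.jitter_sd == 0:
            return base
        return base * rng.lognormal(0.0, spec.jitter_sd, size=base.size)

    bd = jitter_pos(np.repeat(bd_roi, spec.vertices_per_roi))
    d = jitter_pos(np.repeat(d_roi, spec.vertices_per_roi))
    s1 = jitter_pos(np.repeat(s1_roi, spec.vertices_per_roi))
    # pixel-sum drives scale as 2*pi*sigma^2 / spacing^2; pick c so the
    # full-field normalization drive is norm_drive_ratio * d, and a so the
    # peak positive response is O(spec.a) regardless of pRF size and of the
    # suppression strength b/d (early-visual-like vertices then show positive
    # responses larger than their below-baseline flanks)
    from scipy.special import erf

    spacing = 2.0 * spec.extent / (spec.design_pixels - 1)
    s2 = spec.sigma_ratio * s1
    full_drive2 = 2.0 * np.pi * s2**2 / spacing**2
    full_drive1 = 2.0 * np.pi * s1**2 / spacing**2
    # fraction of each Gaussian covered by a centred bar of the design width
    f1 = erf(spec.bar_width / (2.0 * np.sqrt(2.0) * s1))
    f2 = erf(spec.bar_width / (2.0 * np.sqrt(2.0) * s2))
    kappa = spec.norm_drive_ratio
    c = jitter_pos(kappa * d / full_drive2)
    a = jitter_pos(
        d * ((spec.a + bd) * (1.0 + kappa * f2) - bd) / (f1 * full_drive1)
    )

    x0 = np.repeat(ecc_roi * np.cos(ang_roi), spec.vertices_per_roi)
    y0 = np.repeat(ecc_roi * np.sin(ang_roi), spec.vertices_per_roi)
    if spec.jitter_sd > 0 and spec.position_jitter_sd > 0:
        x0 = x0 + rng.normal(0.0, spec.position_jitter_sd, n)
        y0 = y0 + rng.normal(0.0, spec.position_jitter_sd, n)
    # keep pRF centres comfortably inside the stimulated field
    radius = np.hypot(x0, y0)
    limit = 0.9 * spec.extent
    over = radius > limit
    if over.any():
        shrink = limit / radius[over]
        x0[over] *= shrink
        y0[over] *= shrink

    table = pd.DataFrame(
        dict(
            roi=roi, x0=x0, y0=y0, sigma1=s1, sigma2=s2,
            a=a, b=bd * d, c=c, d=d,
        )
    )
    return add_derived_columns(table)


@dataclass
class ParticipantData:
    """One synthetic participant: perturbed parameters and two noisy runs."""

    params: pd.DataFrame
    run1: np.ndarray
    run2: np.ndarray


def _perturb_truth(
    truth: pd.DataFrame, rng: np.random.Generator, mult_sd: float, pos_sd: float
) -> pd.DataFrame:
    """Participant-level perturbation: multiplicative on canonical ratios and
    sizes, additive on positions."""
    p = truth.copy()
    n = len(p)
    if mult_sd > 0:
        bd = p["b"] / p["d"] * rng.lognormal(0.0, mult_sd, n)
        p["d"] = p["d"] * rng.lognormal(0.0, mult_sd, n)
        p["b"] = bd * p["d"]
        p["a"] = p["a"] * rng.lognormal(0.0, mult_sd, n)
        p["sigma1"] = p["sigma1"] * rng.lognormal(0.0, mult_sd, n)
        p["sigma2"] = p["sigma2"] * rng.lognormal(0.0, mult_sd, n)
    if pos_sd > 0:
        p["x0"] = p["x0"] + rng.normal(0.0, pos_sd, n)
        p["y0"] = p["y0"] + rng.normal(0.0, pos_sd, n)
    return add_derived_columns(p[["roi", "x0", "y0", "sigma1", "sigma2", "a", "b", "c", "d"]])


def _noise(rng, shape, sd, ar1_rho):
    eps = rng.normal(0.0, 1.0, shape)
    if ar1_rho:
        for t in range(1, shape[-1]):
            eps[..., t] = ar1_rho * eps[..., t - 1] + np.sqrt(1 - ar1_rho**2) * eps[..., t]
    return sd[..., None] * eps


def simulate_participants(
    truth: pd.DataFrame,
    design: StimulusDesign,
    n_participants: int = 1,
    snr: float | None = 3.0,
    participant_sd: float = 0.0,
    position_sd: float = 0.0,
    hrf_weight: float = 0.25,
    ar1_rho: float = 0.0,
    seed=None,
) -> list[ParticipantData]:
    """Two noisy runs per participant from the DN forward model.

    Each participant perturbs the truth (runs share parameters, differ only
    in noise).  ``snr`` sets the per-vertex noise sd to
    ``std(clean signal)/snr`` (temporal SNR); ``None`` means noiseless.
    """
    rng = np.random.default_rng(seed)
    hrf = HRFSpec(deriv_weight=hrf_weight, dt=design.frame_duration)
    out = []
    for _ in range(n_participants):
        params = _perturb_truth(truth, rng, participant_sd, position_sd)
        clean = np.stack(
            [
                predict_bold(
                    DNParams(
                        x0=r.x0, y0=r.y0, sigma1=r.sigma1, sigma2=r.sigma2,
                        a=r.a, b=r.b, c=r.c, d=r.d,
                    ),
                    design,
                    hrf,
                )
                for r in params.itertuples()
            ]
        )
        if snr is None or np.isinf(snr):
            sd = np.zeros(clean.shape[0])
        else:
            sd = clean.std(axis=1) / snr
        run1 = clean + _noise(rng, clean.shape, sd, ar1_rho)
        run2 = clean + _noise(rng, clean.shape, sd, ar1_rho)
        out.append(ParticipantData(params=params, run1=run1, run2=run2))
    return out


def simulate_participant_estimates(
    truth: pd.DataFrame,
    n_participants: int,
    participant_sd: float = 0.1,
    estimation_sd: float = 0.1,
    position_sd: float = 0.1,
    cv_profile: tuple[float, float] = (0.6, 0.25),
    cv_sd: float = 0.15,
    seed=None,
) -> list[ParticipantFit]:
    """Participant-level parameter estimates without time-course fitting.

    Estimates = truth + participant effect + estimation noise (both
    multiplicative log-normal on positive quantities, additive on
    positions).  cvR2 declines across the ROI sequence from
    ``cv_profile[0]`` to ``cv_profile[1]`` (early areas are modelled best)
    with Gaussian spread ``cv_sd``, clipped to [-0.3, 0.95], so a small
    fraction of vertex fits is non-contributing, as in real data.
    """
    rng = np.random.default_rng(seed)
    roi = truth["roi"].to_numpy()
    roi_ids = np.unique(roi)
    cv_base_roi = np.linspace(cv_profile[0], cv_profile[1], roi_ids.size)
    cv_base = cv_base_roi[np.searchsorted(roi_ids, roi)]

    out = []
    for _ in range(n_participants):
        params = _perturb_truth(truth, rng, participant_sd, position_sd)
        est = _perturb_truth(params, rng, estimation_sd, position_sd)
        table = est.drop(columns=["roi"])
        cv = np.clip(cv_base + rng.normal(0.0, cv_sd, len(table)), -0.3, 0.95)
        table["hrf_weight"] = 0.0
        table["offset"] = 0.0
        table["r2_train"] = np.clip(cv + 0.05, -0.3, 1.0)
        table["r2_run1"] = table["r2_train"]
        table["r2_run2"] = table["r2_train"]
        table["cv_r2"] = cv
        table["flag"] = 0
        out.append(ParticipantFit(table=table))
    return out


@dataclass
class ReceptorSpec:
    """One synthetic receptor map.

    Either planted on a DN quantity with a signed ROI-level correlation
    ``rho`` (``target`` names a truth column, e.g. ``bd``, ``d``, ``ecc``),
    or built from two latent factors via ``latent_loadings`` for PCA tests.
    ``scale``/``intercept`` put the map on its own density-like unit scale.
    """

    name: str
    target: str = "bd"
    rho: float = 0.65
    scale: float = 1.0
    intercept: float = 10.0
    latent_loadings: tuple[float, float] | None = None
    latent_noise: float = 0.05


def planted_receptor_set(rho: float = 0.65) -> list[ReceptorSpec]:
    """The hypothesized four relations: GABA-like and 5-HT1A-like maps with
    opposite signs on the activation ratio b/d; 5-HT1B-like and 5-HT2A-like
    with opposite signs on the normalization constant d.  Plus 5-HT4-like
    and 5-HTT-like maps planted weakly on size and eccentricity."""
    return [
        ReceptorSpec("GABA", target="bd", rho=+rho, scale=2.0, intercept=20.0),
        ReceptorSpec("5HT1A", target="bd", rho=-rho, scale=1.5, intercept=15.0),
        ReceptorSpec("5HT1B", target="d", rho=+rho, scale=1.0, intercept=10.0),
        ReceptorSpec("5HT2A", target="d", rho=-rho, scale=3.0, intercept=30.0),
        ReceptorSpec("5HT4", target="sigma1", rho=0.3, scale=0.8, intercept=8.0),
        ReceptorSpec("5HTT", target="ecc", rho=0.5, scale=1.2, intercept=12.0),
    ]


def latent_factor_receptor_set(noise: float = 0.05) -> list[ReceptorSpec]:
    """Six receptors mixing two latent factors (factor 1 follows the
    activation-ratio profile) plus ``noise``-scaled independent noise."""
    loadings = [
        ("GABA", (0.9, 0.2)),
        ("5HT1A", (-0.8, 0.3)),
        ("5HT1B", (0.7, -0.4)),
        ("5HT2A", (0.1, 0.9)),
        ("5HT4", (-0.4, -0.7)),
        ("5HTT", (0.6, 0.5)),
    ]
    return [
        ReceptorSpec(name, latent_loadings=l, latent_noise=noise,
                     scale=1.0 + 0.5 * i, intercept=10.0 * (i + 1))
        for i, (name, l) in enumerate(loadings)
    ]


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def simulate_receptors(
    truth: pd.DataFrame,
    specs: Sequence[ReceptorSpec] | None = None,
    within_roi_sd: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Per-vertex receptor density maps with planted ROI-level structure.

    For a planted spec, the ROI-level (z-scored) receptor profile is
    ``rho * z(target profile) + sqrt(1 - rho^2) * noise``, so ``rho`` is the
    expected ROI-level correlation with the true target quantity.  Latent
    specs mix the two shared factors instead.  Vertex values add independent
    within-ROI noise (sd ``within_roi_sd`` in z units).
    """
    if specs is None:
        specs = planted_receptor_set()
    rng = np.random.default_rng(seed)
    roi = truth["roi"].to_numpy()
    roi_ids = np.unique(roi)
    n_rois = roi_ids.size
    roi_index = np.searchsorted(roi_ids, roi)
    roi_means = truth.groupby("roi").mean(numeric_only=True)

    # shared latent factors: factor 1 tracks the activation-ratio profile,
    # factor 2 is an independent direction orthogonalized against it
    f1 = _zscore(roi_means["bd"].to_numpy())
    raw = rng.normal(size=n_rois)
    f2 = raw - (raw @ f1) / (f1 @ f1) * f1
    f2 = _zscore(f2)

    cols = {}
    for spec in specs:
        if spec.latent_loadings is not None:
            l1, l2 = spec.latent_loadings
            norm = np.hypot(l1, l2)
            profile = (l1 * f1 + l2 * f2) / norm + spec.latent_noise * rng.normal(size=n_rois)
        else:
            z = _zscore(roi_means[spec.target].to_numpy())
            rho = float(np.clip(spec.rho, -1.0, 1.0))
            profile = rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(size=n_rois)
        vertex = profile[roi_index]
        if within_roi_sd > 0:
            vertex = vertex + rng.normal(0.0, within_roi_sd, vertex.size)
        cols[spec.name] = spec.intercept + spec.scale * vertex
    return pd.DataFrame(cols)


@dataclass
class StudyConfig:
    """Everything needed to build one synthetic study on disk."""

    truth: TruthSpec = field(default_factory=TruthSpec)
    n_participants: int = 40
    participant_model: str = "bold"  # "bold" | "estimates"
    snr: float = 3.0
    participant_sd: float = 0.1
    estimation_sd: float = 0.1
    position_sd: float = 0.1
    hrf_weight: float = 0.25
    ar1_rho: float = 0.0
    receptor_set: str = "planted"  # "planted" | "latent"
    rho: float = 0.65
    within_roi_sd: float = 0.05
    seed: int = 0
    # stimulus (synthetic studies default to a 50x50 grid; simulation and
    # fitting share it, and drives differ <1% from a 100x100 grid)
    n_pixels: int = 50
    bar_width: float = 2.0
    steps_per_pass: int = 16
    blank_frames: int = 4
    frame_duration: float = 1.0

    def receptor_specs(self) -> list[ReceptorSpec]:
        if self.receptor_set == "planted":
            return planted_receptor_set(self.rho)
        if self.receptor_set == "latent":
            return latent_factor_receptor_set()
        raise ValueError(f"unknown receptor_set {self.receptor_set!r}")

    def make_design(self) -> StimulusDesign:
        grid = make_grid(self.truth.extent, self.n_pixels)
        return make_bar_sequence(
            grid,
            bar_width_deg=self.bar_width,
            steps_per_pass=self.steps_per_pass,
            blank_frames=self.blank_frames,
            frame_duration=self.frame_duration,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        truth = data.pop("truth", {})
        if isinstance(truth, dict):
            truth = TruthSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in truth.items()})
        return cls(truth=truth, **data)


def make_dataset(config: StudyConfig, out_dir: str | Path) -> Path:
    """Build a complete synthetic study directory.

    Writes the stimulus design, ground-truth table, ROI label map, receptor
    maps and per-participant data (two-run ``.npz`` files in "bold" mode,
    fit tables in "estimates" mode).  Same config + seed gives byte-identical
    output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.make_design()
    save_design(design, out / "design.npz")

    truth = make_truth(config.truth)
    truth.to_csv(out / "truth.tsv", sep="\t", index_label="vertex")
    truth[["roi"]].to_csv(out / "labels.tsv", sep="\t", index_label="vertex")

    rng = np.random.default_rng(config.seed)
    receptors = simulate_receptors(
        truth, config.receptor_specs(), config.within_roi_sd,
        seed=rng.integers(0, 2**31 - 1),
    )
    receptors.to_csv(out / "receptors.tsv", sep="\t", index_label="vertex")

    pdir = out / "participants"
    pdir.mkdir(exist_ok=True)
    if config.participant_model == "estimates":
        fits = simulate_participant_estimates(
            truth, config.n_participants,
            participant_sd=config.participant_sd,
            estimation_sd=config.estimation_sd,
            position_sd=config.position_sd,
            seed=rng.integers(0, 2**31 - 1),
        )
        for i, fit in enumerate(fits):
            fit.to_tsv(pdir / f"p{i:03d}_fit.tsv")
    elif config.participant_model == "bold":
        data = simulate_participants(
            truth, design, config.n_participants,
            snr=config.snr, participant_sd=config.participant_sd,
            position_sd=config.position_sd, hrf_weight=config.hrf_weight,
            ar1_rho=config.ar1_rho, seed=rng.integers(0, 2**31 - 1),
        )
        for i, part in enumerate(data):
            np.savez_compressed(pdir / f"p{i:03d}.npz", run1=part.run1, run2=part.run2)
            part.params.to_csv(pdir / f"p{i:03d}_params.tsv", sep="\t", index_label="vertex")
    else:
        raise ValueError(f"unknown participant_model {config.participant_model!r}")
    return out
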