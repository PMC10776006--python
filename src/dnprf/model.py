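"""Divisive-normalization pRF forward model.

The neural response of a cortical location to the stimulus movie ``S`` is

    p(t) = (a * G1.S + b) / (c * G2.S + d) - b/d

where ``G1`` and ``G2`` are unnormalized 2-D Gaussian fields (the activation
and normalization pRFs, sizes ``sigma1`` and ``sigma2``, shared centre
``(x0, y0)``), ``G.S`` is the pixel-wise product summed over the visual field,
``a``/``c`` are the pRF amplitudes, and ``b``/``d`` are the activation and
normalization constants.  Subtracting ``b/d`` makes the blank-screen response
zero.  The BOLD prediction convolves ``p(t)`` with a one-parameter
hemodynamic response function (canonical double-gamma plus a weighted
temporal derivative, unit peak magnitude).

The four constants ``(a, b, c, d)`` are jointly scale-degenerate: scaling all
of them by a positive factor leaves ``p(t)`` unchanged, so comparisons across
fits should use the canonical ratios ``a/d``, ``b/d``, ``c/d`` (equivalently
the reduced formulation with ``d = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.stats import gamma as gamma_dist

from .stimulus import StimulusDesign, VisualFieldGrid

__all__ = [
    "DNParams",
    "HRFSpec",
    "gaussian_field",
    "drive_timecourse",
    "dn_neural_response",
    "hrf_kernel",
    "predict_bold",
]


class ShapeMismatchError(ValueError):
    """A field image does not match the design's pixel grid."""


@dataclass
class DNParams:
    """Per-vertex DN model parameters.

    ``x0, y0`` centre (deg); ``sigma1, sigma2`` activation/normalization pRF
    sizes (deg); ``a, c`` amplitudes; ``b, d`` activation and normalization
    constants.  Invariants: ``sigma1, sigma2, d > 0``; ``b, c >= 0`` so the
    denominator is positive for any non-negative drive and the baseline
    ``b/d`` is defined.
    """

    x0: float
    y0: float
    sigma1: float
    sigma2: float
    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")
        if self.d <= 0:
            raise ValueError("normalization constant d must be positive")
        if self.b < 0 or self.c < 0:
            raise ValueError("b and c must be non-negative")

    @property
    def bd(self) -> float:
        """Activation constant in the reduced d=1 formulation."""
        return self.b / self.d

    @property
    def ad(self) -> float:
        return self.a / self.d

    @property
    def cd(self) -> float:
        return self.c / self.d

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))

    @property
    def polar_angle(self) -> float:
        return float(np.arctan2(self.y0, self.x0))

    def reduced(self) -> "DNParams":
        """Equivalent parameterization with d fixed to 1."""
        return replace(
            self, a=self.a / self.d, b=self.b / self.d, c=self.c / self.d, d=1.0
        )

    def scaled(self, lam: float) -> "DNParams":
        """Scale all four constants by ``lam`` (prediction-invariant)."""
        if lam <= 0:
            raise ValueError("scale factor must be positive")
        return replace(
            self, a=self.a * lam, b=self.b * lam, c=self.c * lam, d=self.d * lam
        )


@dataclass(frozen=True)
class HRFSpec:
    """One-parameter HRF: canonical double-gamma + derivative weight.

    ``deriv_weight`` shifts the kernel earlier/later in time, absorbing
    hemodynamic speed differences across cortex; the kernel is rescaled to
    unit peak absolute value so response amplitude stays in the pRF gain.
    """

    deriv_weight: float = 0.0
    dt: float = 1.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")


def gaussian_field(
    x0: float, y0: float, sigma: float, grid: VisualFieldGrid
) -> np.ndarray:
    """Unnormalized 2-D Gaussian weight image (value 1 at the centre)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    flat = _gaussian_flat(x0, y0, sigma, grid)
    return flat.reshape(grid.shape)


def _gaussian_flat(
    x0: float, y0: float, sigma: float, grid: VisualFieldGrid
) -> np.ndarray:
    dx = grid.pixel_x - x0
    dy = grid.pixel_y - y0
    return np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))


def drive_timecourse(field: np.ndarray, design: StimulusDesign) -> np.ndarray:
    """Per-frame stimulus drive: Gaussian field times frame, summed over pixels."""
    field = np.asarray(field, dtype=float)
    if field.shape == design.grid.shape:
        field = field.ravel()
    elif field.shape != (design.frame_matrix.shape[1],):
        raise ShapeMismatchError(
            f"field shape {field.shape} does not match grid {design.grid.shape}"
        )
    return design.frame_matrix @ field


def dn_neural_response(drive1, drive2, params: DNParams):
    """Divisive-normalization response to activation/normalization drives."""
    drive1 = np.asarray(drive1, dtype=float)
    drive2 = np.asarray(drive2, dtype=float)
    denom = params.c * drive2 + params.d
    if np.any(denom <= 0):
        raise ValueError("normalization denominator must be positive")
    return (params.a * drive1 + params.b) / denom - params.b / params.d


# SPM canonical double-gamma: response peak at 6 s, undershoot at 16 s,
# undershoot amplitude 1/6 of the peak.
_PEAK_SHAPE = 6.0
_UNDERSHOOT_SHAPE = 16.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def hrf_kernel(spec: HRFSpec) -> np.ndarray:
    """Sampled HRF kernel: canonical + deriv_weight * temporal derivative.

    Rescaled to unit peak absolute value; starts at (approximately) zero.
    """
    t = np.arange(0.0, spec.duration, spec.dt)

    def _canonical(ts):
        ts = np.maximum(ts, 0.0)
        return gamma_dist.pdf(ts, _PEAK_SHAPE) - _UNDERSHOOT_RATIO * gamma_dist.pdf(
            ts, _UNDERSHOOT_SHAPE
        )

    canonical = _canonical(t)
    # backward-shifted difference (the kernel is zero before onset), so the
    # combined kernel stays causal with a zero first sample
    deriv = (canonical - _canonical(t - spec.dt)) / spec.dt
    kernel = canonical + spec.deriv_weight * deriv
    peak = np.abs(kernel).max()
    if peak == 0:
        raise ValueError("degenerate HRF kernel (all zero)")
    return kernel / peak


def predict_bold(
    params: DNParams,
    design: StimulusDesign,
    hrf: HRFSpec | None = None,
) -> np.ndarray:
    """Predicted BOLD time course: DN neural response convolved with the HRF.

    Returned at frame resolution (length = number of frames), arbitrary
    response units, zero baseline during blanks.
    """
    if hrf is None:
        hrf = HRFSpec(dt=design.frame_duration)
    elif not np.isclose(hrf.dt, design.frame_duration):
        raise ValueError("HRF sampling interval must equal the frame duration")
    d1 = drive_timecourse(_gaussian_flat(params.x0, params.y0, params.sigma1, design.grid), design)
    d2 = drive_timecourse(_gaussian_flat(params.x0, params.y0, params.sigma2, design.grid), design)
    neural = dn_neural_response(d1, d2, params)
    kernel = hrf_kernel(hrf)
    return signal.convolve(neural, kernel, mode="full")[: design.n_frames]
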