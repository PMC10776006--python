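"""Population-level parameter maps and ROI summaries.

Group maps average single-participant parameter estimates across
participants, weighting each by its cvR2 and excluding contributions with
cvR2 <= 0 (unreliable fits cannot serve as weights).  A vertex enters
downstream analyses only if enough participants contributed; the minimum is
chosen data-driven by minimizing Li's cross-entropy over the
contributing-count histogram, with the ceiling of the real-valued threshold
as the inclusion minimum.

ROI summaries reduce the masked group maps over an integer label map: DN
parameters as cvR2-weighted vertex means, receptor densities as unweighted
means over the same vertices (receptor maps carry no cvR2), and the ROI
weight -- used by all association statistics -- as the mean cvR2 in the ROI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import FLAG_BAD_DATA, ParticipantFit

__all__ = [
    "GroupMaps",
    "ROITable",
    "group_parameter_map",
    "li_threshold",
    "roi_summaries",
    "DEFAULT_PARAMETERS",
]

DEFAULT_PARAMETERS = [
    "x0", "y0", "sigma1", "sigma2", "a", "b", "c", "d",
    "bd", "ad", "cd", "ecc", "polar",
]


class DegenerateInputError(ValueError):
    """Histogram has fewer than two distinct values; no threshold exists."""


@dataclass
class GroupMaps:
    """cvR2-weighted group parameter maps.

    ``params`` holds one column per parameter (NaN where no participant
    contributed); ``mean_cv_r2`` and ``n_contributing`` are per-vertex;
    ``mask`` marks vertices meeting the participation minimum.
    """

    params: pd.DataFrame
    mean_cv_r2: np.ndarray
    n_contributing: np.ndarray
    threshold: float | None = None
    mask: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.params)


def group_parameter_map(
    fits: Sequence[ParticipantFit | pd.DataFrame],
    parameters: Sequence[str] | None = None,
    min_participants: float | str | None = "li",
) -> GroupMaps:
    """Aggregate participant fits into cvR2-weighted group maps.

    At each vertex, each parameter is the cvR2-weighted mean over the
    participants with cvR2 > 0 there; ``mean_cv_r2`` averages cvR2 over the
    same participants.  ``min_participants`` may be ``"li"`` (data-driven Li
    threshold on the count map), an explicit number, or ``None`` (no mask).
    """
    if len(fits) == 0:
        raise ValueError("at least one participant fit is required")
    tables = [f.table if isinstance(f, ParticipantFit) else f for f in fits]
    if parameters is None:
        parameters = [c for c in DEFAULT_PARAMETERS if c in tables[0].columns]
    n_v = len(tables[0])
    if any(len(t) != n_v for t in tables):
        raise ValueError("all fits must share the vertex space")

    cv = np.stack([t["cv_r2"].to_numpy(float) for t in tables])  # (P, V)
    flags = np.stack([
        t["flag"].to_numpy() if "flag" in t.columns else np.zeros(len(t))
        for t in tables
    ])
    contributing = (cv > 0) & np.isfinite(cv) & (flags != FLAG_BAD_DATA)
    weights = np.where(contributing, cv, 0.0)
    wsum = weights.sum(axis=0)
    count = contributing.sum(axis=0)

    maps = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for p in parameters:
            vals = np.stack([t[p].to_numpy(float) for t in tables])
            maps[p] = np.where(wsum > 0, (weights * vals).sum(axis=0) / wsum, np.nan)
        mean_cv = np.where(count > 0, np.where(contributing, cv, 0.0).sum(axis=0) / np.maximum(count, 1), np.nan)

    gm = GroupMaps(
        params=pd.DataFrame(maps),
        mean_cv_r2=mean_cv,
        n_contributing=count.astype(int),
    )
    if min_participants is None:
        gm.mask = count > 0
    elif min_participants == "li":
        try:
            gm.threshold = li_threshold(count)
            gm.mask = count >= math.ceil(gm.threshold)
        except DegenerateInputError:
            # every vertex has the same participation; nothing to threshold
            warnings.warn("constant participation counts; keeping count > 0",
                          stacklevel=2)
            gm.mask = count > 0
    else:
        gm.threshold = float(min_participants)
        gm.mask = count >= math.ceil(gm.threshold)
    return gm


def _li_cross_entropy(values: np.ndarray, cut: float) -> float:
    """Li & Lee's cross-entropy of a two-class (<=cut / >cut) summary."""
    low = values[values <= cut]
    high = values[values > cut]
    ce = 0.0
    for part in (low, high):
        if part.size == 0:
            continue
        mu = part.mean()
        if mu > 0:
            ce -= part.sum() * np.log(mu)
    return ce


def li_threshold(counts: np.ndarray) -> float:
    """Minimum-cross-entropy (Li) threshold of a non-negative count histogram.

    Scans every midpoint between consecutive distinct values and returns the
    cut minimizing Li's cross-entropy.  The inclusion rule downstream is
    ``count >= ceil(threshold)``.
    """
    values = np.asarray(counts, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    uniq = np.unique(values)
    if uniq.size < 2:
        raise DegenerateInputError("constant counts admit no threshold")
    cuts = 0.5 * (uniq[:-1] + uniq[1:])
    ces = np.array([_li_cross_entropy(values, c) for c in cuts])
    return float(cuts[int(np.argmin(ces))])


@dataclass
class ROITable:
    """Per-ROI summaries feeding all association statistics.

    ``table`` is indexed by ROI label with the cvR2-weighted DN parameter
    means, unweighted receptor density means, ``weight`` (mean cvR2 in the
    ROI) and ``n_vertices``.
    """

    table: pd.DataFrame
    param_columns: list[str]
    receptor_columns: list[str]

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="roi")

    @classmethod
    def from_tsv(cls, path, param_columns=None, receptor_columns=None) -> "ROITable":
        df = pd.read_csv(path, sep="\t", index_col="roi")
        special = {"weight", "n_vertices"}
        if param_columns is None:
            param_columns = [c for c in df.columns if c in DEFAULT_PARAMETERS]
        if receptor_columns is None:
            receptor_columns = [
                c for c in df.columns if c not in special and c not in param_columns
            ]
        return cls(df, list(param_columns), list(receptor_columns))


def roi_summaries(
    groupmaps: GroupMaps,
    labels: np.ndarray,
    receptors: pd.DataFrame | None = None,
    exclude_rois: Sequence[int] | None = None,
) -> ROITable:
    """Summarize masked group maps over an integer ROI label map.

    ROIs with no masked vertices are dropped with a warning; ``exclude_rois``
    removes whole ROIs (e.g. a V1-exclusion robustness analysis).  Receptor
    maps are averaged over exactly the same masked vertices so both sides of
    every downstream comparison see the same support.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != groupmaps.n_vertices:
        raise ValueError("labels must align with the vertex space")
    mask = groupmaps.mask if groupmaps.mask is not None else np.ones(labels.shape, bool)
    exclude = set(exclude_rois or ())
    param_cols = list(groupmaps.params.columns)
    receptor_cols = list(receptors.columns) if receptors is not None else []

    rows = []
    for roi in np.unique(labels):
        if roi in exclude:
            continue
        sel = (labels == roi) & mask
        if not sel.any():
            warnings.warn(f"ROI {roi} has no masked vertices; dropped", stacklevel=2)
            continue
        w = groupmaps.mean_cv_r2[sel]
        row = {"roi": roi, "weight": float(np.mean(w)), "n_vertices": int(sel.sum())}
        wsum = w.sum()
        for p in param_cols:
            vals = groupmaps.params[p].to_numpy(float)[sel]
            row[p] = float(np.sum(w * vals) / wsum) if wsum > 0 else float(np.mean(vals))
        for r in receptor_cols:
            row[r] = float(np.mean(receptors[r].to_numpy(float)[sel]))
        rows.append(row)
    if not rows:
        raise ValueError("no ROI overlaps the inclusion mask")
    table = pd.DataFrame(rows).set_index("roi")
    return ROITable(table=table, param_columns=param_cols, receptor_columns=receptor_cols)
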