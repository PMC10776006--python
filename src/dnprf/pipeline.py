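"""Stage orchestration: simulate -> fit -> aggregate -> correlate -> pca.

Each stage is a pure function of its declared inputs; all randomness flows
from named seeds in the config, so re-running an identical config reproduces
identical outputs.  A JSON manifest records the config, its hash, the seeds
and package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import GroupMaps, ROITable, group_parameter_map, roi_summaries
from .fitting import GridSpec, ParticipantFit, fit_participant
from .stats import (
    component_parameter_scan,
    crossval_glm,
    pca_receptors,
    permutation_test,
    surrogate_pair_test,
    weighted_pearson,
)
from .stimulus import load_design
from .synth import StudyConfig, make_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("dnprf")

ALL_STAGES = ("simulate", "fit", "aggregate", "correlate", "pca")

DEFAULT_CORRELATION_PAIRS = [
    ("bd", "GABA"),
    ("bd", "5HT1A"),
    ("d", "5HT1B"),
    ("d", "5HT2A"),
]
DEFAULT_GLM_MODELS = [
    ("bd", ("GABA", "5HT1A")),
    ("d", ("5HT1B", "5HT2A")),
]


@dataclass
class PipelineConfig:
    """Full study configuration (see ``StudyConfig`` for the data half)."""

    study: StudyConfig = field(default_factory=StudyConfig)
    out_dir: str = "study_out"
    stages: tuple[str, ...] = ALL_STAGES
    n_perm: int = 10_000
    stats_seed: int = 1
    split_seed: int = 2
    exclude_rois: tuple[int, ...] = ()
    fix_d: bool = False
    min_participants: float | str = "li"
    correlation_pairs: list = field(default_factory=lambda: list(DEFAULT_CORRELATION_PAIRS))
    glm_models: list = field(default_factory=lambda: list(DEFAULT_GLM_MODELS))
    grid_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study"] = self.study.to_dict()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        study = data.pop("study", {})
        if isinstance(study, dict):
            study = StudyConfig.from_dict(study)
        cfg = cls(study=study, **data)
        cfg.stages = tuple(cfg.stages)
        cfg.exclude_rois = tuple(cfg.exclude_rois)
        cfg.correlation_pairs = [tuple(p) for p in cfg.correlation_pairs]
        cfg.glm_models = [(p, tuple(r)) for p, r in cfg.glm_models]
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _load_participant_fits(config: PipelineConfig, study_dir: Path) -> list[ParticipantFit]:
    pdir = study_dir / "participants"
    if config.study.participant_model == "estimates":
        fits = [
            ParticipantFit.from_tsv(p) for p in sorted(pdir.glob("p*_fit.tsv"))
        ]
        if config.fix_d:
            fits = [_reduce_to_unit_d(f) for f in fits]
        return fits
    design = load_design(study_dir / "design.npz")
    grid = GridSpec.for_extent(design.grid.extent, **config.grid_overrides)
    grid.fix_d = config.fix_d
    fits = []
    for path in sorted(pdir.glob("p*.npz")):
        with np.load(path) as data:
            run1, run2 = data["run1"], data["run2"]
        log.info("fitting %s (%d vertices)", path.name, run1.shape[0])
        fits.append(fit_participant(run1, run2, design, grid))
    return fits


def _reduce_to_unit_d(fit: ParticipantFit) -> ParticipantFit:
    """Re-express estimates in the reduced d=1 formulation (divide by d)."""
    t = fit.table.copy()
    t["a"], t["b"], t["c"] = t["ad"], t["bd"], t["cd"]
    t["d"] = 1.0
    t["ad"], t["bd"], t["cd"] = t["a"], t["b"], t["c"]
    return ParticipantFit(table=t)


def _split_halves(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    perm = np.random.default_rng(seed).permutation(n)
    return perm[: n // 2], perm[n // 2 :]


def _aggregate(config, fits, labels, receptors):
    gm = group_parameter_map(fits, min_participants=config.min_participants)
    roi = roi_summaries(gm, labels, receptors, exclude_rois=config.exclude_rois)
    return gm, roi


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the study report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study_dir = out / "study"
    report: dict = {"config_hash": config.config_hash()}

    if "simulate" in config.stages:
        log.info("stage: simulate -> %s", study_dir)
        make_dataset(config.study, study_dir)
    if not study_dir.exists():
        raise FileNotFoundError(f"study directory missing: {study_dir}")

    labels = pd.read_csv(study_dir / "labels.tsv", sep="\t", index_col="vertex")["roi"].to_numpy()
    receptors = pd.read_csv(study_dir / "receptors.tsv", sep="\t", index_col="vertex")

    fits: list[ParticipantFit] | None = None
    fit_dir = out / "fits"
    if "fit" in config.stages:
        log.info("stage: fit (%s mode)", config.study.participant_model)
        fits = _load_participant_fits(config, study_dir)
        fit_dir.mkdir(exist_ok=True)
        for i, f in enumerate(fits):
            f.to_tsv(fit_dir / f"p{i:03d}_fit.tsv")
    elif fit_dir.exists():
        fits = [ParticipantFit.from_tsv(p) for p in sorted(fit_dir.glob("p*_fit.tsv"))]

    roi_full = roi_a = roi_b = None
    if "aggregate" in config.stages:
        if fits is None:
            raise RuntimeError("aggregate stage requires fits")
        log.info("stage: aggregate (%d participants)", len(fits))
        gm, roi_full = _aggregate(config, fits, labels, receptors)
        gm.params.assign(
            mean_cv_r2=gm.mean_cv_r2, n_contributing=gm.n_contributing, mask=gm.mask
        ).to_csv(out / "group_maps.tsv", sep="\t", index_label="vertex")
        roi_full.to_tsv(out / "roi_table.tsv")
        idx_a, idx_b = _split_halves(len(fits), config.split_seed)
        _, roi_a = _aggregate(config, [fits[i] for i in idx_a], labels, receptors)
        _, roi_b = _aggregate(config, [fits[i] for i in idx_b], labels, receptors)
        roi_a.to_tsv(out / "roi_table_half_a.tsv")
        roi_b.to_tsv(out / "roi_table_half_b.tsv")
        report["li_threshold"] = gm.threshold
        report["n_masked_vertices"] = int(gm.mask.sum()) if gm.mask is not None else None
        report["n_rois"] = len(roi_full.table)
    else:
        if (out / "roi_table.tsv").exists():
            roi_full = ROITable.from_tsv(out / "roi_table.tsv")
        if (out / "roi_table_half_a.tsv").exists():
            roi_a = ROITable.from_tsv(out / "roi_table_half_a.tsv")
            roi_b = ROITable.from_tsv(out / "roi_table_half_b.tsv")

    rng = np.random.default_rng(config.stats_seed)
    if "correlate" in config.stages:
        if roi_full is None:
            raise RuntimeError("correlate stage requires an ROI table")
        log.info("stage: correlate")
        pairs = list(config.correlation_pairs)
        dropped = []
        if config.fix_d:
            # the normalization constant is fixed to 1 in the reduced
            # formulation; its correlations cannot be computed
            dropped = [p for p in pairs if p[0] in ("d", "cd")]
            pairs = [p for p in pairs if p[0] not in ("d", "cd")]
        rows = []
        t = roi_full.table
        w = roi_full.weights
        for param, receptor in pairs:
            res = permutation_test(
                t[receptor].to_numpy(float), t[param].to_numpy(float), w,
                n_perm=config.n_perm, seed=int(rng.integers(0, 2**31 - 1)),
            )
            rows.append(dict(parameter=param, receptor=receptor,
                             wcc=res.statistic, p=res.p, p_floored=res.floored))
        corr_df = pd.DataFrame(rows)
        corr_df.to_csv(out / "correlations.tsv", sep="\t", index=False)
        report["correlations"] = rows
        if dropped:
            report["dropped_pairs_fix_d"] = [list(p) for p in dropped]

        glm_rows = []
        for param, recs in config.glm_models:
            if config.fix_d and param in ("d", "cd"):
                continue
            ya, wa = roi_a.table[param].to_numpy(float), roi_a.weights
            yb, wb = roi_b.table[param].to_numpy(float), roi_b.weights
            xa = roi_a.table[list(recs)].to_numpy(float)
            xb = roi_b.table[list(recs)].to_numpy(float)
            entry = dict(parameter=param, receptors="+".join(recs))
            entry["wcc_cv_two"] = crossval_glm(xa, ya, wa, xb, yb, wb)
            for k, rec in enumerate(recs):
                entry[f"wcc_cv_{rec}"] = crossval_glm(
                    xa[:, k], ya, wa, xb[:, k], yb, wb
                )
            surro = surrogate_pair_test(
                t[recs[0]].to_numpy(float), t[recs[1]].to_numpy(float),
                t[param].to_numpy(float), w, n_perm=config.n_perm,
                seed=int(rng.integers(0, 2**31 - 1)), names=recs,
            )
            for rec in recs:
                entry[f"surrogate_p_{rec}"] = surro.p[rec]
            glm_rows.append(entry)
        pd.DataFrame(glm_rows).to_csv(out / "glm.tsv", sep="\t", index=False)
        report["glm"] = glm_rows

    if "pca" in config.stages:
        if roi_full is None:
            raise RuntimeError("pca stage requires an ROI table")
        log.info("stage: pca")
        pca = pca_receptors(roi_full.table[roi_full.receptor_columns])
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t", index_label="receptor")
        pd.DataFrame(
            {"component": pca.loadings.columns, "variance_ratio": pca.variance_ratio}
        ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
        scan = component_parameter_scan(
            pca, roi_full, n_perm=config.n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scan.to_csv(out / "pca_scan.tsv", sep="\t", index=False)
        report["pca_variance_ratio"] = pca.variance_ratio.tolist()
        report["pca_n_above_threshold"] = pca.n_above_threshold

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {
            "study": config.study.seed,
            "stats": config.stats_seed,
            "split": config.split_seed,
        },
        "versions": {"dnprf": __version__, "numpy": np.__version__},
        "stages": list(config.stages),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
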