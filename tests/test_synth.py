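"""Synthetic study generation: truth maps, BOLD runs, receptor maps."""

import numpy as np
import pandas as pd
import pytest

from dnprf.model import DNParams, HRFSpec, predict_bold
from dnprf.stats import weighted_pearson
from dnprf.synth import (
    ReceptorSpec,
    StudyConfig,
    TruthSpec,
    latent_factor_receptor_set,
    make_dataset,
    make_truth,
    planted_receptor_set,
    simulate_participant_estimates,
    simulate_participants,
    simulate_receptors,
)


class TestMakeTruth:
    def test_zero_jitter_shares_parameters_within_roi(self):
        spec = TruthSpec(n_rois=4, vertices_per_roi=5, jitter_sd=0.0,
                         position_jitter_sd=0.0)
        truth = make_truth(spec)
        for _, block in truth.groupby("roi"):
            assert (block.nunique() == 1).all()

    def test_roi_gradient_reproduced_exactly_at_zero_jitter(self):
        spec = TruthSpec(n_rois=5, vertices_per_roi=2, jitter_sd=0.0,
                         position_jitter_sd=0.0, bd_range=(2.0, 0.1))
        truth = make_truth(spec)
        bd_means = truth.groupby("roi")["bd"].mean().to_numpy()
        assert np.allclose(bd_means, np.geomspace(2.0, 0.1, 5))
        d_means = truth.groupby("roi")["d"].mean().to_numpy()
        assert np.all(np.diff(d_means) < 0)

    def test_deterministic_under_fixed_seed(self):
        spec = TruthSpec(n_rois=3, vertices_per_roi=4, seed=9)
        pd.testing.assert_frame_equal(make_truth(spec), make_truth(spec))

    def test_parameters_satisfy_invariants(self):
        truth = make_truth(TruthSpec(n_rois=6, vertices_per_roi=10, jitter_sd=0.3))
        assert (truth.sigma1 > 0).all() and (truth.sigma2 > 0).all()
        assert (truth.d > 0).all() and (truth.b >= 0).all() and (truth.c >= 0).all()
        assert (np.hypot(truth.x0, truth.y0) <= 0.9 * 8.0 + 1e-9).all()


class TestSimulateParticipants:
    def test_noiseless_runs_equal_forward_prediction(self, small_design):
        spec = TruthSpec(n_rois=2, vertices_per_roi=2, jitter_sd=0.0,
                         position_jitter_sd=0.0,
                         design_pixels=small_design.grid.n_pixels)
        truth = make_truth(spec)
        parts = simulate_participants(truth, small_design, 1, snr=None,
                                      participant_sd=0.0, seed=0, hrf_weight=0.3)
        part = parts[0]
        assert np.array_equal(part.run1, part.run2)
        p = truth.iloc[0]
        clean = predict_bold(
            DNParams(p.x0, p.y0, p.sigma1, p.sigma2, p.a, p.b, p.c, p.d),
            small_design, HRFSpec(deriv_weight=0.3, dt=1.0),
        )
        assert np.allclose(part.run1[0], clean)

    def test_temporal_snr_matches_request(self, small_design):
        """Monte-Carlo: realized signal-sd / noise-sd ratio ~= requested."""
        spec = TruthSpec(n_rois=4, vertices_per_roi=25, jitter_sd=0.1,
                         design_pixels=small_design.grid.n_pixels)
        truth = make_truth(spec)
        parts = simulate_participants(truth, small_design, 1, snr=3.0,
                                      participant_sd=0.0, seed=1)
        part = parts[0]
        # noise realization: half the difference of the two runs has sd
        # noise_sd/sqrt(2); clean signal sd = noise_sd * snr
        noise_sd = (part.run1 - part.run2).std(axis=1) / np.sqrt(2)
        clean = 0.5 * (part.run1 + part.run2)
        signal_sd = np.sqrt(np.maximum(clean.var(axis=1) - noise_sd.mean() ** 2, 0))
        realized = np.median(signal_sd / noise_sd)
        assert abs(realized / 3.0 - 1) < 0.1

    def test_more_noise_decreases_agreement_between_runs(self, small_design):
        spec = TruthSpec(n_rois=2, vertices_per_roi=10,
                         design_pixels=small_design.grid.n_pixels)
        truth = make_truth(spec)
        def run_corr(snr):
            p = simulate_participants(truth, small_design, 1, snr=snr, seed=2)[0]
            return np.median([np.corrcoef(a, b)[0, 1] for a, b in zip(p.run1, p.run2)])
        assert run_corr(6.0) > run_corr(3.0) > run_corr(1.5)

    def test_runs_share_parameters_but_not_noise(self, small_design):
        spec = TruthSpec(n_rois=2, vertices_per_roi=2,
                         design_pixels=small_design.grid.n_pixels)
        truth = make_truth(spec)
        part = simulate_participants(truth, small_design, 1, snr=3.0, seed=3)[0]
        assert not np.array_equal(part.run1, part.run2)


class TestReceptors:
    def test_noiseless_positive_slope_gives_unit_correlation(self):
        truth = make_truth(TruthSpec(n_rois=10, vertices_per_roi=3))
        spec = [ReceptorSpec("R+", target="bd", rho=1.0)]
        rec = simulate_receptors(truth, spec, within_roi_sd=0.0, seed=0)
        roi_rec = rec.groupby(truth.roi).mean()["R+"]
        roi_bd = truth.groupby("roi")["bd"].mean()
        assert weighted_pearson(roi_rec, roi_bd) > 0.999999

    def test_negative_slope_variant(self):
        truth = make_truth(TruthSpec(n_rois=10, vertices_per_roi=3))
        rec = simulate_receptors(truth, [ReceptorSpec("R-", target="d", rho=-1.0)],
                                 within_roi_sd=0.0, seed=0)
        roi_rec = rec.groupby(truth.roi).mean()["R-"]
        roi_d = truth.groupby("roi")["d"].mean()
        assert weighted_pearson(roi_rec, roi_d) < -0.999999

    def test_planted_correlation_magnitude_calibrated(self):
        """Planted rho=0.65 recovered within +-0.15 averaged over replicates."""
        truth = make_truth(TruthSpec(n_rois=20, vertices_per_roi=3))
        roi_bd = truth.groupby("roi")["bd"].mean()
        rs = []
        for rep in range(50):
            rec = simulate_receptors(
                truth, [ReceptorSpec("GABA", target="bd", rho=0.65)],
                within_roi_sd=0.0, seed=rep,
            )
            roi_rec = rec.groupby(truth.roi).mean()["GABA"]
            rs.append(weighted_pearson(roi_rec, roi_bd))
        assert abs(np.mean(rs) - 0.65) < 0.15

    def test_planted_set_covers_hypothesized_sign_pattern(self):
        specs = planted_receptor_set()
        by_name = {s.name: s for s in specs}
        assert by_name["GABA"].target == "bd" and by_name["GABA"].rho > 0
        assert by_name["5HT1A"].target == "bd" and by_name["5HT1A"].rho < 0
        assert by_name["5HT1B"].target == "d" and by_name["5HT1B"].rho > 0
        assert by_name["5HT2A"].target == "d" and by_name["5HT2A"].rho < 0

    def test_latent_set_has_six_receptors_two_factors(self):
        specs = latent_factor_receptor_set()
        assert len(specs) == 6
        assert all(s.latent_loadings is not None for s in specs)


class TestParticipantEstimates:
    def test_zero_perturbation_returns_truth(self):
        truth = make_truth(TruthSpec(n_rois=3, vertices_per_roi=4))
        fits = simulate_participant_estimates(
            truth, 2, participant_sd=0.0, estimation_sd=0.0, position_sd=0.0, seed=0,
        )
        assert len(fits) == 2
        for col in ("x0", "y0", "sigma1", "b", "d", "bd"):
            assert np.allclose(fits[0].table[col], truth[col])

    def test_cv_r2_declines_across_hierarchy_with_some_negatives(self):
        truth = make_truth(TruthSpec(n_rois=10, vertices_per_roi=30))
        fits = simulate_participant_estimates(truth, 3, seed=1)
        cv = fits[0].table["cv_r2"]
        early = cv[truth.roi <= 3].mean()
        late = cv[truth.roi >= 8].mean()
        assert early > late
        all_cv = np.concatenate([f.table["cv_r2"] for f in fits])
        assert (all_cv <= 0).mean() > 0  # some non-contributing vertices
        assert (all_cv <= 0).mean() < 0.2


class TestMakeDataset:
    def test_same_seed_gives_byte_identical_study(self, tmp_path):
        cfg = StudyConfig(
            truth=TruthSpec(n_rois=3, vertices_per_roi=2),
            n_participants=2, participant_model="estimates",
            n_pixels=20, steps_per_pass=4, blank_frames=1, seed=5,
        )
        out1 = make_dataset(cfg, tmp_path / "a")
        out2 = make_dataset(cfg, tmp_path / "b")
        for f1 in sorted(out1.rglob("*")):
            if f1.is_file():
                f2 = out2 / f1.relative_to(out1)
                assert f2.read_bytes() == f1.read_bytes(), f1.name

    def test_bold_mode_writes_two_runs_per_participant(self, tmp_path):
        cfg = StudyConfig(
            truth=TruthSpec(n_rois=2, vertices_per_roi=2, design_pixels=20),
            n_participants=2, participant_model="bold",
            n_pixels=20, steps_per_pass=4, blank_frames=1, seed=5,
        )
        out = make_dataset(cfg, tmp_path / "study")
        npzs = sorted((out / "participants").glob("p*.npz"))
        assert len(npzs) == 2
        with np.load(npzs[0]) as data:
            assert data["run1"].shape == data["run2"].shape
        assert (out / "design.npz").exists()
        assert (out / "truth.tsv").exists()
        assert (out / "receptors.tsv").exists()

    def test_config_roundtrip(self):
        cfg = StudyConfig(seed=3, receptor_set="latent")
        again = StudyConfig.from_dict(cfg.to_dict())
        assert again == cfg
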