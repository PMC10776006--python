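"""Group maps, Li threshold, and ROI summaries."""

import numpy as np
import pandas as pd
import pytest

from dnprf.aggregation import (
    DegenerateInputError,
    GroupMaps,
    group_parameter_map,
    li_threshold,
    roi_summaries,
)
from dnprf.fitting import ParticipantFit


def _fit(values, cv, flag=0):
    """Minimal one-parameter participant table."""
    n = len(values)
    return ParticipantFit(pd.DataFrame({
        "x0": values, "cv_r2": cv, "flag": [flag] * n,
    }))


class TestGroupParameterMap:
    def test_single_participant_passthrough(self):
        fit = _fit([1.0, 2.0, 3.0], [0.5, -0.1, 0.2])
        gm = group_parameter_map([fit], parameters=["x0"], min_participants=None)
        assert gm.params.x0[0] == 1.0
        assert np.isnan(gm.params.x0[1])  # cvR2 <= 0: no contribution
        assert gm.n_contributing.tolist() == [1, 0, 1]

    def test_negative_cv_participant_contributes_nothing(self):
        f1 = _fit([1.0], [0.4])
        f2 = _fit([100.0], [-0.1])
        gm = group_parameter_map([f1, f2], parameters=["x0"], min_participants=None)
        assert gm.params.x0[0] == 1.0
        assert gm.n_contributing[0] == 1

    def test_weighted_mean_hand_computed(self):
        # (0.2*1 + 0.6*2) / 0.8 = 1.75
        f1 = _fit([1.0], [0.2])
        f2 = _fit([2.0], [0.6])
        gm = group_parameter_map([f1, f2], parameters=["x0"], min_participants=None)
        assert np.isclose(gm.params.x0[0], 1.75)
        assert np.isclose(gm.mean_cv_r2[0], 0.4)

    def test_weighted_mean_within_contributing_range(self):
        rng = np.random.default_rng(0)
        fits = [_fit(rng.normal(size=6), rng.uniform(-0.2, 0.9, 6)) for _ in range(7)]
        gm = group_parameter_map(fits, parameters=["x0"], min_participants=None)
        vals = np.stack([f.table.x0.to_numpy() for f in fits])
        cv = np.stack([f.table.cv_r2.to_numpy() for f in fits])
        for v in range(6):
            contrib = vals[cv[:, v] > 0, v]
            if contrib.size:
                assert contrib.min() - 1e-12 <= gm.params.x0[v] <= contrib.max() + 1e-12

    def test_zero_weight_participant_is_a_no_op(self):
        rng = np.random.default_rng(1)
        fits = [_fit(rng.normal(size=5), rng.uniform(0.1, 0.9, 5)) for _ in range(4)]
        ghost = _fit(rng.normal(size=5), np.zeros(5))
        gm1 = group_parameter_map(fits, parameters=["x0"], min_participants=None)
        gm2 = group_parameter_map(fits + [ghost], parameters=["x0"], min_participants=None)
        assert np.allclose(gm1.params.x0, gm2.params.x0)
        assert np.array_equal(gm1.n_contributing, gm2.n_contributing)

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            group_parameter_map([])


def _naive_li(values, cuts):
    """Independent oracle: naive loop over candidate cuts."""
    best_cut, best_ce = None, np.inf
    for cut in cuts:
        low = values[values <= cut]
        high = values[values > cut]
        ce = 0.0
        for part in (low, high):
            if part.size and part.mean() > 0:
                ce -= part.sum() * np.log(part.mean())
        if ce < best_ce:
            best_cut, best_ce = cut, ce
    return best_cut


class TestLiThreshold:
    def test_matches_bruteforce_scan_on_random_bimodal_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            lo = rng.integers(0, 8)
            hi = rng.integers(15, 60)
            counts = np.concatenate([
                rng.poisson(lo, rng.integers(30, 120)),
                rng.poisson(hi, rng.integers(30, 120)),
            ]).astype(float)
            if np.unique(counts).size < 2:
                continue
            th = li_threshold(counts)
            uniq = np.unique(counts)
            cuts = 0.5 * (uniq[:-1] + uniq[1:])
            assert th == _naive_li(counts, cuts)
            assert lo < th < hi + 5

    def test_two_point_histogram_separates_classes(self):
        counts = np.array([0] * 40 + [9] * 60)
        th = li_threshold(counts)
        mask = counts >= np.ceil(th)
        assert mask.sum() == 60

    def test_shift_moves_threshold_by_offset(self):
        rng = np.random.default_rng(3)
        counts = np.concatenate([rng.poisson(3, 80), rng.poisson(30, 80)]).astype(float)
        th = li_threshold(counts)
        th_shifted = li_threshold(counts + 7)
        assert abs(th_shifted - (th + 7)) <= 1.0

    def test_agrees_with_skimage_on_clearly_bimodal_data(self):
        """Cross-check against the reference Li implementation."""
        from skimage.filters import threshold_li

        rng = np.random.default_rng(5)
        counts = np.concatenate([rng.poisson(2, 150), rng.poisson(28, 150)]).astype(float)
        ours = li_threshold(counts)
        ref = threshold_li(counts)
        # same inclusion decision for every vertex
        assert np.array_equal(counts >= np.ceil(ours), counts >= np.ceil(ref))

    def test_constant_counts_rejected(self):
        with pytest.raises(DegenerateInputError):
            li_threshold(np.full(10, 4))


class TestROISummaries:
    def _groupmaps(self, values, cv, mask=None):
        n = len(values)
        return GroupMaps(
            params=pd.DataFrame({"bd": values}),
            mean_cv_r2=np.asarray(cv, float),
            n_contributing=np.full(n, 5),
            mask=np.ones(n, bool) if mask is None else np.asarray(mask),
        )

    def test_single_vertex_roi_passthrough(self):
        gm = self._groupmaps([2.5, 1.0], [0.3, 0.2])
        roi = roi_summaries(gm, np.array([1, 2]))
        assert roi.table.loc[1, "bd"] == 2.5
        assert roi.table.loc[1, "weight"] == 0.3

    def test_uniform_weights_reduce_to_plain_mean(self):
        gm = self._groupmaps([1.0, 3.0], [0.4, 0.4])
        roi = roi_summaries(gm, np.array([7, 7]))
        assert np.isclose(roi.table.loc[7, "bd"], 2.0)

    def test_weighted_mean_hand_computed(self):
        # (0.1*1 + 0.3*5)/0.4 = 4.0
        gm = self._groupmaps([1.0, 5.0], [0.1, 0.3])
        roi = roi_summaries(gm, np.array([1, 1]))
        assert np.isclose(roi.table.loc[1, "bd"], 4.0)

    def test_receptors_averaged_unweighted_over_same_support(self):
        gm = self._groupmaps([1.0, 5.0, 9.0], [0.1, 0.3, 0.5], mask=[True, True, False])
        rec = pd.DataFrame({"GABA": [10.0, 20.0, 99.0]})
        roi = roi_summaries(gm, np.array([1, 1, 1]), rec)
        assert np.isclose(roi.table.loc[1, "GABA"], 15.0)  # masked vertex excluded

    def test_unmasked_roi_dropped_with_warning(self):
        gm = self._groupmaps([1.0, 2.0], [0.2, 0.2], mask=[True, False])
        with pytest.warns(UserWarning, match="no masked vertices"):
            roi = roi_summaries(gm, np.array([1, 2]))
        assert list(roi.table.index) == [1]

    def test_exclude_rois_flag(self):
        gm = self._groupmaps([1.0, 2.0], [0.2, 0.2])
        roi = roi_summaries(gm, np.array([1, 2]), exclude_rois=[1])
        assert list(roi.table.index) == [2]

    def test_roundtrip_tsv(self, tmp_path):
        gm = self._groupmaps([1.0, 2.0], [0.2, 0.4])
        rec = pd.DataFrame({"GABA": [1.0, 2.0]})
        roi = roi_summaries(gm, np.array([1, 2]), rec)
        roi.to_tsv(tmp_path / "roi.tsv")
        from dnprf.aggregation import ROITable

        loaded = ROITable.from_tsv(tmp_path / "roi.tsv")
        pd.testing.assert_frame_equal(loaded.table, roi.table)
        assert loaded.receptor_columns == ["GABA"]
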