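"""ROI statistics, contrast/SDNR formulas, threshold volumetry, sweep report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioswi.metrics import contrast_sdnr, roi_stats, sweep_report, threshold_volume
from cardioswi.phantom import (
    PhantomSpec,
    TissueParams,
    default_tissues,
    ground_truth_image,
    phantom_rois,
    simulate_kspace,
)
from cardioswi.recon import hpf_phase, reconstruct, sos_magnitude
from cardioswi.rois import RoiSet
from cardioswi.swi import swi_series


def _simple_rois(shape=(10, 10)):
    lesion = np.zeros(shape, dtype=bool)
    remote = np.zeros(shape, dtype=bool)
    noise = np.zeros(shape, dtype=bool)
    lesion[2:4, 2:4] = True
    remote[6:9, 6:9] = True
    noise[0, 5:10] = True
    return RoiSet({"lesion": lesion, "remote_myocardium": remote, "noise": noise})


class TestRoiStats:
    def test_constant_image(self):
        stats = roi_stats(np.full((10, 10), 3.5), _simple_rois())
        assert (stats["mean"] == 3.5).all()
        assert (stats["std"] == 0.0).all()

    def test_noiseless_phantom_means_match_decay_model(self):
        spec = PhantomSpec(noise_sigma=0.0, n_coils=1)
        es = reconstruct(simulate_kspace(spec))
        mag = sos_magnitude(es)
        rois = phantom_rois(spec)
        stats = roi_stats(mag[11], rois)
        te = spec.echo_times[11]
        assert stats.loc["remote_myocardium", "mean"] == pytest.approx(np.exp(-te / 34.1), abs=1e-9)
        assert stats.loc["lesion", "mean"] == pytest.approx(np.exp(-te / 16.2), abs=1e-9)

    def test_missing_required_roi_named_in_error(self):
        rois = RoiSet({"lesion": np.ones((4, 4), dtype=bool)})
        with pytest.raises(KeyError, match="remote_myocardium"):
            contrast_sdnr(np.ones((4, 4)), rois)


class TestContrastSdnr:
    def test_formula_arithmetic(self):
        """S1 = 1.0, S2 = 0.4, STD = 0.1 -> contrast 0.6, SDNR 6.0."""
        rois = _simple_rois()
        img = np.zeros((10, 10))
        img[rois["remote_myocardium"]] = 1.0
        img[rois["lesion"]] = 0.4
        rng = np.random.default_rng(0)
        img[rois["noise"]] = rng.normal(size=5)
        img[rois["noise"]] = 0.1 * (img[rois["noise"]] - img[rois["noise"]].mean()) / img[rois["noise"]].std()
        r = contrast_sdnr(img, rois)
        assert r.contrast == pytest.approx(0.6)
        assert r.sdnr == pytest.approx(6.0)
        assert r.noise_std == pytest.approx(0.1)

    def test_equal_means_give_zero(self):
        rois = _simple_rois()
        img = np.ones((10, 10))
        img[rois["noise"]] = [0.0, 0.1, -0.1, 0.2, -0.2]
        r = contrast_sdnr(img, rois)
        assert r.contrast == 0.0
        assert r.sdnr == 0.0

    def test_zero_reference_flagged_undefined(self):
        rois = _simple_rois()
        img = np.zeros((10, 10))
        img[rois["noise"]] = [0.0, 0.1, -0.1, 0.2, -0.2]
        r = contrast_sdnr(img, rois)
        assert not r.defined

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=50, deadline=None)
    def test_contrast_scale_invariant_sdnr_scales_jointly(self, scale):
        rois = _simple_rois()
        img = np.zeros((10, 10))
        img[rois["remote_myocardium"]] = 1.0
        img[rois["lesion"]] = 0.3
        img[rois["noise"]] = [0.0, 0.05, -0.05, 0.1, -0.1]
        r0 = contrast_sdnr(img, rois)
        r1 = contrast_sdnr(scale * img, rois)
        assert r1.contrast == pytest.approx(r0.contrast, rel=1e-9)
        assert r1.sdnr == pytest.approx(r0.sdnr, rel=1e-9)

    def test_warns_when_noise_roi_contains_signal(self):
        rois = _simple_rois()
        img = np.ones((10, 10))
        img[rois["lesion"]] = 0.2
        img[rois["noise"]] = [0.5, 0.6, 0.5, 0.6, 0.5]
        with pytest.warns(UserWarning, match="noise ROI"):
            contrast_sdnr(img, rois)


class TestThresholdVolume:
    def test_uniform_lv_is_all_lesion(self):
        lv = np.zeros((12, 12), dtype=bool)
        lv[2:10, 2:10] = True
        r = threshold_volume(np.ones((12, 12)), lv)
        assert r.percent_lv == 100.0

    def test_constructed_lge_with_enclosed_dark_core(self):
        """Bright region 30% of LV with an enclosed 5% dark core counts as 35%."""
        lv = np.zeros((40, 40), dtype=bool)
        lv[0:20, 0:20] = True  # 400 LV pixels
        img = np.full((40, 40), 0.1)
        bright = np.zeros_like(lv)
        bright[2:12, 2:16] = True  # 140 px gross; 120 px = 30% net of the core
        core = np.zeros_like(lv)
        core[5:9, 5:10] = True  # 20 px = 5%, strictly inside bright
        img[bright] = 1.0
        img[core] = 0.05
        r = threshold_volume(img, lv)
        assert r.lesion_pixels == 120 + 20
        assert r.percent_lv == pytest.approx(35.0)

    def test_half_above_threshold_no_holes(self):
        lv = np.zeros((10, 10), dtype=bool)
        lv[0:10, 0:10] = True
        img = np.zeros((10, 10))
        img[:, 5:] = 1.0  # open boundary: not an enclosed hole
        r = threshold_volume(img, lv)
        assert r.percent_lv == pytest.approx(50.0)

    def test_idempotent_and_affine_invariant(self):
        rng = np.random.default_rng(7)
        img = rng.random((20, 20))
        lv = np.zeros((20, 20), dtype=bool)
        lv[3:17, 3:17] = True
        r0 = threshold_volume(img, lv)
        r1 = threshold_volume(2.5 * img + 1.0, lv)
        # positive-slope affine maps move the half-max threshold but the
        # half_max rule is defined on max over the mask, so only pure scaling
        # is exactly invariant; check scaling here
        r2 = threshold_volume(2.5 * img, lv)
        assert r2.lesion_pixels == r0.lesion_pixels
        assert r1.lv_pixels == r0.lv_pixels

    def test_manual_hypo_rule(self):
        lv = np.zeros((8, 8), dtype=bool)
        lv[1:7, 1:7] = True
        img = np.ones((8, 8))
        img[2:4, 2:4] = 0.1
        r = threshold_volume(img, lv, rule="manual_hypo", threshold=0.2)
        assert r.lesion_pixels == 4
        with pytest.raises(ValueError, match="threshold"):
            threshold_volume(img, lv, rule="manual_hypo")

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_volume(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


class TestSweepReport:
    def test_swi6_beats_swi3_beats_magnitude_at_fixed_nte(self, sweep_table):
        for n_te in range(1, 13):
            rows = sweep_table[sweep_table.n_te == n_te].set_index("source")
            assert rows.loc["swi6", "contrast"] >= rows.loc["swi3", "contrast"]
            assert rows.loc["swi3", "contrast"] > rows.loc["magnitude", "contrast"]

    def test_interior_nte_sdnr_exceeds_single_echo(self, sweep_table):
        for src in ("magnitude", "swi3", "swi6"):
            rows = sweep_table[sweep_table.source == src].set_index("n_te")
            assert rows.sdnr[2:12].max() > rows.loc[1, "sdnr"]

    def test_lesion_free_phantom_has_near_zero_contrast(self):
        tissues = default_tissues()
        tissues["lesion"] = TissueParams(1.0, 34.1, off_resonance=10.0)  # lesion == myocardium
        spec = PhantomSpec(tissues=tissues, seed=11)
        es = reconstruct(simulate_kspace(spec))
        mag = sos_magnitude(es)
        phase, valid = hpf_phase(es)
        rois = phantom_rois(spec)
        swi6 = swi_series(mag, phase, 6, valid)
        rep = sweep_report(mag, {"swi6": swi6}, rois, es.echo_times,
                           np.broadcast_to(valid, mag.shape))
        # noise-propagated bound: lesion-mean SEM ~ sigma/sqrt(n_lesion * n_te)
        n_lesion = rois["lesion"].sum()
        for _, row in rep.iterrows():
            bound = 2.0 * row.noise_std / (np.sqrt(n_lesion) * row.s1)
            assert abs(row.contrast) < 2 * bound + 0.02


class TestContrastOnGroundTruth:
    def test_identical_rois_make_reconstructions_comparable(self):
        spec = PhantomSpec(noise_sigma=0.0, n_coils=1)
        img, rois = ground_truth_image(spec, 11)
        mag = np.abs(img)
        a = roi_stats(mag, rois)
        b = roi_stats(mag * 2, rois)
        assert (a["n_pixels"] == b["n_pixels"]).all()
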