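"""Scintigraphy quantification: fractional-max ROI segmentation, syringe
calibration, renogram behavior under normal and obstructed kinetics, DMSA
normalization, paired t comparisons."""

import numpy as np
import pytest
from scipy import ndimage

from renomark import scintigraphy as sc
from renomark import synthetic


def frame_from(counts, t_min=10.0, duration=1.0, syringe_MBq=5.0, injected=55.0):
    return sc.PlanarFrame(
        counts=np.asarray(counts),
        frame_time_min=t_min,
        duration_min=duration,
        syringe_activity_MBq=syringe_MBq,
        injected_MBq=injected,
    )


def gaussian_image(center, sigma, peak, shape=(256, 256)):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return peak * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


class TestSegmentRoi:
    def test_uniform_image_spans_whole_window(self):
        f = frame_from(np.full((256, 256), 50))
        roi = sc.segment_roi(f, (128, 128), window_half=10)
        assert roi.mask.sum() == 21 * 21

    def test_gaussian_blob_matches_bruteforce_threshold_count(self):
        img = gaussian_image((128, 128), sigma=4.0, peak=1000.0)
        f = frame_from(img)
        roi = sc.segment_roi(f, (128, 128), threshold_frac=0.10, window_half=24)
        brute = int((img >= 0.10 * img.max()).sum())
        assert roi.mask.sum() == brute

    def test_second_blob_excluded_by_connectivity(self):
        img = gaussian_image((100, 80), 3.0, 500.0) + gaussian_image((100, 180), 3.0, 500.0)
        f = frame_from(img)
        roi = sc.segment_roi(f, (100, 80), window_half=40)
        assert not roi.mask[100, 180]
        assert roi.mask[100, 80]

    def test_seed_below_threshold_raises(self):
        img = gaussian_image((128, 128), 3.0, 1000.0)
        f = frame_from(img)
        with pytest.raises(sc.EmptyRoiError):
            sc.segment_roi(f, (128, 150), window_half=24)

    def test_idempotent_on_masked_region(self):
        img = gaussian_image((128, 128), 4.0, 800.0)
        f = frame_from(img)
        roi = sc.segment_roi(f, (128, 128))
        masked = np.where(roi.mask, img, 0.0)
        roi2 = sc.segment_roi(frame_from(masked), (128, 128))
        np.testing.assert_array_equal(roi.mask, roi2.mask)

    def test_monotone_in_threshold(self):
        img = gaussian_image((128, 128), 5.0, 800.0)
        f = frame_from(img)
        lo = sc.segment_roi(f, (128, 128), threshold_frac=0.10)
        hi = sc.segment_roi(f, (128, 128), threshold_frac=0.30)
        assert np.all(lo.mask[hi.mask])  # higher threshold => subset
        assert hi.mask.sum() < lo.mask.sum()


class TestQuantifyFrame:
    def test_calibration_identity(self):
        counts = np.zeros((64, 64))
        counts[10:20, 10:20] = 7.0
        f = frame_from(counts, syringe_MBq=3.5, t_min=0.001)
        mask = counts > 0
        act, _ = sc.quantify_frame(f, mask, mask)
        assert act == pytest.approx(3.5)

    def test_empty_roi_gives_zero(self):
        counts = np.zeros((64, 64))
        counts[5:10, 5:10] = 4.0
        f = frame_from(counts)
        act, pct = sc.quantify_frame(f, np.zeros((64, 64), bool), counts > 0)
        assert act == 0.0 and pct == 0.0

    def test_zero_syringe_counts_raise(self):
        f = frame_from(np.zeros((64, 64)))
        with pytest.raises(sc.CalibrationError):
            sc.quantify_frame(f, np.ones((64, 64), bool), np.ones((64, 64), bool))

    def test_unbiased_recovery_over_poisson_seeds(self, geometry, roi_seeds):
        # truth 5 %IA in the kidneys; recover with truth masks over 500
        # Poisson realizations and compare means within 3 standard errors
        truth_k, truth_b = 5.0, 15.0
        rr, cc = geometry.grids()
        kidney_mask = np.zeros(geometry.shape, bool)
        for (r0, c0) in geometry.kidney_centers:
            kidney_mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= (
                5 * geometry.kidney_sigma_px
            ) ** 2
        bladder_mask = geometry.bladder_mask()
        syringe_mask = geometry.syringe_mask()
        rec_k, rec_b, rec_s = [], [], []
        for seed in range(500):
            # no diffuse remainder: the truth masks must see only their
            # own object's counts for the bias comparison to be exact
            f = synthetic.gen_static_frame(
                truth_k,
                geometry,
                seed=seed,
                bladder_percent_ia=truth_b,
                remainder_percent_ia=0.0,
            )
            _, pk = sc.quantify_frame(f, kidney_mask, syringe_mask)
            _, pb = sc.quantify_frame(f, bladder_mask, syringe_mask)
            act_s, _ = sc.quantify_frame(f, syringe_mask, syringe_mask)
            rec_k.append(pk)
            rec_b.append(pb)
            rec_s.append(act_s)
        for rec, truth in ((rec_k, truth_k), (rec_b, truth_b)):
            se = np.std(rec, ddof=1) / np.sqrt(len(rec))
            assert abs(np.mean(rec) - truth) < 3 * se + 1e-9
        assert np.mean(rec_s) == pytest.approx(
            np.mean(rec_s), abs=0
        )  # syringe self-calibration is exact by construction
        assert rec_s[0] == pytest.approx(rec_s[1])


class TestRenogram:
    def _series(self, impairment, seed=0, noise=True):
        kin = synthetic.RenalKinetics(impairment_factor=impairment)
        geo = synthetic.FrameGeometry()
        frames = synthetic.gen_scintigraphy_series(
            kin, geo, sc.DTPA_PROTOCOL_TIMES_MIN, seed=seed, noise=noise
        )
        return kin, geo, frames

    def test_normal_kinetics_excretion_phase(self, roi_seeds):
        _, _, frames = self._series(1.0)
        ren = sc.build_renogram(
            frames, roi_seeds["kidneys"], roi_seeds["bladder"], roi_seeds["syringe"]
        )
        assert np.all(np.diff(ren.kidney_percent_ia[-4:]) < 0)
        assert np.all(np.diff(ren.bladder_percent_ia) > 0)

    def test_obstruction_accumulates_in_kidneys(self, roi_seeds):
        _, _, frames = self._series(0.0)
        ren = sc.build_renogram(
            frames, roi_seeds["kidneys"], roi_seeds["bladder"], roi_seeds["syringe"]
        )
        assert np.all(np.diff(ren.kidney_percent_ia) >= 0)
        assert ren.bladder_at_27_5 < 1.0

    def test_all_zero_frames_quantify_to_zero(self):
        frames = [
            sc.PlanarFrame(
                np.zeros((256, 256), np.uint16), t, 1.0, 5.0, 55.0
            )
            for t in sc.DTPA_PROTOCOL_TIMES_MIN
        ]
        ren = sc.build_renogram(frames, ((100, 96), (100, 160)), (190, 128), (16, 12))
        assert np.all(ren.kidney_percent_ia == 0)
        assert ren.bladder_at_27_5 == 0.0

    def test_missing_bladder_frame_rejected_in_protocol_mode(self, roi_seeds):
        _, _, frames = self._series(1.0)
        short = [f for f in frames if f.frame_time_min != 27.5]
        with pytest.raises(sc.ProtocolError):
            sc.build_renogram(
                short, roi_seeds["kidneys"], roi_seeds["bladder"], roi_seeds["syringe"]
            )

    def test_mass_balance_noise_free(self, geometry, roi_seeds):
        # kidney + bladder + remainder %IA within 2% of 100 (decay-corrected)
        kin = synthetic.RenalKinetics(impairment_factor=0.5)
        frames = synthetic.gen_scintigraphy_series(
            kin, geometry, [2.5, 17.5, 32.5], seed=0, noise=False
        )
        rr, cc = geometry.grids()
        organ = np.zeros(geometry.shape, bool)
        for (r0, c0) in geometry.kidney_centers:
            organ |= (rr - r0) ** 2 + (cc - c0) ** 2 <= (
                3 * geometry.kidney_sigma_px
            ) ** 2
        bladder = geometry.bladder_mask()
        syringe = geometry.syringe_mask()
        remainder = geometry.body_mask() & ~organ & ~bladder & ~syringe
        for f in frames:
            total = 0.0
            for mask in (organ, bladder, remainder):
                _, pct = sc.quantify_frame(f, mask, syringe)
                total += pct
            assert total == pytest.approx(100.0, abs=2.0)


class TestDmsa:
    def _measure(self, frame, geometry, roi_seeds):
        return sc.dmsa_uptake(
            frame, roi_seeds["kidneys"], roi_seeds["syringe"], [100.0]
        )

    def test_subject_equal_to_control_mean_gives_100(self, geometry, roi_seeds):
        f = synthetic.gen_static_frame(15.0, geometry, seed=0)
        pct = self._measure(f, geometry, roi_seeds)
        assert sc.dmsa_uptake(
            f, roi_seeds["kidneys"], roi_seeds["syringe"], [pct]
        ) == pytest.approx(100.0)

    def test_planted_ratio_recovered(self, geometry, roi_seeds):
        # truth ratio 1.4 (subject 21 %IA vs controls 15 %IA)
        controls = [
            self._measure(
                synthetic.gen_static_frame(15.0, geometry, seed=s), geometry, roi_seeds
            )
            for s in range(3)
        ]
        subject = synthetic.gen_static_frame(21.0, geometry, seed=7)
        ratio = sc.dmsa_uptake(
            subject, roi_seeds["kidneys"], roi_seeds["syringe"], controls
        )
        assert ratio == pytest.approx(140.0, rel=0.05)

    def test_controls_average_to_100(self, geometry, roi_seeds):
        controls = [
            self._measure(
                synthetic.gen_static_frame(15.0, geometry, seed=s), geometry, roi_seeds
            )
            for s in range(4)
        ]
        normalized = [
            sc.dmsa_uptake(
                synthetic.gen_static_frame(15.0, geometry, seed=s),
                roi_seeds["kidneys"],
                roi_seeds["syringe"],
                controls,
            )
            for s in range(4)
        ]
        assert np.mean(normalized) == pytest.approx(100.0, rel=0.03)

    def test_empty_control_list_rejected(self, geometry, roi_seeds):
        f = synthetic.gen_static_frame(15.0, geometry, seed=0)
        with pytest.raises(ValueError):
            sc.dmsa_uptake(f, roi_seeds["kidneys"], roi_seeds["syringe"], [])


class TestCompareGroups:
    def test_identical_vectors(self):
        t, p, sig = sc.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, sig) == (0.0, 1.0, False)

    def test_hand_paired_t(self):
        # differences (1, 2, 3): t = 2*sqrt(3) = 3.464, p ~ 0.0742 at 2 df
        t, p, sig = sc.compare_groups([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(3.464, abs=1e-3)
        assert p == pytest.approx(0.0742, abs=2e-3)
        assert not sig

    def test_constant_nonzero_shift_is_significant(self):
        t, p, sig = sc.compare_groups([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert sig and p == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sc.compare_groups([1.0, 2.0], [1.0])
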