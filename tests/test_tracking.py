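"""MOSSE, KCF and NCC tracker behaviour on synthetic navigators."""

import numpy as np
import pytest

import navmoco as nm
from navmoco.tracking import (
    FlatPatchError,
    TrackerParams,
    make_tracker,
    ncc_track,
    register_tracker,
    track_series,
)

from conftest import make_sin_series

ALL_KINDS = ["mosse", "kcf", "ncc"]
INT_PARAMS = TrackerParams(subpixel=False)


def shifted_frame(plane, spec, shift_px):
    d3 = nm.image_to_patient(shift_px, plane)
    return nm.render_navigator(plane, spec, d3)


class TestInitialization:
    def test_bbox_outside_image_rejected(self, disc_frame):
        with pytest.raises(ValueError, match="outside"):
            nm.MosseTracker(disc_frame, nm.BoundingBox(60, 60, 10, 10))

    def test_tiny_bbox_rejected(self, disc_frame):
        with pytest.raises(ValueError, match="area"):
            nm.KcfTracker(disc_frame, nm.BoundingBox(10, 10, 3, 3))

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_flat_patch_is_explicit_error(self, kind):
        flat = np.ones((64, 64))
        with pytest.raises(FlatPatchError):
            make_tracker(kind, flat, nm.BoundingBox(20, 20, 16, 16))

    def test_unknown_kind_rejected(self, disc_frame):
        with pytest.raises(ValueError, match="unknown tracker"):
            make_tracker("boosting", disc_frame, nm.BoundingBox(20, 20, 16, 16))

    def test_registry_accepts_external_backend(self, disc_frame):
        class Dummy:
            def __init__(self, image, bbox, params):
                self.bbox = bbox

            def update(self, image):
                return nm.TrackerResult(self.bbox, False, 1.0)

        register_tracker("dummy", Dummy)
        try:
            t = make_tracker("dummy", disc_frame, nm.BoundingBox(20, 20, 16, 16))
            assert not t.update(disc_frame).failed
        finally:
            del nm.tracking.TRACKER_KINDS["dummy"]


class TestShiftRecovery:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_identical_frame_zero_shift(self, kind, disc_frame, coronal):
        bbox = nm.auto_bbox(disc_frame)
        log = track_series([disc_frame, disc_frame], bbox, kind, INT_PARAMS,
                           coronal.pixel_size)
        assert not log.results[1].failed
        assert np.allclose(log.displacements_px[1], 0)

    @pytest.mark.parametrize("kind", ALL_KINDS)
    @pytest.mark.parametrize("shift", [(3, 0), (-2, 1), (0, -4), (4, 4)])
    def test_integer_shift_within_one_px(self, kind, shift, coronal,
                                         noiseless_spec, disc_frame):
        frames = [disc_frame, shifted_frame(coronal, noiseless_spec, shift)]
        bbox = nm.auto_bbox(disc_frame)
        log = track_series(frames, bbox, kind, INT_PARAMS, coronal.pixel_size)
        assert not log.results[1].failed
        assert np.all(np.abs(log.displacements_px[1] - shift) <= 1)

    def test_ncc_integer_shift_exact(self, coronal, noiseless_spec, disc_frame):
        target = (2, -1)
        frames = [disc_frame, shifted_frame(coronal, noiseless_spec, target)]
        log = track_series(frames, nm.auto_bbox(disc_frame), "ncc",
                           INT_PARAMS, coronal.pixel_size)
        assert np.array_equal(log.displacements_px[1], target)
        assert log.results[1].confidence > 0.99

    def test_ncc_exact_copy_scores_one(self, disc_frame):
        patch = disc_frame[22:38, 25:41]
        center, conf, failed = ncc_track(patch, disc_frame, (33.0, 30.0))
        assert np.isclose(conf, 1.0)
        assert not failed
        assert center == (33.0, 30.0)

    def test_ncc_pure_noise_low_confidence(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(12, 12))
        img = rng.normal(size=(64, 64))
        _, conf, _ = ncc_track(ref, img, (32, 32))
        assert conf < 0.6


class TestFailureDetection:
    def blank_frame(self, coronal, sigma=0.05, seed=1):
        spec = nm.PhantomSpec(target_intensity=0.15,
                              background_intensity=0.15, noise_sigma=sigma)
        return nm.render_navigator(coronal, spec, (0, 0, 0), seed=seed)

    def test_mosse_fails_on_blanked_target(self, disc_frame, coronal):
        t = nm.MosseTracker(disc_frame, nm.auto_bbox(disc_frame))
        good = t.update(disc_frame)
        bad = t.update(self.blank_frame(coronal))
        assert not good.failed and good.confidence > 8.0
        assert bad.failed
        assert bad.confidence < good.confidence

    def test_kcf_fails_on_blanked_target(self, disc_frame, coronal):
        t = nm.KcfTracker(disc_frame, nm.auto_bbox(disc_frame))
        good = t.update(disc_frame)
        bad = t.update(self.blank_frame(coronal))
        assert not good.failed
        assert bad.failed
        assert bad.confidence < 0.5 * good.confidence

    def test_failed_frames_carry_no_displacement(self, disc_frame, coronal):
        frames = [disc_frame, disc_frame, self.blank_frame(coronal)]
        log = track_series(frames, nm.auto_bbox(disc_frame), "mosse")
        assert not log.failed_flags[1]
        assert log.failed_flags[2]
        assert np.all(np.isnan(log.displacements_px[2]))
        df = log.to_frame()
        assert bool(df.loc[2, "failed"])


class TestSeriesProperties:
    def test_static_series_all_zero(self, coronal, noiseless_spec):
        frames = [nm.render_navigator(coronal, noiseless_spec, (0, 0, 0))] * 10
        for kind in ALL_KINDS:
            log = track_series(frames, nm.auto_bbox(frames[0]), kind,
                               INT_PARAMS, coronal.pixel_size)
            assert np.allclose(log.displacements_px, 0)
            assert not log.failed_flags.any()

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_sinusoid_snr20_subpixel_tracking(self, kind):
        series = make_sin_series(snr=20.0, n_frames=40, seed=2)
        imgs = series.images["cor"]
        truth = series.truth_px["cor"]
        log = track_series(imgs, nm.auto_bbox(imgs[0]), kind,
                           TrackerParams(), (2.7, 2.7))
        err = np.linalg.norm(log.displacements_px - truth, axis=1)
        assert np.nanmean(err[~log.failed_flags]) < 1.0

    def test_translation_equivariance_ncc_exact(self, coronal, noiseless_spec,
                                                disc_frame):
        # rolling the whole frame moves the reported box by the same amount
        u, v = 3, -2
        rolled = np.roll(disc_frame, (v, u), axis=(0, 1))
        log = track_series([disc_frame, rolled], nm.auto_bbox(disc_frame),
                           "ncc", INT_PARAMS)
        assert np.array_equal(log.displacements_px[1], (u, v))

    @pytest.mark.parametrize("kind", ["mosse", "kcf"])
    def test_translation_equivariance_filters_within_one_px(self, kind,
                                                            disc_frame):
        u, v = 3, -2
        rolled = np.roll(disc_frame, (v, u), axis=(0, 1))
        log = track_series([disc_frame, rolled], nm.auto_bbox(disc_frame),
                           kind, INT_PARAMS)
        assert np.all(np.abs(log.displacements_px[1] - (u, v)) <= 1)

    def test_agreement_with_ncc_oracle(self):
        """MOSSE/KCF agree with exhaustive NCC on noiseless sequences."""
        n_ok = {"mosse": 0, "kcf": 0}
        total = 0
        for seed in range(10):
            series = make_sin_series(snr=np.inf, n_frames=12, seed=seed)
            imgs = series.images["cor"]
            bbox = nm.auto_bbox(imgs[0])
            ref = track_series(imgs, bbox, "ncc", INT_PARAMS)
            for kind in n_ok:
                log = track_series(imgs, bbox, kind, INT_PARAMS)
                d = np.abs(log.displacements_px - ref.displacements_px)
                n_ok[kind] += int(np.sum(np.all(d <= 1, axis=1)))
            total += imgs.shape[0]
        for kind, ok in n_ok.items():
            assert ok / total >= 0.95, kind

    def test_radiometric_invariance(self, coronal):
        series = make_sin_series(snr=10.0, n_frames=15, seed=4)
        imgs = series.images["cor"]
        bbox = nm.auto_bbox(imgs[0])
        for kind in ALL_KINDS:
            a = track_series(imgs, bbox, kind, TrackerParams())
            b = track_series([7.5 * f for f in imgs], bbox, kind,
                             TrackerParams())
            da, db = a.displacements_px, b.displacements_px
            assert np.allclose(da[np.isfinite(da)], db[np.isfinite(db)],
                               atol=1e-6)

    def test_too_short_series_rejected(self, disc_frame):
        with pytest.raises(ValueError, match="2 frames"):
            track_series([disc_frame], nm.auto_bbox(disc_frame))
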