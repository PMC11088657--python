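"""Synthetic motion traces and navigator rendering."""

import numpy as np
import pytest

import navmoco as nm
from navmoco.fusion import FusionConfig
from navmoco.simnav import (
    MotionTrace,
    PhantomSpec,
    make_breathing_trace,
    make_step_trace,
    render_navigator,
    simulate_series,
)


def centroid(img):
    im = img - img.min()
    ys, xs = np.mgrid[: img.shape[0], : img.shape[1]]
    return np.array([(xs * im).sum() / im.sum(), (ys * im).sum() / im.sum()])


class TestBreathingTrace:
    def test_zero_amplitude_is_flat(self):
        tr = make_breathing_trace(10, 0.25, 0.0, seed=0)
        assert np.allclose(tr.disp, 0)

    def test_reference_anchored(self):
        tr = make_breathing_trace(10, 0.25, 12.0, seed=0)
        assert np.allclose(tr.disp[0], 0)

    def test_pure_sinusoid_percentile_range(self):
        # 10th-90th percentile range of A*sin is 1.902*A (arcsine law);
        # oracle: dense sampling of whole cycles
        A = 10.0
        tr = make_breathing_trace(200.0, 0.1, A, period_s=4.0,
                                  axis_weights=(0, 0, 1))
        dense = A * np.sin(2 * np.pi * np.linspace(0, 1, 200001)[:-1])
        oracle = np.quantile(dense, 0.9) - np.quantile(dense, 0.1)
        got = np.quantile(tr.disp[:, 2], 0.9) - np.quantile(tr.disp[:, 2], 0.1)
        assert abs(got - oracle) / oracle < 0.01
        assert abs(oracle - 1.902 * A) / (1.902 * A) < 1e-3

    def test_seed_determinism(self):
        kw = dict(duration_s=20, TR_s=0.25, amplitude_mm=10,
                  amp_jitter=0.3, drift_mm_per_min=2.0)
        a = make_breathing_trace(**kw, seed=11)
        b = make_breathing_trace(**kw, seed=11)
        c = make_breathing_trace(**kw, seed=12)
        assert np.array_equal(a.disp, b.disp)
        assert not np.array_equal(a.disp, c.disp)

    def test_jitter_varies_cycle_amplitudes(self):
        tr = make_breathing_trace(40, 0.1, 10.0, period_s=4.0,
                                  amp_jitter=0.3, axis_weights=(0, 0, 1),
                                  seed=5)
        peaks = [np.abs(tr.disp[i:i + 40, 2]).max()
                 for i in range(0, 400, 40)]
        assert np.std(peaks) > 0.1


class TestStepTrace:
    def test_phantom_parameters_reach_40mm(self):
        tr = make_step_trace(step_mm=4.0, steps_per_excursion=10)
        assert np.isclose(np.abs(tr.disp).max(), 40.0)

    def test_single_step_alternates(self):
        tr = make_step_trace(4.0, 1, n_cycles=3)
        assert np.allclose(tr.disp[:, 2], [0, 4, 0, 4, 0, 4, 0])

    def test_all_samples_are_step_multiples(self):
        tr = make_step_trace(4.0, 10, n_cycles=2)
        assert np.allclose(tr.disp[:, 2] % 4.0, 0)

    def test_per_tr_increment_is_one_step(self):
        tr = make_step_trace(4.0, 10)
        assert np.allclose(np.abs(np.diff(tr.disp[:, 2])), 4.0)


class TestMotionTrace:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            MotionTrace(t=np.array([0.0, 1.0, 0.5]), disp=np.zeros((3, 3)))

    def test_sample_interpolates(self):
        tr = MotionTrace(t=np.array([0.0, 1.0]),
                         disp=np.array([[0, 0, 0], [2, 4, 6]], dtype=float))
        assert np.allclose(tr.sample(0.5), (1, 2, 3))


class TestRenderNavigator:
    def test_centered_symmetric_when_static(self, coronal, noiseless_spec):
        img = render_navigator(coronal, noiseless_spec, (0, 0, 0))
        assert np.allclose(img, img[::-1, :])
        assert np.allclose(img, img[:, ::-1])
        assert np.allclose(centroid(img), ((64 - 1) / 2, (64 - 1) / 2))

    def test_centroid_follows_in_plane_shift(self, coronal, noiseless_spec):
        d3 = nm.image_to_patient((2, 0), coronal)
        img = render_navigator(coronal, noiseless_spec, d3)
        ref = render_navigator(coronal, noiseless_spec, (0, 0, 0))
        shift = centroid(img) - centroid(ref)
        assert np.allclose(shift, (2, 0), atol=0.05)

    def test_through_plane_shift_shrinks_then_vanishes(self, coronal):
        spec = PhantomSpec(target_radius=20.0, noise_sigma=0.0)
        full = render_navigator(coronal, spec, (0, 0, 0))
        # coronal normal is e1 x e2 = (0,-1,0): displace along AP
        half = render_navigator(coronal, spec, (0, 15.0, 0))
        gone = render_navigator(coronal, spec, (0, 20.0, 0))
        area = lambda im: np.sum(im > 0.5)
        assert 0 < area(half) < area(full)
        assert np.allclose(gone, spec.background_intensity)

    def test_target_outside_fov_gives_background(self, coronal, noiseless_spec):
        d3 = nm.image_to_patient((200, 0), coronal)
        img = render_navigator(coronal, noiseless_spec, d3)
        assert np.allclose(img, noiseless_spec.background_intensity)

    def test_coil_falloff_darkens_with_depth(self, coronal):
        spec = PhantomSpec(noise_sigma=0.0, coil_falloff_scale=80.0)
        img = render_navigator(coronal, spec, (0, 0, 0))
        assert img[60, 32] < img[4, 32]

    @pytest.mark.parametrize("shape", ["disc", "ellipse", "ring"])
    def test_shapes_render(self, coronal, shape):
        spec = PhantomSpec(target_shape=shape, noise_sigma=0.0)
        img = render_navigator(coronal, spec, (0, 0, 0))
        assert img.max() > img.min()

    def test_rician_noise_floor_and_determinism(self, coronal):
        spec = PhantomSpec(noise_sigma=0.1)
        a = render_navigator(coronal, spec, (0, 0, 0), seed=3)
        b = render_navigator(coronal, spec, (0, 0, 0), seed=3)
        assert np.array_equal(a, b)
        assert (a >= 0).all()  # magnitude images are nonnegative


class TestSimulateSeries:
    def test_static_trace_frames_identical_up_to_noise(self, coronal):
        trace = MotionTrace(t=np.arange(5.0), disp=np.zeros((5, 3)))
        series = simulate_series({"cor": coronal}, trace,
                                 PhantomSpec(noise_sigma=0.0), seed=0)
        imgs = series.images["cor"]
        assert all(np.array_equal(imgs[0], f) for f in imgs[1:])
        assert np.allclose(series.truth_px["cor"], 0)

    def test_seed_gives_bit_identical_series(self, coronal):
        trace = nm.make_breathing_trace(3, 0.25, 10, seed=0)
        a = simulate_series({"cor": coronal}, trace, PhantomSpec(), seed=9)
        b = simulate_series({"cor": coronal}, trace, PhantomSpec(), seed=9)
        assert np.array_equal(a.images["cor"], b.images["cor"])

    def test_shared_hf_axis_on_orthogonal_planes(self, coronal, sagittal):
        # HF motion appears identically on the image-y axis of both planes
        trace = MotionTrace(
            t=np.arange(4.0),
            disp=np.outer([0, 5, 10, 5], [0.0, 0.0, 1.0]))
        series = simulate_series({"cor": coronal, "sag": sagittal}, trace,
                                 PhantomSpec(noise_sigma=0.0),
                                 nav_duration_per_slice_s=0.0, seed=0)
        assert np.allclose(series.truth_px["cor"], series.truth_px["sag"])

    def test_truth_matches_projection_at_slice_midtime(self, coronal, sagittal):
        trace = nm.make_breathing_trace(10, 0.5, 12, seed=1)
        series = simulate_series([sagittal, coronal], trace, PhantomSpec(),
                                 nav_duration_per_slice_s=0.07, seed=1)
        for s, name in enumerate(series.names):
            t_mid = trace.t + (s + 0.5) * 0.07
            expected = nm.patient_to_image(trace.sample(t_mid),
                                           series.planes[name])
            assert np.allclose(series.truth_px[name], expected)

    def test_ground_truth_fusion_recovers_trace(self, coronal, sagittal):
        """Fusing the exact per-slice truth reproduces the 3D trace."""
        trace = nm.make_breathing_trace(10, 0.5, 12,
                                        axis_weights=(0.5, 0.3, 1.0), seed=2)
        series = simulate_series({"cor": coronal, "sag": sagittal}, trace,
                                 PhantomSpec(noise_sigma=0.0),
                                 nav_duration_per_slice_s=0.0, seed=0)
        log = nm.run_prospective(series, "truth",
                                 latency=nm.LatencyModel(0.0, 0.0, 0.5),
                                 cfg=FusionConfig(tau=0.05))
        assert np.abs(log.residual).max() < 0.02
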