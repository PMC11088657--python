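import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import navmoco as nm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def identity_plane():
    """Plane whose basis is the identity embedding (x->LR, y->AP), 1 mm px."""
    return nm.SlicePlane(e1=[1.0, 0.0, 0.0], e2=[0.0, 1.0, 0.0],
                         pixel_size=(1.0, 1.0), dims=(64, 64))


@pytest.fixture
def coronal():
    return nm.named_plane("coronal", (2.7, 2.7), (64, 64))


@pytest.fixture
def sagittal():
    return nm.named_plane("sagittal", (2.7, 2.7), (64, 64))


@pytest.fixture
def noiseless_spec():
    return nm.PhantomSpec(noise_sigma=0.0)


@pytest.fixture
def disc_frame(coronal, noiseless_spec):
    """Noiseless reference navigator frame with the disc centred."""
    return nm.render_navigator(coronal, noiseless_spec, (0.0, 0.0, 0.0))


def make_sin_series(snr=10.0, amplitude_mm=12.0, n_frames=50, seed=0,
                    planes=None, tr_s=0.25):
    """Sinusoidal-motion navigator series at a given SNR (1/noise_sigma)."""
    if planes is None:
        planes = {"cor": nm.named_plane("coronal", (2.7, 2.7), (64, 64))}
    trace = nm.make_breathing_trace(
        duration_s=(n_frames - 1) * tr_s, TR_s=tr_s,
        amplitude_mm=amplitude_mm, period_s=4.0,
        axis_weights=(0.3, 0.1, 1.0), seed=seed)
    sigma = 0.0 if np.isinf(snr) else 1.0 / snr
    return nm.simulate_series(
        planes, trace, nm.PhantomSpec(noise_sigma=sigma),
        nav_duration_per_slice_s=0.0, seed=seed)
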