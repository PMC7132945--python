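import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import commissura as cm
from commissura.tensor import OrientationField

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom():
    """Noise-free human-flavor commissural phantom with its ground truth."""
    dwi, field, truth = cm.build_phantom("dhc_default", flavor="human")
    return dwi, field, truth


@pytest.fixture(scope="session")
def tracking_params():
    return cm.TrackingParams()


@pytest.fixture(scope="session")
def bilateral(phantom, tracking_params):
    """Gated left- and right-seeded tractograms of the phantom commissure."""
    _, field, truth = phantom
    return cm.run_bilateral_protocol(field, truth.protocol, tracking_params)


@pytest.fixture(scope="session")
def fa_md_maps(phantom):
    """Noise-free tensor fit of the phantom -> (FA map, MD map)."""
    dwi, _, _ = phantom
    tf = cm.fit_tensor_lls(dwi)
    return cm.compute_fa_md(tf)


def make_uniform_field(shape, regions, affine=None):
    """Hand-built orientation field for small tracking fixtures.

    ``regions`` is a list of (mask, direction, amplitude) or
    (mask, [(direction, amplitude), ...]) entries; later entries append
    extra peaks to overlapping voxels.
    """
    if affine is None:
        affine = np.eye(4)
    shape = tuple(shape)
    flat_peaks = []
    for mask, *rest in regions:
        if len(rest) == 1 and isinstance(rest[0], list):
            entries = rest[0]
        else:
            entries = [tuple(rest)]
        flat_peaks.append((np.asarray(mask, dtype=bool), entries))
    max_p = max(1, sum(len(e) for _, e in flat_peaks))
    peaks = np.zeros(shape + (max_p, 3))
    amps = np.zeros(shape + (max_p,))
    n_peaks = np.zeros(shape, dtype=np.int64)
    for mask, entries in flat_peaks:
        for d, a in entries:
            d = np.asarray(d, dtype=float)
            d = d / np.linalg.norm(d)
            idx = np.argwhere(mask)
            for i, j, k in idx:
                s = n_peaks[i, j, k]
                peaks[i, j, k, s] = d
                amps[i, j, k, s] = a
                n_peaks[i, j, k] = s + 1
    support = n_peaks > 0
    return OrientationField(peaks, amps, n_peaks, support, affine)
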