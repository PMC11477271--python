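import numpy as np
import pytest

from nquant import CellSpec, ImagingParams, generate_neuron_scene


@pytest.fixture
def small_params():
    return ImagingParams(image_shape=(160, 160), seed=11)


@pytest.fixture
def one_cell_spec():
    """Soma disk r=10 at (60,60) with one straight 3-px-wide neurite."""
    return CellSpec(soma_center=(60, 60), soma_radius=10,
                    neurites=[([(60, 70), (60, 120)], 3.0)])


@pytest.fixture
def one_cell_scene(one_cell_spec, small_params):
    return generate_neuron_scene([one_cell_spec], small_params)


@pytest.fixture
def one_cell_scene_noise_free(one_cell_spec, small_params):
    return generate_neuron_scene([one_cell_spec], small_params.noise_free())


def brute_force_disk_area(center, radius, shape):
    """Independent pixel-count oracle for a rasterized disk."""
    n = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius ** 2:
                n += 1
    return n


def brute_force_segment_area(p0, p1, width, shape, exclude=None):
    """Pixel-count oracle for a thick segment (round caps), optionally
    excluding pixels for which ``exclude(r, c)`` is true."""
    a = np.asarray(p0, float)
    b = np.asarray(p1, float)
    ab = b - a
    denom = float(ab @ ab)
    n = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            p = np.array([r, c], float)
            t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
            d = np.hypot(*(p - (a + t * ab)))
            if d <= width / 2 and not (exclude and exclude(r, c)):
                n += 1
    return n
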