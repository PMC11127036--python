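import numpy as np
import pytest

from plexiquant import SynthFieldParams, generate_coculture_field, generate_section_image
from plexiquant.micrograph import BinaryMask, CellObject, Micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def coculture_field():
    """One deterministic noiseless co-culture field with truth."""
    return generate_coculture_field(SynthFieldParams(seed=42))


@pytest.fixture(scope="session")
def section_field():
    """One deterministic noiseless section with 4 ganglia and truth."""
    params = SynthFieldParams(
        seed=42, image_size_px=(512, 512), n_tcells=3, tcell_radius_um=3.5
    )
    return generate_section_image(params, n_ganglia=4, tcell_rate_per_ganglion=2.42)


def make_mask(array, pixel_size_um=1.0):
    return BinaryMask(np.asarray(array, dtype=bool), pixel_size_um)


def make_object(pixels, pixel_size_um=1.0, object_id=1):
    return CellObject(
        object_id=object_id, pixels=np.asarray(pixels, dtype=int), pixel_size_um=pixel_size_um
    )


def brute_force_overlap(tcell_pixels, glia_mask):
    """Pixel-loop oracle for the overlap fraction."""
    inside = 0
    for r, c in tcell_pixels:
        if glia_mask[r, c]:
            inside += 1
    return inside / len(tcell_pixels)


def brute_force_min_chebyshev(pixels_a, pixels_b):
    """All-pairs minimum Chebyshev distance oracle."""
    best = None
    for ra, ca in pixels_a:
        for rb, cb in pixels_b:
            d = max(abs(int(ra) - int(rb)), abs(int(ca) - int(cb)))
            if best is None or d < best:
                best = d
    return best
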