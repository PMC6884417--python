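import numpy as np
import pytest

from blastoquant.imaging import Projection, ROI
from blastoquant.simulate import ImageSimParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_image_params(**overrides) -> ImageSimParams:
    """A scaled-down stack configuration for simulation-heavy tests.

    Keeps the default regime (thin equatorial slab, bright sparse spots on
    near-zero background) but at ~1/30 of the pixel count so that
    replicate studies fit the test budget.
    """
    base = dict(
        image_shape=(96, 96),
        n_slices=11,
        geometry="oocyte",
        blastomere_radii_px=(30.0,),
        n_spots=300,
        seed=0,
    )
    base.update(overrides)
    return ImageSimParams(**base)


def density_matched_params(**overrides) -> ImageSimParams:
    """Scaled-down stack whose dimensionless spot coverage matches the
    full-size defaults.

    The maximum-intensity projection saturates where spot columns overlap,
    so a faithful scale-down must preserve the coverage fraction
    n_window * pi*(2 sigma)^2 / (pi r^2) (~0.16 at the 512x512 defaults),
    not the absolute spot count: r 140->40 px, PSF sigma 1->0.6 px,
    n_spots 2000->195.
    """
    base = dict(
        image_shape=(128, 128),
        n_slices=11,
        geometry="oocyte",
        blastomere_radii_px=(40.0,),
        psf_sigma_px=0.6,
        n_spots=195,
        seed=0,
    )
    base.update(overrides)
    return ImageSimParams(**base)


@pytest.fixture
def constant_projection():
    return Projection(
        pixels=np.full((16, 16), 3.0), source_slices=(0, 1), span_um=0.22
    )


@pytest.fixture
def full_roi():
    return ROI(mask=np.ones((16, 16), bool), kind="whole_embryo", label="e")
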