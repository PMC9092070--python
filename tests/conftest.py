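import numpy as np
import pytest

from retinaquant.synthgen import PhantomSpec, generate_section


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_spec():
    """Flat layers, no curvature/noise/blur, single well-separated cells."""
    return PhantomSpec(
        width_px=200, height_px=200,
        rnfl_px=20.0, ipl_px=30.0, inl_px=25.0, opl_px=10.0,
        curvature_amplitude_px=0.0,
        cell_count=8, cell_radius_px=4.0, cell_clump_fraction=0.0,
        vacuole_density=0.0, noise_sigma=0.0, blur_sigma=0.0,
        top_margin_px=20.0, seed=7,
    )


@pytest.fixture
def flat_section(flat_spec):
    return generate_section(flat_spec)


@pytest.fixture
def small_section():
    spec = PhantomSpec(
        width_px=64, height_px=64,
        rnfl_px=8.0, ipl_px=10.0, inl_px=8.0, opl_px=5.0,
        cell_count=2, cell_radius_px=3.0, top_margin_px=8.0,
        noise_sigma=3.0, blur_sigma=0.4, seed=11,
    )
    return generate_section(spec)
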