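import numpy as np
import pytest

from chipcyto.simulate import CellCycleMixture, OpticsConfig, render_field, sample_dna_contents


@pytest.fixture(scope="session")
def cycling_mixture() -> CellCycleMixture:
    """Default two-peak population: G1-dominated with an S band and a 4N peak."""
    return CellCycleMixture(f_g1=0.55, f_s=0.20, f_g2m=0.25, cv=0.06)


@pytest.fixture(scope="session")
def small_optics() -> OpticsConfig:
    """Small, fast field in the bright linear regime used by unit tests."""
    return OpticsConfig(
        exposure_ms=5.0,
        gain=360.0,
        detector_max=65535,
        background_mean=100.0,
        background_sd=1.0,
        nucleus_radius_px=(5.0, 0.5),
        field_shape=(300, 300),
        cells_per_field=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def rendered_field(cycling_mixture, small_optics):
    """One rendered field with ground truth (20 separated nuclei)."""
    contents = sample_dna_contents(cycling_mixture, 20, seed=3)
    return render_field(contents, small_optics)
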