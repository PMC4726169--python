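import numpy as np
import pytest

from goldendose.enhancement import EnhancementConfig
from goldendose.physics import (
    fit_range_model,
    load_attenuation_table,
    load_gold_shells,
)
from goldendose.synthetic import SyntheticCellSpec, make_cell_image


@pytest.fixture(scope="session")
def shells():
    return load_gold_shells()


@pytest.fixture(scope="session")
def gold_photo():
    return load_attenuation_table("gold", "photoelectric")


@pytest.fixture(scope="session")
def water_total():
    return load_attenuation_table("water", "total")


@pytest.fixture(scope="session")
def range_model():
    return fit_range_model()


@pytest.fixture(scope="session")
def default_config():
    """Model defaults on the coarse 1 keV grid (fast to evaluate)."""
    return EnhancementConfig(energy_grid=np.arange(10.0, 61.0, 1.0))


@pytest.fixture(scope="session")
def noisy_cell():
    """One default synthetic cell (perinuclear ring + cytoplasm, Poisson noise)."""
    spec = SyntheticCellSpec(seed=7)
    image, truth = make_cell_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_cell():
    """Noise-free counterpart of the default synthetic cell."""
    spec = SyntheticCellSpec(seed=7, noise=False)
    image, truth = make_cell_image(spec)
    return spec, image, truth
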