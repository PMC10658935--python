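import numpy as np
import pytest

from dcebench.synthetic import (
    DEFAULT_KINETICS,
    ProtocolConfig,
    generate_dce_case,
)
from dcebench.types import EnhancementType, LesionSpec, Pathology


@pytest.fixture(scope="session")
def protocol() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture(scope="session")
def clean_protocol() -> ProtocolConfig:
    """Zero noise, spatially uniform background: analytically tractable."""
    return ProtocolConfig(noise_sigma_frac=0.0, background_texture_frac=0.0)


def make_case(
    enhancement=EnhancementType.MASS,
    pathology=Pathology.MALIGNANT,
    diameter=10.0,
    seed=11,
    protocol=None,
    case_id="case",
):
    spec = LesionSpec(
        enhancement_type=enhancement,
        pathology=pathology,
        effective_diameter_mm=diameter,
        kinetic=DEFAULT_KINETICS[pathology],
        seed=seed,
    )
    return generate_dce_case(spec, protocol or ProtocolConfig(), case_id=case_id)


@pytest.fixture(scope="session")
def mass_case(protocol):
    return make_case(protocol=protocol, case_id="mass0")


@pytest.fixture(scope="session")
def clean_mass_case(clean_protocol):
    return make_case(protocol=clean_protocol, case_id="mass_clean")


@pytest.fixture(scope="session")
def nonmass_case(protocol):
    return make_case(
        enhancement=EnhancementType.NONMASS,
        pathology=Pathology.BENIGN,
        protocol=protocol,
        seed=23,
        case_id="nonmass0",
    )


def random_mask(rng: np.random.Generator, shape=(12, 12), p=0.3) -> np.ndarray:
    return rng.uniform(size=shape) < p
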