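import numpy as np
import pytest

from axonrve.config import GeometryConfig
from axonrve.constitutive import OgdenMaterial
from axonrve.fe import MaterialSet
from axonrve.geometry import build_rve


@pytest.fixture(scope="session")
def default_rve():
    """RVE under the study's default conditions (53% fraction, seed 1)."""
    return build_rve(GeometryConfig(), seed=1)


@pytest.fixture(scope="session")
def sparse_rve():
    """A light RVE (8% fiber fraction) for fast FE exercises."""
    return build_rve(GeometryConfig(target_volume_fraction=0.08), seed=3)


@pytest.fixture(scope="session")
def tissue_material():
    """Ogden parameters fitted to embryonic spinal-cord tension data."""
    return OgdenMaterial(32.8, 8.22)


@pytest.fixture(scope="session")
def material_set():
    """Axon/ECM pair at the identified axon modulus, 3x stiffness ratio."""
    return MaterialSet.from_axon_modulus(33.28, 8.22)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
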