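"""Shared fixtures: default materials/geometry and a small, fast probe.

The small probe trades the full-size acquisition (100 MHz, 512 lines) for a
20 MHz / 96-line configuration over the same tumor region, keeping RF
synthesis and tracking tests to a few seconds without changing any physics.
"""

import numpy as np
import pytest
from hypothesis import settings

from elastinv.mr_core import BREAST_MATERIALS, MRParams

# fully deterministic property tests: fixed example generation, no timing
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from elastinv.phantom_forward import LoadSpec, PhantomGeometry
from elastinv.rf_sim import ProbeConfig


@pytest.fixture(scope="session")
def tumor() -> MRParams:
    return BREAST_MATERIALS["tumor"]


@pytest.fixture(scope="session")
def fat() -> MRParams:
    return BREAST_MATERIALS["fat"]


@pytest.fixture(scope="session")
def fibroglandular() -> MRParams:
    return BREAST_MATERIALS["fibroglandular"]


@pytest.fixture(scope="session")
def known_materials(fat, fibroglandular) -> dict:
    return {"fat": fat, "fibroglandular": fibroglandular}


@pytest.fixture(scope="session")
def geometry() -> PhantomGeometry:
    return PhantomGeometry()


@pytest.fixture(scope="session")
def load() -> LoadSpec:
    return LoadSpec()


@pytest.fixture(scope="session")
def small_probe() -> ProbeConfig:
    return ProbeConfig(
        center_frequency_hz=3.5e6,
        sampling_frequency_hz=20e6,
        n_lines=96,
        lateral_spacing_mm=0.15,
        axial_window_mm=(55.0, 95.0),
        lateral_sigma_mm=0.3,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
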