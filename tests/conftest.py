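from __future__ import annotations

import numpy as np
import pytest

from migdetour import GeoPoint, Polyline, SimulationConfig

#: Breeding and wintering sites of the study system.
BREEDING = GeoPoint(100.2, 36.8)
WINTERING = GeoPoint(90.0, 22.0)


@pytest.fixture
def breeding() -> GeoPoint:
    return BREEDING


@pytest.fixture
def wintering() -> GeoPoint:
    return WINTERING


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def zigzag_route(rng) -> Polyline:
    """A 50-segment jittered route between the two sites."""
    n_seg = 50
    base = np.linspace(BREEDING.as_tuple(), WINTERING.as_tuple(), n_seg + 1)
    base[1:-1] += rng.normal(0.0, 0.8, size=(n_seg - 1, 2))
    return Polyline(base)


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A fast population: 3 individuals x 2 years x both seasons."""
    return SimulationConfig(
        n_individuals=3,
        years_per_individual=(2, 2, 2),
        seed=42,
    )
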