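import math

import numpy as np
import pytest

from sweatsense.optics_model import (
    Composition,
    LayerOptics,
    SkinStack,
    WavelengthGrid,
    build_skin_stack,
)
from sweatsense.synthetic_ppg import RunProfile, generate_run


@pytest.fixture(scope="session")
def nir_grid():
    return WavelengthGrid((970.0, 1450.0))


@pytest.fixture(scope="session")
def default_stack(nir_grid):
    return build_skin_stack(grid=nir_grid)


def toy_stack(layers, n_ambient=1.0):
    """Ad-hoc stack (any layer count) for transport physics tests."""
    grid = WavelengthGrid((970.0,))
    return SkinStack(
        grid=grid,
        layers=tuple(layers),
        composition=Composition(),
        film_thickness_mm=0.0,
        n_ambient=n_ambient,
    )


def toy_layer(thickness, mua, mus, g=0.0, n=1.0, name="slab"):
    return LayerOptics(
        name=name,
        thickness=thickness,
        mu_a=np.array([float(mua)]),
        mu_s=np.array([float(mus)]),
        g=float(g),
        n=float(n),
    )


@pytest.fixture(scope="session")
def short_runs():
    """Eight quick low-duration runs for classification-layer tests."""
    profile = RunProfile(duration_s=600.0)
    return [generate_run(profile, seed=100 + i) for i in range(8)]
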