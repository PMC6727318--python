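import numpy as np
import pytest

from planqa.core import BinaryMask, DoseGrid, VoxelGrid
from planqa.synthetic import (
    BeamSpec,
    PerturbationSpec,
    PhantomSpec,
    make_case,
    make_phantom,
)


def small_phantom_spec(seed: int = 1, **overrides) -> PhantomSpec:
    """A compact pelvis phantom: fast enough for end-to-end tests."""
    kwargs = dict(
        body_semi_axes_mm=(80.0, 60.0),
        body_length_mm=80.0,
        spacing_mm=2.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def small_beams(**overrides) -> BeamSpec:
    kwargs = dict(n_beams=7, half_width_mm=30.0)
    kwargs.update(overrides)
    return BeamSpec(**kwargs)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def zero_case():
    """Zero-perturbation synthetic case: pseudo-CT identical to CT."""
    return make_case(small_phantom_spec(), PerturbationSpec(), small_beams())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def uniform_dose(value: float, n: int = 20, spacing: float = 2.0) -> DoseGrid:
    origin = -np.ones(3) * (n - 1) / 2 * spacing
    grid = VoxelGrid(origin, np.full(3, spacing), np.full((n, n, n), float(value)))
    return DoseGrid(grid, np.zeros(3))


def full_mask(dose: DoseGrid) -> BinaryMask:
    return BinaryMask.like(dose.grid, np.ones(dose.grid.dims, dtype=bool))
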