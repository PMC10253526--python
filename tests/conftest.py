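import numpy as np
import pytest

from radchemxt.chemistry import (
    Reaction,
    ReactionNetwork,
    Species,
    build_default_network,
)
from radchemxt.radial_field import ConcentrationField, RadialGrid, SystemState

K_SI = 1e-9  # M^-1 s^-1 -> M^-1 ns^-1


@pytest.fixture
def default_net():
    return build_default_network()


@pytest.fixture
def oxic_net():
    return build_default_network(po2=0.21)


@pytest.fixture
def small_grid():
    """bw = 20 nm, r_max = 2 um, h = 10 um — light but realistic."""
    return RadialGrid(bin_width=20.0, n_bins=100, track_length=1.0e4)


@pytest.fixture
def default_grid():
    return RadialGrid.default()


def make_state(grid, concentrations, time=0.0, flattened=False):
    """SystemState with spatially uniform per-species concentrations."""
    fields = {}
    for name, c in concentrations.items():
        fields[name] = ConcentrationField(
            name, np.full(grid.n_bins, float(c)),
            flattened=flattened, flat_value=float(c),
        )
    return SystemState(time, grid, fields)


def make_gaussian_state(grid, name, sigma, amplitude=1e-6, time=0.0):
    """Single-species Gaussian radial profile exp(-r^2 / 2 sigma^2)."""
    r = grid.bin_centers
    vals = amplitude * np.exp(-(r**2) / (2.0 * sigma**2))
    return SystemState(time, grid, {name: ConcentrationField(name, vals)})


def simple_network(reactions, species_names=("A", "B", "C"), diffusion=0.0):
    """Tiny ad-hoc network for kinetics tests; k given in M^-1 s^-1."""
    species = [Species(n, diffusion) for n in species_names]
    rxs = [Reaction(tuple(r), tuple(p), k * K_SI) for r, p, k in reactions]
    return ReactionNetwork(species=species, reactions=rxs)
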