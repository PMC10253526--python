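"""Synthetic track snapshots standing in for the Monte Carlo front-end.

The generator produces per-species discrete coordinates around the track
axis at the hand-over time: Poisson counts, a radially Gaussian profile
(optionally a core+penumbra mixture) and axial homogeneity.  The presets
are *fixtures* — tunable, approximately track-like parameter sets — not
reproductions of any measured yield table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemistry import ReactionNetwork
from .radial_field import POSITIONS_COLUMNS, RadialGrid, SystemState

__all__ = [
    "TrackModel",
    "sample_track_positions",
    "apply_o2_exposure",
    "uniform_random_state",
    "low_let_preset",
    "high_let_preset",
]


@dataclass(frozen=True)
class TrackModel:
    """Parameters of one synthetic track snapshot.

    ``yields`` are expected molecules per track per species at the snapshot
    time; ``sigma_nm`` is the radial Gaussian scale (one value for all
    species or a per-species mapping).  With ``penumbra_sigma_nm`` set, a
    fraction ``1 - core_weight`` of each species is drawn from the wider
    penumbra component.
    """

    yields: dict[str, float]
    sigma_nm: float | dict[str, float]
    let: float  # keV/um
    track_length_nm: float
    seed: int | None = None
    t_in_ns: float = 500.0
    core_weight: float = 1.0
    penumbra_sigma_nm: float | None = None

    def __post_init__(self) -> None:
        if any(y < 0 for y in self.yields.values()):
            raise ValueError("yields must be non-negative")
        sigmas = (self.sigma_nm.values() if isinstance(self.sigma_nm, dict)
                  else [self.sigma_nm])
        if any(s <= 0 for s in sigmas):
            raise ValueError("sigma must be positive")
        if not 0.0 < self.core_weight <= 1.0:
            raise ValueError("core_weight must be in (0, 1]")

    def sigma_for(self, species: str) -> float:
        if isinstance(self.sigma_nm, dict):
            return self.sigma_nm[species]
        return self.sigma_nm


def sample_track_positions(
    model: TrackModel,
    n_tracks: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample discrete species coordinates for ``n_tracks`` pooled tracks.

    Per species the count is Poisson(n_tracks * yield); x, y are drawn from
    an isotropic Gaussian of the species' radial scale and z uniformly along
    the track.  Reproducible for a fixed ``model.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    frames = []
    for species in sorted(model.yields):
        mean = model.yields[species] * n_tracks
        count = int(rng.poisson(mean)) if mean > 0 else 0
        if count == 0:
            continue
        sigma = model.sigma_for(species)
        if model.penumbra_sigma_nm is not None and model.core_weight < 1.0:
            in_core = rng.random(count) < model.core_weight
            scale = np.where(in_core, sigma, model.penumbra_sigma_nm)
        else:
            scale = sigma
        x = rng.normal(0.0, 1.0, count) * scale
        y = rng.normal(0.0, 1.0, count) * scale
        z = rng.uniform(0.0, model.track_length_nm, count)
        frames.append(pd.DataFrame({
            "species": species, "x_nm": x, "y_nm": y, "z_nm": z,
        }))
    if not frames:
        return pd.DataFrame(columns=POSITIONS_COLUMNS)
    return pd.concat(frames, ignore_index=True)[POSITIONS_COLUMNS]


#: First-order O2-scavenging channels applied during the pre-snapshot
#: exposure: reactant -> product of the corresponding reaction with O2.
_O2_CONVERSIONS = {"e_aq-": "O2-", "H": "HO2"}


def apply_o2_exposure(
    positions: pd.DataFrame,
    net: ReactionNetwork,
    duration_ns: float,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Emulate dissolved-O2 scavenging during the pre-snapshot stage.

    In an oxygenated medium the scavenging channels e_aq- + O2 -> O2- and
    H + O2 -> HO2 act from the very start of the chemical stage, so a
    snapshot taken at the hand-over time already contains mostly the
    products.  Each reducing radical is converted to its O2 product with
    probability 1 - exp(-k [O2] t), using the network's own rate constants
    and continuum O2 molarity; positions are kept.
    """
    if duration_ns < 0:
        raise ValueError("duration must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    o2 = net.continuum_concentrations.get("O2", 0.0)
    out = positions.copy()
    if o2 <= 0.0 or duration_ns == 0.0 or len(out) == 0:
        return out
    species = out["species"].to_numpy().copy()
    for reactant, product in _O2_CONVERSIONS.items():
        try:
            rx = net.find_reaction(f"{reactant}+O2->{product}")
        except KeyError:
            continue
        p_convert = 1.0 - math.exp(-rx.rate_constant * o2 * duration_ns)
        sel = species == reactant
        converted = sel & (rng.random(len(out)) < p_convert)
        species[converted] = product
    out["species"] = species
    return out


def uniform_random_state(
    grid: RadialGrid,
    species_names,
    concentration_range: tuple[float, float] = (1e-9, 1e-6),
    seed: int | None = None,
) -> SystemState:
    """Uniform "dummy" state: one log-uniform concentration per species,
    constant across bins and already flattened."""
    lo, hi = concentration_range
    if lo <= 0 or hi < lo:
        raise ValueError("need 0 < lo <= hi concentration range")
    rng = np.random.default_rng(seed)
    state = SystemState.zeros(grid, list(species_names))
    for name in species_names:
        c = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        fld = state.fields[name]
        fld.values = np.full(grid.n_bins, c)
        fld.flattened = True
        fld.flat_value = c
    return state


def low_let_preset(seed: int | None = 0) -> TrackModel:
    """Dilute, electron-like track fixture (~0.2 keV/um, h = 10 um).

    Yields follow typical late-heterogeneous-stage low-LET G-values
    (molecules per 100 eV, times the 2 keV deposited per track); the radial
    scale reflects a few hundred ns of free diffusion.  Only categories
    (i)/(ii) are seeded.
    """
    e_dep_100ev = 0.2 * 10.0 * 1e3 / 100.0  # deposited energy / 100 eV
    g = {
        "OH": 2.8, "e_aq-": 2.9, "H3O+": 3.3, "H": 0.62,
        "H2": 0.40, "H2O2": 0.55, "OH-": 0.45,
    }
    return TrackModel(
        yields={k: v * e_dep_100ev for k, v in g.items()},
        sigma_nm=150.0,
        let=0.2,
        track_length_nm=1.0e4,
        seed=seed,
    )


def high_let_preset(seed: int | None = 0) -> TrackModel:
    """Dense, carbon-like track fixture (~160 keV/um, h = 2 um).

    Lower per-100 eV yields and a narrow core mimic the heavier
    recombination of densely ionising radiation; a faint penumbra component
    stands in for secondary-electron spread.
    """
    e_dep_100ev = 160.0 * 2.0 * 1e3 / 100.0
    g = {
        "OH": 1.4, "e_aq-": 1.2, "H3O+": 1.9, "H": 0.45,
        "H2": 0.65, "H2O2": 0.75, "OH-": 0.15,
    }
    return TrackModel(
        yields={k: v * e_dep_100ev for k, v in g.items()},
        sigma_nm=35.0,
        let=160.0,
        track_length_nm=2.0e3,
        seed=seed,
        core_weight=0.9,
        penumbra_sigma_nm=300.0,
    )
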