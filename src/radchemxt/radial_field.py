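"""Radial grid, concentration fields, binning and observables.

Geometry: a cylinder of radius ``r_max`` and height ``track_length`` around
the track axis (z).  Concentration histograms live on a uniform radial grid
whose first edge is exactly 0; bin j covers the annulus [e_j, e_{j+1}) and
carries one molarity value, averaged over the ``n_tracks`` input tracks.

Internal units: nm, ns, mol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import CATEGORIES
from .constants import (
    AVOGADRO,
    CM_TO_NM,
    DOSE_LET_PREFACTOR,
    KEV_TO_EV,
    NM3_TO_L,
)

__all__ = [
    "RadialGrid",
    "ConcentrationField",
    "SystemState",
    "BeamSpec",
    "GValueRecord",
    "bin_positions",
    "total_amount",
    "gvalues",
    "category_sums",
    "deviation",
    "dose_from_fluence",
    "surface_from_fluence",
    "read_positions_csv",
    "write_positions_csv",
    "read_state_csv",
    "write_state_csv",
    "write_gvalues_csv",
    "read_gvalues_csv",
]

POSITIONS_COLUMNS = ["species", "x_nm", "y_nm", "z_nm"]
STATE_COLUMNS = ["species", "bin_index", "concentration_M"]


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial histogram grid on [0, r_max] with track length h."""

    bin_width: float  # nm
    n_bins: int
    track_length: float  # nm

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.track_length <= 0:
            raise ValueError("bin_width and track_length must be positive")
        if self.n_bins < 3:
            raise ValueError("need at least 3 radial bins")

    @classmethod
    def from_rmax(cls, bin_width: float, r_max: float, track_length: float
                  ) -> "RadialGrid":
        n = round(r_max / bin_width)
        if not np.isclose(n * bin_width, r_max, rtol=1e-9):
            raise ValueError("r_max must be an integer multiple of bin_width")
        return cls(bin_width, int(n), track_length)

    @classmethod
    def default(cls) -> "RadialGrid":
        """bw = 20 nm, r_max = 5 um (J = 250), h = 10 um."""
        return cls(bin_width=20.0, n_bins=250, track_length=1.0e4)

    @property
    def r_max(self) -> float:
        return self.bin_width * self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def bin_volumes_l(self) -> np.ndarray:
        """Annulus volumes pi (e_{j+1}^2 - e_j^2) h, in litres."""
        e = self.bin_edges
        return np.pi * (e[1:] ** 2 - e[:-1] ** 2) * self.track_length * NM3_TO_L

    @property
    def total_volume_l(self) -> float:
        return float(np.pi * self.r_max**2 * self.track_length * NM3_TO_L)


@dataclass
class ConcentrationField:
    """One species' radial concentration histogram."""

    species: str
    values: np.ndarray  # molarity at bin centers
    flattened: bool = False
    flat_value: float = 0.0

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(self.species, self.values.copy(),
                                  self.flattened, self.flat_value)


@dataclass
class SystemState:
    """Time plus all concentration fields on a shared radial grid."""

    time: float  # ns
    grid: RadialGrid
    fields: dict[str, ConcentrationField]
    n_tracks_averaged: int = 1

    def copy(self) -> "SystemState":
        return SystemState(
            self.time,
            self.grid,
            {k: f.copy() for k, f in self.fields.items()},
            self.n_tracks_averaged,
        )

    @property
    def all_flattened(self) -> bool:
        return all(f.flattened for f in self.fields.values())

    @classmethod
    def zeros(cls, grid: RadialGrid, species_names, time: float = 0.0,
              n_tracks: int = 1) -> "SystemState":
        return cls(
            time,
            grid,
            {n: ConcentrationField(n, np.zeros(grid.n_bins)) for n in species_names},
            n_tracks,
        )


@dataclass(frozen=True)
class BeamSpec:
    """Beam quality: LET (keV/um), fluence (1/cm^2), dose (Gy), density (g/cm^3).

    Any subset may be given; when LET, fluence and dose are all set they must
    satisfy D = 1.6e-9 * LET * Phi / rho.
    """

    let: float
    fluence: float | None = None
    dose: float | None = None
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.let <= 0 or self.density <= 0:
            raise ValueError("LET and density must be positive")
        if self.fluence is not None and self.fluence <= 0:
            raise ValueError("fluence must be positive")
        if self.dose is not None and self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.fluence is not None and self.dose is not None:
            implied = DOSE_LET_PREFACTOR * self.let * self.fluence / self.density
            if not np.isclose(implied, self.dose, rtol=1e-6):
                raise ValueError(
                    f"inconsistent beam spec: dose {self.dose} Gy vs "
                    f"LET/fluence-implied {implied} Gy"
                )


@dataclass
class GValueRecord:
    """Per-species yields in molecules per 100 eV at one time point."""

    time: float  # ns
    values: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# binning and totals
# ---------------------------------------------------------------------------

def bin_positions(
    positions: pd.DataFrame,
    grid: RadialGrid,
    n_tracks: int = 1,
    species_names=None,
) -> tuple[SystemState, int]:
    """Convert discrete species coordinates into a binned ``SystemState``.

    ``positions`` has columns ``species, x_nm, y_nm, z_nm`` (pooled over all
    ``n_tracks`` tracks); the resulting concentrations are per-track averages:
    values[j] = count_j / (N_A V_j n_tracks).

    Positions with r >= r_max or z outside [0, h] are discarded; the discard
    count is returned alongside the state.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if species_names is None:
        species_names = sorted(positions["species"].unique()) if len(positions) else []
    state = SystemState.zeros(grid, species_names, n_tracks=n_tracks)
    if len(positions) == 0:
        return state, 0

    r = np.hypot(positions["x_nm"].to_numpy(float), positions["y_nm"].to_numpy(float))
    z = positions["z_nm"].to_numpy(float)
    inside = (r < grid.r_max) & (z >= 0.0) & (z <= grid.track_length)
    n_discarded = int((~inside).size - inside.sum())

    vol = grid.bin_volumes_l
    edges = grid.bin_edges
    species_col = positions["species"].to_numpy()
    for name in species_names:
        sel = inside & (species_col == name)
        counts, _ = np.histogram(r[sel], bins=edges)
        state.fields[name].values = counts / (AVOGADRO * vol * n_tracks)
    return state, n_discarded


def total_amount(fld: ConcentrationField, grid: RadialGrid) -> float:
    """Molecules per track represented by the field: sum_j c_j N_A V_j."""
    if fld.flattened:
        return fld.flat_value * AVOGADRO * grid.total_volume_l
    return float(np.dot(fld.values, grid.bin_volumes_l)) * AVOGADRO


def gvalues(state: SystemState, beam: BeamSpec) -> GValueRecord:
    """Per-species molecules per 100 eV of deposited energy.

    E_dep per track = LET[keV/um] * h[um] * 1000 eV.
    """
    h_um = state.grid.track_length * 1e-3
    e_dep = beam.let * h_um * KEV_TO_EV  # eV per track
    if e_dep <= 0:
        raise ValueError("deposited energy must be positive")
    rec = GValueRecord(time=state.time)
    for name, fld in state.fields.items():
        rec.values[name] = 100.0 * total_amount(fld, state.grid) / e_dep
    return rec


def category_sums(state: SystemState, categories: dict | None = None
                  ) -> dict[str, np.ndarray]:
    """Element-wise sums of member fields per category (i, ii, iii)."""
    cats = categories if categories is not None else CATEGORIES
    out = {}
    for cat, members in cats.items():
        total = np.zeros(state.grid.n_bins)
        for name in members:
            if name in state.fields:
                fld = state.fields[name]
                total += (np.full(state.grid.n_bins, fld.flat_value)
                          if fld.flattened else fld.values)
        out[cat] = total
    return out


def deviation(state_a: SystemState, state_b: SystemState
              ) -> tuple[dict[str, float], list[str]]:
    """Per-species relative difference of total amounts, (N_a - N_b) / N_b.

    Species with zero reference total are skipped and returned in the second
    element.
    """
    if set(state_a.fields) != set(state_b.fields):
        raise ValueError("states track different species sets")
    devs: dict[str, float] = {}
    skipped: list[str] = []
    for name in state_a.fields:
        nb = total_amount(state_b.fields[name], state_b.grid)
        na = total_amount(state_a.fields[name], state_a.grid)
        if nb <= 0.0:
            skipped.append(name)
        else:
            devs[name] = (na - nb) / nb
    return devs, skipped


# ---------------------------------------------------------------------------
# dose / fluence geometry
# ---------------------------------------------------------------------------

def dose_from_fluence(beam: BeamSpec) -> float:
    """D[Gy] = 1.6e-9 * LET[keV/um] * Phi[1/cm^2] / rho."""
    if beam.fluence is None or beam.fluence <= 0:
        raise ValueError("beam fluence must be set and positive")
    return DOSE_LET_PREFACTOR * beam.let * beam.fluence / beam.density


def surface_from_fluence(beam: BeamSpec) -> tuple[float, float]:
    """Average surface per track S = 1/Phi (cm^2) and equivalent radius (nm).

    If only dose is given, the fluence is recovered from the dose-LET
    relation first.
    """
    if beam.fluence is not None:
        phi = beam.fluence
    elif beam.dose is not None:
        phi = beam.dose * beam.density / (DOSE_LET_PREFACTOR * beam.let)
    else:
        raise ValueError("need fluence or dose to compute the track surface")
    if phi <= 0:
        raise ValueError("fluence must be positive")
    surface_cm2 = 1.0 / phi
    r_equiv_nm = np.sqrt(surface_cm2 / np.pi) * CM_TO_NM
    return surface_cm2, float(r_equiv_nm)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"


def read_positions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(POSITIONS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"positions CSV missing columns {sorted(missing)}")
    df = df[POSITIONS_COLUMNS].copy()
    for col in ("x_nm", "y_nm", "z_nm"):
        df[col] = df[col].astype(float)
    return df


def write_positions_csv(df: pd.DataFrame, path) -> None:
    df[POSITIONS_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_state_csv(state: SystemState, path) -> None:
    rows = []
    for name, fld in state.fields.items():
        vals = (np.full(state.grid.n_bins, fld.flat_value)
                if fld.flattened else fld.values)
        for j, c in enumerate(vals):
            rows.append((name, j, c))
    pd.DataFrame(rows, columns=STATE_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_state_csv(path, grid: RadialGrid, time: float = 0.0,
                   n_tracks: int = 1) -> SystemState:
    df = pd.read_csv(path)
    missing = set(STATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"state CSV missing columns {sorted(missing)}")
    names = sorted(df["species"].unique())
    state = SystemState.zeros(grid, names, time=time, n_tracks=n_tracks)
    for name, grp in df.groupby("species"):
        vals = np.zeros(grid.n_bins)
        idx = grp["bin_index"].to_numpy(int)
        if (idx < 0).any() or (idx >= grid.n_bins).any():
            raise ValueError("bin_index outside grid")
        vals[idx] = grp["concentration_M"].to_numpy(float)
        state.fields[name].values = vals
    return state


def write_gvalues_csv(records: list[GValueRecord], path) -> None:
    rows = [
        (rec.time, name, g)
        for rec in records
        for name, g in sorted(rec.values.items())
    ]
    pd.DataFrame(rows, columns=["time_ns", "species", "g_per_100eV"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_gvalues_csv(path) -> list[GValueRecord]:
    df = pd.read_csv(path)
    records = []
    for t, grp in df.groupby("time_ns", sort=True):
        records.append(
            GValueRecord(float(t), dict(zip(grp["species"], grp["g_per_100eV"])))
        )
    return records
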