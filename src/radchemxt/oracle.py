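"""Independent well-mixed kinetics engines.

Two reference implementations of the homogeneous limit of the reaction
network, deliberately sharing no numerics with the radial solver:

* :func:`ode_wellmixed` — deterministic mass-action rate equations
  integrated with SciPy's adaptive stiff solver (LSODA);
* :func:`ssa_wellmixed` — exact stochastic simulation (Gillespie direct
  method) on molecule counts in a fixed volume.

Both honour the same conventions as the chemistry module: continuum
solutes enter at fixed concentration, and same-species reactions consume
two molecules per event (deterministic rate -2 k [A]^2, propensity
k/(N_A V) n (n-1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .chemistry import ReactionNetwork
from .constants import AVOGADRO, CM3_TO_L, CM_TO_NM
from .radial_field import BeamSpec, surface_from_fluence

__all__ = [
    "WellMixedTrajectory",
    "ode_wellmixed",
    "ssa_wellmixed",
    "volume_from_fluence",
]


@dataclass
class WellMixedTrajectory:
    """Times (ns) and per-species values (molarity or counts)."""

    times: np.ndarray
    values: dict[str, np.ndarray]

    def at_end(self) -> dict[str, float]:
        return {name: float(v[-1]) for name, v in self.values.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, name, self.values[name][i])
            for i, t in enumerate(self.times)
            for name in sorted(self.values)
        ]
        return pd.DataFrame(rows, columns=["time_ns", "species", "value"])


def _stoichiometry(net: ReactionNetwork, names: list[str]
                   ) -> tuple[np.ndarray, list[tuple[np.ndarray, float]]]:
    """Net stoichiometric matrix and per-reaction (reactant idx, k_eff).

    Continuum reactants are folded into the effective rate constant; the
    returned index arrays refer only to evolving species.
    """
    index = {n: i for i, n in enumerate(names)}
    stoich = np.zeros((len(net.reactions), len(names)))
    terms = []
    for r_i, rx in enumerate(net.reactions):
        k_eff = rx.rate_constant
        idxs = []
        for name in rx.reactants:
            if net.is_continuum(name):
                k_eff *= net.continuum_concentrations[name]
            else:
                idxs.append(index[name])
        if rx.is_same_species:
            stoich[r_i, idxs[0]] -= 2.0
        else:
            for i in idxs:
                stoich[r_i, i] -= 1.0
        for name in rx.products:
            if not net.is_continuum(name):
                stoich[r_i, index[name]] += 1.0
        terms.append((np.array(idxs, dtype=int), k_eff))
    return stoich, terms


def ode_wellmixed(
    initial: dict[str, float],
    net: ReactionNetwork,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-15,
    t_eval: np.ndarray | None = None,
) -> WellMixedTrajectory:
    """Integrate the mass-action rate equations to ``t_end`` ns."""
    names = net.species_names
    y0 = np.array([initial.get(n, 0.0) for n in names])
    stoich, terms = _stoichiometry(net, names)

    def rhs(_t, y):
        rates = np.array([k * np.prod(y[idx]) for idx, k in terms])
        return rates @ stoich

    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA",
        rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"well-mixed ODE integration failed: {sol.message}")
    return WellMixedTrajectory(
        times=sol.t,
        values={n: sol.y[i] for i, n in enumerate(names)},
    )


def ssa_wellmixed(
    initial_counts: dict[str, int],
    volume_l: float,
    net: ReactionNetwork,
    t_end: float,
    seed: int | None = None,
    record_times: np.ndarray | None = None,
) -> WellMixedTrajectory:
    """Gillespie direct-method trajectory of molecule counts to ``t_end`` ns."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    rng = np.random.default_rng(seed)
    names = net.species_names
    index = {n: i for i, n in enumerate(names)}
    counts = np.array([int(initial_counts.get(n, 0)) for n in names], dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")

    nav = AVOGADRO * volume_l
    # per-reaction: evolving reactant indices, propensity prefactor, count changes
    prop_terms = []
    changes = []
    for rx in net.reactions:
        k_eff = rx.rate_constant
        idxs = []
        for name in rx.reactants:
            if net.is_continuum(name):
                k_eff *= net.continuum_concentrations[name]
            else:
                idxs.append(index[name])
        if len(idxs) == 2:
            k_eff /= nav
        elif len(idxs) == 0:
            continue  # nothing evolving to consume
        change = np.zeros(len(names), dtype=np.int64)
        if rx.is_same_species:
            change[idxs[0]] -= 2
        else:
            for i in idxs:
                change[i] -= 1
        for name in rx.products:
            if not net.is_continuum(name):
                change[index[name]] += 1
        prop_terms.append((tuple(idxs), k_eff, rx.is_same_species))
        changes.append(change)

    if record_times is None:
        record_times = np.array([0.0, t_end])
    record_times = np.asarray(record_times, dtype=float)
    recorded = np.zeros((len(record_times), len(names)), dtype=np.int64)
    rec_i = 0

    t = 0.0
    while rec_i < len(record_times) and record_times[rec_i] <= t:
        recorded[rec_i] = counts
        rec_i += 1
    while rec_i < len(record_times):
        props = np.empty(len(prop_terms))
        for j, (idxs, k_eff, same) in enumerate(prop_terms):
            if same:
                n = counts[idxs[0]]
                props[j] = k_eff * n * (n - 1)
            elif len(idxs) == 2:
                props[j] = k_eff * counts[idxs[0]] * counts[idxs[1]]
            else:
                props[j] = k_eff * counts[idxs[0]]
        total = props.sum()
        if total <= 0.0:
            t_next = np.inf  # no further events
        else:
            t_next = t + rng.exponential(1.0 / total)
        # flush record points passed before the next event fires
        while rec_i < len(record_times) and record_times[rec_i] < t_next:
            recorded[rec_i] = counts
            rec_i += 1
        if rec_i >= len(record_times) or not np.isfinite(t_next):
            break
        t = t_next
        j = rng.choice(len(prop_terms), p=props / total)
        counts = counts + changes[j]

    return WellMixedTrajectory(
        times=record_times,
        values={n: recorded[:, index[n]] for n in names},
    )


def volume_from_fluence(beam: BeamSpec, track_length_nm: float) -> float:
    """Per-track well-mixed volume V = S * h = h / Phi, in litres."""
    surface_cm2, _ = surface_from_fluence(beam)
    h_cm = track_length_nm / CM_TO_NM
    return surface_cm2 * h_cm * CM3_TO_L
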