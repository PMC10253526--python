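"""Operator-split numerical core.

Each time step is a Lie split: one Crank-Nicolson cylindrical diffusion
half (per species, across bins) followed by one explicit forward-Euler
reaction half (per bin, across species).  Once a field's relative standard
deviation over bins drops below the flatten threshold it is collapsed to a
single mass-conserving value; when every field is flat the diffusion half
is skipped entirely and the integration degenerates to homogeneous
kinetics.

The CN operator uses the stencil

    L a_j = (a_{j+1} - 2 a_j + a_{j-1}) / bw^2
          + (a_{j+1} - a_{j-1}) / (2 bw r_j)

on bin centers, with virtual points eliminated by mirror conditions
a_{-1} = a_0 (smoothness at the axis) and a_J = a_{J-1} (zero flux at
r_max, standing in for the balance with neighbouring tracks).  The linear
systems are tridiagonal and solved with the Thomas algorithm.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .chemistry import ReactionNetwork
from .constants import AVOGADRO
from .radial_field import (
    BeamSpec,
    GValueRecord,
    RadialGrid,
    SystemState,
    gvalues,
)

__all__ = [
    "TimeStepSchedule",
    "SolverConfig",
    "Tridiagonal",
    "Diagnostics",
    "SimulationResult",
    "assemble_cn_matrices",
    "tridiagonal_solve",
    "cn_propagator",
    "diffusion_step",
    "reaction_increments",
    "reaction_step",
    "advance",
    "check_and_flatten",
    "run_simulation",
]

#: (t_start offset, t_end, dt) table defining the default step schedule, ns.
#: The first interval starts at t_in; times are absolute otherwise.
DEFAULT_SCHEDULE_TABLE = (
    (None, 1.0e3, 0.5),   # t_in - 1 us
    (1.0e3, 1.0e4, 1.0),  # 1 us - 10 us
    (1.0e4, 1.0e5, 2.5),  # 10 us - 100 us
    (1.0e5, 1.0e6, 5.0),  # 100 us - 1 ms
    (1.0e6, None, 10.0),  # >= 1 ms
)


class ScheduleError(ValueError):
    """Raised for gaps/overlaps or non-covering step schedules."""


@dataclass(frozen=True)
class TimeStepSchedule:
    """Contiguous (t_start, t_end, dt) intervals in ns."""

    intervals: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ScheduleError("empty schedule")
        prev_end = None
        for t0, t1, dt in self.intervals:
            if dt <= 0:
                raise ScheduleError(f"non-positive dt in interval ({t0}, {t1})")
            if t1 <= t0:
                raise ScheduleError(f"empty/reversed interval ({t0}, {t1})")
            if prev_end is not None and not np.isclose(t0, prev_end, rtol=0, atol=1e-9):
                raise ScheduleError(f"schedule gap/overlap at t = {t0} ns")
            prev_end = t1

    @classmethod
    def default(cls, t_in: float, t_end: float) -> "TimeStepSchedule":
        """The bundled interval->dt table, clipped to [t_in, t_end]."""
        intervals = []
        for t0, t1, dt in DEFAULT_SCHEDULE_TABLE:
            lo = t_in if t0 is None else max(t0, t_in)
            hi = t_end if t1 is None else min(t1, t_end)
            if hi > lo:
                intervals.append((lo, hi, dt))
        if not intervals:
            raise ScheduleError(f"default schedule cannot cover [{t_in}, {t_end}]")
        return cls(tuple(intervals))

    @property
    def t_start(self) -> float:
        return self.intervals[0][0]

    @property
    def t_end(self) -> float:
        return self.intervals[-1][1]

    def dt_at(self, t: float) -> float:
        return self.interval_at(t)[2]

    def interval_at(self, t: float) -> tuple[float, float, float]:
        for t0, t1, dt in self.intervals:
            if t0 - 1e-9 <= t < t1 - 1e-9:
                return t0, t1, dt
        raise ScheduleError(f"t = {t} ns outside schedule")

    def covers(self, t_in: float, t_end: float) -> bool:
        return self.t_start <= t_in + 1e-9 and self.t_end >= t_end - 1e-9


@dataclass
class SolverConfig:
    """Integration settings for :func:`run_simulation`."""

    t_in: float = 500.0  # ns; hand-over time from the track snapshot
    t_end: float = 1.0e6  # ns
    schedule: TimeStepSchedule | None = None
    flatten_threshold: float = 0.05
    record_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.t_in >= self.t_end:
            raise ValueError("t_in must precede t_end")
        if not 0.0 < self.flatten_threshold < 1.0:
            raise ValueError("flatten_threshold must be in (0, 1)")
        if self.schedule is None:
            self.schedule = TimeStepSchedule.default(self.t_in, self.t_end)
        elif not self.schedule.covers(self.t_in, self.t_end):
            raise ScheduleError("schedule does not cover [t_in, t_end]")


@dataclass
class Diagnostics:
    """Counters and bookkeeping accumulated during a run."""

    reaction_clamps: int = 0
    diffusion_clamps: int = 0
    flatten_times: dict[str, float] = dataclass_field(default_factory=dict)
    n_steps: int = 0
    wall_seconds: float = 0.0


@dataclass
class SimulationResult:
    snapshots: list[SystemState]
    gvalue_records: list[GValueRecord]
    diagnostics: Diagnostics
    final_state: SystemState


# ---------------------------------------------------------------------------
# Crank-Nicolson diffusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tridiagonal:
    """Tridiagonal matrix as (lower, diag, upper) bands."""

    lower: np.ndarray  # length n-1
    diag: np.ndarray   # length n
    upper: np.ndarray  # length n-1

    def to_dense(self) -> np.ndarray:
        return (np.diag(self.diag) + np.diag(self.lower, -1)
                + np.diag(self.upper, 1))

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.diag * x
        y[:-1] += self.upper * x[1:]
        y[1:] += self.lower * x[:-1]
        return y


def _cn_operator_bands(grid: RadialGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bands of the discrete cylindrical Laplacian L with mirror BCs."""
    bw = grid.bin_width
    r = grid.bin_centers
    n = grid.n_bins
    inv_bw2 = 1.0 / bw**2
    adv = 1.0 / (2.0 * bw * r)  # advection-like 1/r term

    lower = inv_bw2 - adv[1:]
    diag = np.full(n, -2.0 * inv_bw2)
    upper = inv_bw2 + adv[:-1]

    # mirror at the axis: a_{-1} = a_0 folds into the diagonal
    diag[0] = -(inv_bw2 + adv[0])
    # zero flux at r_max: a_J = a_{J-1}
    diag[-1] = -(inv_bw2 - adv[-1])
    return lower, diag, upper


def assemble_cn_matrices(D: float, dt: float, grid: RadialGrid
                         ) -> tuple[Tridiagonal, Tridiagonal]:
    """Build (M, N) with M a^{n+1} = N a^n for one CN diffusion step."""
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    lower, diag, upper = _cn_operator_bands(grid)
    alpha = 0.5 * D * dt
    n = grid.n_bins
    eye = np.ones(n)
    M = Tridiagonal(-alpha * lower, eye - alpha * diag, -alpha * upper)
    N = Tridiagonal(alpha * lower, eye + alpha * diag, alpha * upper)
    return M, N


class NumericalError(ArithmeticError):
    pass


def tridiagonal_solve(M: Tridiagonal, rhs: np.ndarray) -> np.ndarray:
    """Solve M x = rhs with the Thomas algorithm.

    ``rhs`` may be a vector (n,) or a matrix (n, k); columns are solved
    simultaneously.  Raises :class:`NumericalError` on a zero pivot.
    """
    n = M.diag.size
    b = np.array(rhs, dtype=float, copy=True)
    if b.shape[0] != n:
        raise ValueError("rhs size mismatch")
    cp = np.empty(n - 1)
    pivot = M.diag[0]
    if pivot == 0.0:
        raise NumericalError("zero pivot in Thomas elimination (row 0)")
    if n > 1:
        cp[0] = M.upper[0] / pivot
    b[0] = b[0] / pivot
    for i in range(1, n):
        denom = M.diag[i] - M.lower[i - 1] * cp[i - 1]
        if denom == 0.0:
            raise NumericalError(f"zero pivot in Thomas elimination (row {i})")
        if i < n - 1:
            cp[i] = M.upper[i] / denom
        b[i] = (b[i] - M.lower[i - 1] * b[i - 1]) / denom
    for i in range(n - 2, -1, -1):
        b[i] = b[i] - cp[i] * b[i + 1]
    return b


def cn_propagator(D: float, dt: float, grid: RadialGrid) -> np.ndarray:
    """Dense one-step propagator P = M^{-1} N (cached by callers)."""
    M, N = assemble_cn_matrices(D, dt, grid)
    return tridiagonal_solve(M, N.to_dense())


class _PropagatorCache(dict):
    """(D, dt) -> dense propagator, built lazily for the run's grid."""

    def __init__(self, grid: RadialGrid):
        super().__init__()
        self.grid = grid

    def get_propagator(self, D: float, dt: float) -> np.ndarray:
        key = (D, dt)
        if key not in self:
            self[key] = cn_propagator(D, dt, self.grid)
        return self[key]


def diffusion_step(
    state: SystemState,
    net: ReactionNetwork,
    dt: float,
    cache: _PropagatorCache | None = None,
    diagnostics: Diagnostics | None = None,
) -> SystemState:
    """Advance every non-flattened field by one CN diffusion step (in place).

    Tiny negative values produced by the finite-difference update are
    clamped to zero and counted.
    """
    if cache is None or cache.grid != state.grid:
        cache = _PropagatorCache(state.grid)
    for name, fld in state.fields.items():
        if fld.flattened:
            continue
        D = net.get_species(name).diffusion_coefficient
        if D == 0.0:
            continue
        P = cache.get_propagator(D, dt)
        v = P @ fld.values
        neg = v < 0.0
        if neg.any():
            if diagnostics is not None:
                diagnostics.diffusion_clamps += int(neg.sum())
            v[neg] = 0.0
        fld.values = v
    return state


# ---------------------------------------------------------------------------
# explicit reactions
# ---------------------------------------------------------------------------

def reaction_increments(
    state: SystemState, net: ReactionNetwork, dt: float
) -> dict[str, np.ndarray]:
    """Per-species, per-bin forward-Euler increments over dt.

    Reactions happen bin-by-bin: each bin is an independent, locally
    homogeneous reactor.  Continuum solutes enter as their fixed molarity
    and never receive increments.  Same-species reactions consume two
    molecules per event (d[A]/dt = -2 k [A]^2).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = state.grid.n_bins

    def conc(name: str) -> np.ndarray | float:
        if net.is_continuum(name):
            return net.continuum_concentrations[name]
        fld = state.fields[name]
        return fld.flat_value if fld.flattened else fld.values

    increments = {name: np.zeros(n) for name in state.fields}
    for rx in net.reactions:
        if rx.rate_constant == 0.0:
            continue
        rate = rx.rate_constant
        for name in rx.reactants:
            rate = rate * conc(name)
        if np.isscalar(rate):
            rate = np.full(n, rate)
        events = rate * dt  # molarity converted per bin over dt
        if rx.is_same_species:
            increments[rx.reactants[0]] -= 2.0 * events
        else:
            for name in rx.reactants:
                if not net.is_continuum(name):
                    increments[name] -= events
        for name in rx.products:
            if not net.is_continuum(name):
                increments[name] += events
    return increments


def reaction_step(
    state: SystemState,
    net: ReactionNetwork,
    dt: float,
    diagnostics: Diagnostics | None = None,
) -> SystemState:
    """Apply one simultaneous forward-Euler reaction update (in place).

    All increments are computed from the pre-step state, then applied.
    Negative results (over-depletion within one step) are clamped to zero
    and counted; the step schedule is expected to keep this counter at 0.
    """
    increments = reaction_increments(state, net, dt)
    for name, fld in state.fields.items():
        delta = increments[name]
        if fld.flattened and delta.min() == delta.max():
            # spatially uniform production/consumption keeps the field flat
            new = fld.flat_value + delta[0]
            if new < 0.0:
                if diagnostics is not None:
                    diagnostics.reaction_clamps += 1
                new = 0.0
            fld.flat_value = new
            fld.values.fill(new)
        else:
            if fld.flattened:
                # non-uniform increments re-introduce radial structure
                fld.values = np.full(state.grid.n_bins, fld.flat_value)
                fld.flattened = False
            v = fld.values + delta
            neg = v < 0.0
            if neg.any():
                if diagnostics is not None:
                    diagnostics.reaction_clamps += int(neg.sum())
                v[neg] = 0.0
            fld.values = v
    return state


def advance(
    state: SystemState,
    net: ReactionNetwork,
    dt: float,
    cache: _PropagatorCache | None = None,
    diagnostics: Diagnostics | None = None,
) -> SystemState:
    """One Lie-split step: diffusion first, then reactions, same dt."""
    if not state.all_flattened:
        diffusion_step(state, net, dt, cache, diagnostics)
    reaction_step(state, net, dt, diagnostics)
    state.time += dt
    if diagnostics is not None:
        diagnostics.n_steps += 1
    return state


# ---------------------------------------------------------------------------
# flattening and the driver
# ---------------------------------------------------------------------------

def check_and_flatten(
    state: SystemState,
    threshold: float = 0.05,
    diagnostics: Diagnostics | None = None,
) -> SystemState:
    """Collapse near-uniform fields to single flat values (in place).

    The trigger is the unweighted relative standard deviation over bin
    values; the collapse value is the volume-weighted mean, so the total
    amount is conserved exactly.  An all-zero field counts as flat at 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    vol = state.grid.bin_volumes_l
    total_vol = state.grid.total_volume_l
    for name, fld in state.fields.items():
        if fld.flattened:
            continue
        mean = fld.values.mean()
        if mean == 0.0:
            rel_std = 0.0
        else:
            rel_std = fld.values.std() / mean
        if rel_std < threshold:
            fld.flat_value = float(np.dot(fld.values, vol) / total_vol)
            fld.flattened = True
            fld.values = np.full(state.grid.n_bins, fld.flat_value)
            if diagnostics is not None:
                diagnostics.flatten_times.setdefault(name, state.time)
    return state


def run_simulation(
    initial: SystemState,
    net: ReactionNetwork,
    config: SolverConfig,
    beam: BeamSpec | None = None,
) -> SimulationResult:
    """Advance ``initial`` from t_in to t_end under the step schedule.

    Snapshots (and G-values when ``beam`` is given) are taken at
    ``config.record_times``; each recording time also triggers a flatten
    check.  Recording times are snapped to the first step boundary at or
    beyond the requested time.  The run is deterministic given its inputs.
    """
    schedule = config.schedule
    if not schedule.covers(config.t_in, config.t_end):
        raise ScheduleError("schedule does not cover [t_in, t_end]")

    state = initial.copy()
    state.time = config.t_in
    diag = Diagnostics()
    cache = _PropagatorCache(state.grid)
    t_wall = _time.perf_counter()

    record_times = sorted(t for t in config.record_times
                          if config.t_in <= t <= config.t_end)
    snapshots: list[SystemState] = []
    gvalue_records: list[GValueRecord] = []

    def record(t_requested: float) -> None:
        check_and_flatten(state, config.flatten_threshold, diag)
        snapshots.append(state.copy())
        if beam is not None:
            gvalue_records.append(gvalues(state, beam))

    next_rec = 0
    while next_rec < len(record_times) and record_times[next_rec] <= config.t_in:
        record(record_times[next_rec])
        next_rec += 1

    t = config.t_in
    while t < config.t_end - 1e-9:
        _, t1, dt = schedule.interval_at(t)
        # never step past an interval boundary or the end of the run
        dt = min(dt, t1 - t, config.t_end - t)
        advance(state, net, dt, cache, diag)
        t = state.time
        while next_rec < len(record_times) and t >= record_times[next_rec] - 1e-9:
            record(record_times[next_rec])
            next_rec += 1

    check_and_flatten(state, config.flatten_threshold, diag)
    diag.wall_seconds = _time.perf_counter() - t_wall
    return SimulationResult(snapshots, gvalue_records, diag, state)


def flat_total_from_amount(amount: float, grid: RadialGrid) -> float:
    """Molarity of ``amount`` molecules spread uniformly over the cylinder."""
    return amount / (AVOGADRO * grid.total_volume_l)
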