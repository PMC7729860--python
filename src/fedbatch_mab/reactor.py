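"""Fed-batch bioreactor model: feed policies, mass balances and simulation.

The reactor is a perfectly mixed, isothermal vessel with no outflow.  A feed
policy divides the batch time ``t_f`` into ``N_div`` time-arcs on which all
four control variables — liquid feed rate F_L, inlet glucose, inlet
glutamine and inlet viable-cell density — are held constant.  Each species
balance is

    dC_i/dt = (F_L / V_L) * (C_inlet_i - C_i) + r_i,     dV_L/dt = F_L,

with the reaction terms r_i supplied by :mod:`fedbatch_mab.kinetics`.  Batch
operation is the F_L = 0 special case.

The culture state spans ~10 orders of magnitude (cells/L vs mM), so the
integrator works on biomass scaled to 1e9 cells/L; user-facing units are
always cells/L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (CultureState, KineticParameters, SPECIES,
                       reaction_terms)

__all__ = [
    "FeedArc",
    "FeedPolicy",
    "ReactorState",
    "Trajectory",
    "ScenarioDefinition",
    "SolverOptions",
    "controls_at",
    "build_initial_state",
    "ode_rhs",
    "simulate",
    "IntegrationError",
    "TRAJECTORY_COLUMNS",
]

logger = logging.getLogger(__name__)

_XV_SCALE = 1e9  # biomass integrated in units of 1e9 cells/L

TRAJECTORY_COLUMNS = ("time_h", "Xv_cells_per_L", "Xt_cells_per_L", "GLC_mM",
                      "GLN_mM", "LAC_mM", "AMM_mM", "mAb_mg_per_L", "V_L")


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails; carries the last good state."""

    def __init__(self, message: str, t_last: float, state_last) -> None:
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


@dataclass(frozen=True)
class FeedArc:
    """Constant control values on one time-arc."""

    F_L: float        # L/h
    GLC_in: float     # mM
    GLN_in: float     # mM
    Xv_in: float      # cells/L

    def __post_init__(self) -> None:
        if self.F_L < 0:
            raise ValueError("feed rate F_L must be >= 0")
        for name in ("GLC_in", "GLN_in", "Xv_in"):
            if getattr(self, name) < 0:
                raise ValueError(f"inlet concentration {name} must be >= 0")


@dataclass(frozen=True)
class FeedPolicy:
    """Piecewise-constant feed schedule over ``N_div`` time-arcs.

    ``switch_times`` are the interior arc boundaries T_1 < ... < T_{N-1};
    arc j is active on [T_{j-1}, T_j) and the last arc is closed at ``t_f``.
    Inlet total cells, lactate, ammonia and mAb are fixed at zero.
    """

    t_f: float
    arcs: tuple
    switch_times: tuple
    Xt_in: float = 0.0

    def __post_init__(self) -> None:
        if self.t_f <= 0:
            raise ValueError("batch time t_f must be positive")
        if len(self.arcs) < 1:
            raise ValueError("a policy needs at least one arc")
        if len(self.switch_times) != len(self.arcs) - 1:
            raise ValueError("need exactly N_div - 1 switch times")
        ts = (0.0, *self.switch_times, self.t_f)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("switch times must be strictly increasing "
                             "inside (0, t_f)")
        object.__setattr__(self, "arcs", tuple(self.arcs))
        object.__setattr__(self, "switch_times",
                           tuple(float(t) for t in self.switch_times))

    @classmethod
    def equal_arcs(cls, t_f: float, arcs: Sequence[FeedArc]) -> "FeedPolicy":
        """Build a policy with N_div equal arcs of length t_f/N_div."""
        n = len(arcs)
        switches = tuple(j * t_f / n for j in range(1, n))
        return cls(t_f=t_f, arcs=tuple(arcs), switch_times=switches)

    @property
    def n_div(self) -> int:
        return len(self.arcs)

    @property
    def arc_bounds(self) -> tuple:
        """(start, end) of every arc, covering [0, t_f]."""
        ts = (0.0, *self.switch_times, self.t_f)
        return tuple(zip(ts, ts[1:]))

    @property
    def arc_durations(self) -> tuple:
        return tuple(b - a for a, b in self.arc_bounds)


def controls_at(policy: FeedPolicy, t: float) -> FeedArc:
    """Control values at time ``t``; arcs are left-closed/right-open and
    ``t = t_f`` maps to the last arc."""
    if not 0.0 <= t <= policy.t_f:
        raise ValueError(f"t = {t} outside the batch window [0, {policy.t_f}]")
    for (a, b), arc in zip(policy.arc_bounds, policy.arcs):
        if a <= t < b:
            return arc
    return policy.arcs[-1]


@dataclass(frozen=True)
class ReactorState:
    """Culture composition plus liquid volume."""

    culture: CultureState
    V_L: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.V_L) and self.V_L > 0):
            raise ValueError(f"liquid volume must be positive, got {self.V_L}")

    def as_array(self) -> np.ndarray:
        return np.append(self.culture.as_array(), self.V_L)

    @classmethod
    def from_array(cls, y) -> "ReactorState":
        return cls(culture=CultureState.from_array(y[:7]), V_L=float(y[7]))


@dataclass(frozen=True)
class ScenarioDefinition:
    """A named reactor run: parameters, feed policy and initial overrides.

    The initial substrate and viable-cell concentrations are coupled to the
    first arc's inlet values; mAb, ammonia, lactate and volume start from the
    overrides below, and the total-cell density starts equal to the viable one.
    """

    name: str
    params: KineticParameters
    policy: FeedPolicy
    mAb_0: float = 80.6     # mg/L
    AMM_0: float = 0.31     # mM
    LAC_0: float = 0.0      # mM
    V_L0: float = 1.0       # L

    def with_policy(self, policy: FeedPolicy) -> "ScenarioDefinition":
        return replace(self, policy=policy)


def build_initial_state(scenario: ScenarioDefinition) -> ReactorState:
    """Initial reactor state with first-arc inlet coupling.

    GLC_0, GLN_0 and Xv_0 equal the first arc's inlet values; Xt_0 = Xv_0.
    """
    if not scenario.policy.arcs:
        raise ValueError("scenario policy has no arcs")
    first = scenario.policy.arcs[0]
    culture = CultureState(Xv=first.Xv_in, Xt=first.Xv_in, GLC=first.GLC_in,
                           GLN=first.GLN_in, LAC=scenario.LAC_0,
                           AMM=scenario.AMM_0, mAb=scenario.mAb_0)
    return ReactorState(culture=culture, V_L=scenario.V_L0)


def ode_rhs(t: float, state: ReactorState, policy: FeedPolicy,
            params: KineticParameters,
            strict_printed_xt: bool = False) -> np.ndarray:
    """Time derivative of (Xv, Xt, GLC, GLN, LAC, AMM, mAb, V_L) in user units.

    ``strict_printed_xt`` switches the total-cell dilution term from the
    standard ``-Xt`` form to the ``-Xv`` form; the total-cell density feeds
    back into nothing, so the choice only affects Xt itself.
    """
    arc = controls_at(policy, t)
    y = state.as_array()
    return _rhs(t, y, arc, params, policy.Xt_in, strict_printed_xt, scale=1.0)


def _rhs(t, y, arc: FeedArc, p: KineticParameters, xt_in: float,
         strict_printed_xt: bool, scale: float) -> np.ndarray:
    """Shared RHS; ``scale`` converts stored biomass to cells/L (1 for user
    units, _XV_SCALE inside the integrator)."""
    xv = y[0] * scale
    xt = y[1] * scale
    state = CultureState(Xv=xv, Xt=xt, GLC=y[2], GLN=y[3], LAC=y[4],
                         AMM=y[5], mAb=y[6])
    v_l = y[7]
    r = reaction_terms(state, p)
    d = arc.F_L / v_l
    xt_dil = xv if strict_printed_xt else xt
    dilution = np.array([
        d * (arc.Xv_in - xv),
        d * (xt_in - xt_dil),
        d * (arc.GLC_in - y[2]),
        d * (arc.GLN_in - y[3]),
        d * (0.0 - y[4]),
        d * (0.0 - y[5]),
        d * (0.0 - y[6]),
    ])
    dy = dilution + r
    dy[0] /= scale
    dy[1] /= scale
    return np.append(dy, arc.F_L)


@dataclass(frozen=True)
class SolverOptions:
    """Stiff-integrator settings.

    ``rtol``/``atol`` apply to the scaled state (biomass in 1e9 cells/L);
    ``samples_per_arc`` sets the dense-output resolution used for maxima,
    quadrature and CSV export.
    """

    rtol: float = 1e-7
    atol: float = 1e-9
    method: str = "LSODA"
    samples_per_arc: int = 400
    strict_printed_xt: bool = False

    def __post_init__(self) -> None:
        if self.samples_per_arc < 2:
            raise ValueError("samples_per_arc must be >= 2")


@dataclass
class Trajectory:
    """Dense simulation output: time grid plus full reactor state per point."""

    times: np.ndarray            # h, strictly increasing, [0, t_f]
    states: np.ndarray           # shape (n, 8), user units, SPECIES + V_L
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 8):
            raise ValueError("states must have shape (len(times), 8)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def species(self, name: str) -> np.ndarray:
        if name == "V_L":
            return self.states[:, 7]
        return self.states[:, SPECIES.index(name)]

    @property
    def mab(self) -> np.ndarray:
        return self.states[:, 6]

    @property
    def volume(self) -> np.ndarray:
        return self.states[:, 7]

    def state_at_end(self) -> ReactorState:
        return ReactorState.from_array(self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time_h": self.times}
        for col, j in zip(TRAJECTORY_COLUMNS[1:], range(8)):
            data[col] = self.states[:, j]
        return pd.DataFrame(data, columns=list(TRAJECTORY_COLUMNS))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate(scenario: ScenarioDefinition,
             options: SolverOptions | None = None) -> Trajectory:
    """Integrate the reactor over [0, t_f], restarting at every arc switch.

    Controls are discontinuous at switch times, so each arc is integrated
    separately with dense output; the returned grid contains every switch
    time and ``samples_per_arc`` points per arc.
    """
    opts = options or SolverOptions()
    policy = scenario.policy
    p = scenario.params
    y = build_initial_state(scenario).as_array()
    y[0] /= _XV_SCALE
    y[1] /= _XV_SCALE

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    nfev = 0
    for k, ((t0, t1), arc) in enumerate(zip(policy.arc_bounds, policy.arcs)):
        sol = solve_ivp(
            _rhs, (t0, t1), y,
            args=(arc, p, policy.Xt_in, opts.strict_printed_xt, _XV_SCALE),
            method=opts.method, rtol=opts.rtol, atol=opts.atol,
            dense_output=True)
        nfev += sol.nfev
        if not sol.success:
            last = sol.y[:, -1].copy()
            last[0] *= _XV_SCALE
            last[1] *= _XV_SCALE
            raise IntegrationError(
                f"integrator failed on arc {k + 1} "
                f"[{t0:g}, {t1:g}] h: {sol.message}",
                t_last=float(sol.t[-1]), state_last=last)
        grid = np.linspace(t0, t1, opts.samples_per_arc)
        block = sol.sol(grid).T.copy()
        if k > 0:
            grid, block = grid[1:], block[1:]
        times.append(grid)
        states.append(block)
        y = sol.y[:, -1]
        logger.info("arc %d/%d done at t = %g h (F_L = %g L/h, nfev = %d)",
                    k + 1, policy.n_div, t1, arc.F_L, sol.nfev)

    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    y_all[:, 0] *= _XV_SCALE
    y_all[:, 1] *= _XV_SCALE
    meta = {"scenario": scenario.name, "method": opts.method,
            "rtol": opts.rtol, "atol": opts.atol, "nfev": nfev,
            "samples_per_arc": opts.samples_per_arc,
            "strict_printed_xt": opts.strict_printed_xt}
    return Trajectory(times=t_all, states=y_all, metadata=meta)
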