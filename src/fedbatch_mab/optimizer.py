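"""Feed-policy optimization: maximize the batch-wide mAb titer.

The decision vector stacks the four control variables over the ``N_div``
equal time-arcs, ``[F_L,1..N, GLC_in,1..N, GLN_in,1..N, Xv_in,1..N]`` —
4 x N_div box-constrained reals.  The objective Omega is the maximum mAb
titer over the simulated batch; candidates whose cumulative feed would
dilute the vessel beyond the allowed fraction of the initial volume, or
whose simulation fails, receive a large penalty instead of raising.

The search is an elitist differential-evolution population loop (rand/1/bin)
followed by a bounded derivative-free polish of the incumbent.  A single
integer seed drives every random draw, so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .kinetics import KineticParameters
from .metrics import max_mab, substrate_consumption
from .reactor import (FeedArc, FeedPolicy, IntegrationError,
                      ScenarioDefinition, SolverOptions, simulate)

__all__ = [
    "SearchSpace",
    "FeasibilityFlags",
    "OptimizationResult",
    "encode",
    "decode",
    "objective",
    "feasibility_check",
    "optimize_policy",
]

logger = logging.getLogger(__name__)

#: Penalty floor for infeasible candidates (Omega is O(1e3) mg/L).
_PENALTY = -1.0e6
#: DE hyper-parameters.
_DE_F = 0.7
_DE_CR = 0.9
#: Relative tolerance for the equal-Omega tie-break.
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds of the 4 x N_div decision vector plus run constants.

    ``max_dilution_fraction`` caps the cumulative feed volume relative to
    the initial liquid volume (a hard feasibility constraint coupling all
    F_L arcs).
    """

    n_div: int
    t_f: float
    F_L: tuple          # (min, max), L/h
    GLC_in: tuple       # (min, max), mM
    GLN_in: tuple       # (min, max), mM
    Xv_in: tuple        # (min, max), cells/L
    V_L0: float = 1.0
    max_dilution_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_div < 1:
            raise ValueError("n_div must be >= 1")
        if self.t_f <= 0:
            raise ValueError("t_f must be positive")
        for name in ("F_L", "GLC_in", "GLN_in", "Xv_in"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds inverted: {lo} > {hi}")
            if name != "F_L" and lo <= 0:
                raise ValueError(f"{name} lower bound must be positive")
            if name == "F_L" and lo < 0:
                raise ValueError("F_L lower bound must be >= 0")

    @property
    def dimension(self) -> int:
        return 4 * self.n_div

    def bounds_array(self) -> np.ndarray:
        """(dimension, 2) array of [lower, upper] per decision variable."""
        n = self.n_div
        out = np.empty((4 * n, 2))
        for k, name in enumerate(("F_L", "GLC_in", "GLN_in", "Xv_in")):
            lo, hi = getattr(self, name)
            out[k * n:(k + 1) * n, 0] = lo
            out[k * n:(k + 1) * n, 1] = hi
        return out

    def clip(self, vector: np.ndarray) -> np.ndarray:
        b = self.bounds_array()
        return np.clip(vector, b[:, 0], b[:, 1])


def encode(policy: FeedPolicy) -> np.ndarray:
    """Flatten a policy into the [F_L | GLC_in | GLN_in | Xv_in] layout."""
    return np.concatenate([
        [a.F_L for a in policy.arcs],
        [a.GLC_in for a in policy.arcs],
        [a.GLN_in for a in policy.arcs],
        [a.Xv_in for a in policy.arcs],
    ]).astype(float)


def decode(space: SearchSpace, vector: np.ndarray) -> FeedPolicy:
    """Build an equal-arc policy from a decision vector."""
    v = np.asarray(vector, dtype=float)
    if v.shape != (space.dimension,):
        raise ValueError(f"decision vector must have length "
                         f"{space.dimension}, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("decision vector must be finite")
    n = space.n_div
    arcs = [FeedArc(F_L=v[j], GLC_in=v[n + j], GLN_in=v[2 * n + j],
                    Xv_in=v[3 * n + j]) for j in range(n)]
    return FeedPolicy.equal_arcs(space.t_f, arcs)


@dataclass(frozen=True)
class FeasibilityFlags:
    dilution_ok: bool
    within_bounds: bool
    dilution_fraction: float

    def __bool__(self) -> bool:
        return self.dilution_ok and self.within_bounds


def feasibility_check(space: SearchSpace,
                      policy: FeedPolicy) -> FeasibilityFlags:
    """Check the dilution cap and the per-control boxes for a policy."""
    fed_volume = sum(a.F_L * dt
                     for a, dt in zip(policy.arcs, policy.arc_durations))
    frac = fed_volume / space.V_L0
    b = space.bounds_array()
    v = encode(policy)
    ok_bounds = bool(np.all(v >= b[:, 0] - 1e-12 * np.abs(b[:, 0]))
                     and np.all(v <= b[:, 1] + 1e-12 * np.abs(b[:, 1])))
    return FeasibilityFlags(
        dilution_ok=frac <= space.max_dilution_fraction + 1e-12,
        within_bounds=ok_bounds,
        dilution_fraction=frac)


def _scenario_for(space: SearchSpace, policy: FeedPolicy,
                  template: ScenarioDefinition | None,
                  params: KineticParameters) -> ScenarioDefinition:
    if template is not None:
        return template.with_policy(policy)
    return ScenarioDefinition(name="candidate", params=params, policy=policy,
                              V_L0=space.V_L0)


def objective(space: SearchSpace, vector: np.ndarray,
              params: KineticParameters,
              options: SolverOptions | None = None,
              template: ScenarioDefinition | None = None) -> float:
    """Omega = max mAb titer of the decoded policy, mg/L.

    Dilution-cap violations return ``_PENALTY`` minus the violation (a
    feasible-region indicator the search can descend), and integrator
    failures return a still lower penalty; neither raises.
    """
    policy = decode(space, vector)
    flags = feasibility_check(space, policy)
    if not flags.dilution_ok:
        excess = flags.dilution_fraction - space.max_dilution_fraction
        return _PENALTY * (1.0 + excess)
    scenario = _scenario_for(space, policy, template, params)
    try:
        traj = simulate(scenario, options)
    except (IntegrationError, ValueError):
        return 10.0 * _PENALTY
    return max_mab(traj)[0]


@dataclass
class OptimizationResult:
    """Outcome of a seeded policy search."""

    policy: FeedPolicy
    omega: float                    # mg/L
    n_evaluations: int
    seed: int
    trace: list = field(default_factory=list)   # best Omega per generation
    feasibility: FeasibilityFlags | None = None
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "omega_mg_per_L": self.omega,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "t_f_h": self.policy.t_f,
            "n_div": self.policy.n_div,
            "arcs": [{"F_L_L_per_h": a.F_L, "GLC_in_mM": a.GLC_in,
                      "GLN_in_mM": a.GLN_in, "Xv_in_cells_per_L": a.Xv_in}
                     for a in self.policy.arcs],
            "dilution_fraction": (self.feasibility.dilution_fraction
                                  if self.feasibility else None),
            "message": self.message,
        }


def _total_consumption(space: SearchSpace, vector: np.ndarray) -> float:
    policy = decode(space, vector)
    return (substrate_consumption(policy, "GLC")
            + substrate_consumption(policy, "GLN"))


def _better(space, f_new, x_new, f_old, x_old) -> bool:
    """Elitist comparison; ties in Omega break toward lower feed consumption."""
    if f_new > f_old * (1 + _TIE_RTOL) + _TIE_RTOL:
        return True
    if abs(f_new - f_old) <= _TIE_RTOL * max(1.0, abs(f_old)):
        return _total_consumption(space, x_new) < _total_consumption(
            space, x_old)
    return False


def optimize_policy(space: SearchSpace, params: KineticParameters,
                    seed: int = 0, budget: int = 2000,
                    warm_start: FeedPolicy | None = None,
                    options: SolverOptions | None = None,
                    template: ScenarioDefinition | None = None,
                    popsize: int | None = None,
                    polish: bool = True,
                    spy=None) -> OptimizationResult:
    """Search the box for the policy maximizing the batch-wide mAb titer.

    ``budget`` caps the number of objective evaluations (each one a full
    batch simulation).  ``warm_start`` injects a known policy into the
    initial population; elitism guarantees the result is never worse than
    it.  ``spy``, if given, is called with every candidate vector before
    evaluation (test hook).

    Deterministic given (seed, budget, space, params).
    """
    dim = space.dimension
    pop_n = popsize or max(16, min(10 * dim, budget // 2))
    if budget < pop_n:
        raise ValueError(f"budget ({budget}) is below the population size "
                         f"({pop_n})")
    rng = np.random.default_rng(seed)
    b = space.bounds_array()
    lo, hi = b[:, 0], b[:, 1]

    def evaluate(x: np.ndarray) -> float:
        if spy is not None:
            spy(x)
        return objective(space, x, params, options, template)

    # --- initial population ---------------------------------------------
    pop = rng.uniform(lo, hi, size=(pop_n, dim))
    if warm_start is not None:
        pop[0] = space.clip(encode(warm_start))
    fitness = np.array([evaluate(x) for x in pop])
    n_evals = pop_n
    best_i = int(np.argmax(fitness))
    trace = [float(fitness[best_i])]
    logger.info("generation 0 (init): best Omega = %.4f mg/L", trace[-1])

    # --- DE generations (rand/1/bin, elitist) ---------------------------
    gen = 0
    while n_evals + 1 <= budget - (dim if polish else 0):
        gen += 1
        improved = False
        for i in range(pop_n):
            if n_evals >= budget - (dim if polish else 0):
                break
            idx = rng.choice(pop_n, size=3, replace=False)
            a, c, d = pop[idx]
            mutant = np.clip(a + _DE_F * (c - d), lo, hi)
            cross = rng.random(dim) < _DE_CR
            cross[rng.integers(dim)] = True
            trial = np.where(cross, mutant, pop[i])
            f_trial = evaluate(trial)
            n_evals += 1
            if _better(space, f_trial, trial, fitness[i], pop[i]):
                pop[i], fitness[i] = trial, f_trial
                if _better(space, f_trial, trial, fitness[best_i],
                           pop[best_i]):
                    best_i = i
                    improved = True
        trace.append(float(fitness[best_i]))
        logger.info("generation %d: best Omega = %.4f mg/L%s", gen,
                    trace[-1], " (improved)" if improved else "")
        if n_evals >= budget - (dim if polish else 0):
            break

    best_x = pop[best_i].copy()
    best_f = float(fitness[best_i])

    # --- local polish of the incumbent ----------------------------------
    message = f"DE finished after {gen} generations"
    if polish and budget - n_evals >= dim + 1:
        maxfev = budget - n_evals
        res = minimize(lambda x: -evaluate(space.clip(x)), best_x,
                       method="Powell",
                       bounds=[(l, h) for l, h in zip(lo, hi)],
                       options={"maxfev": maxfev, "xtol": 1e-8})
        n_evals += res.nfev
        cand = space.clip(res.x)
        if _better(space, -res.fun, cand, best_f, best_x):
            best_x, best_f = cand, float(-res.fun)
            message += "; polish improved the incumbent"
        else:
            message += "; polish kept the incumbent"
        trace.append(best_f)

    best_policy = decode(space, best_x)
    flags = feasibility_check(space, best_policy)
    return OptimizationResult(policy=best_policy, omega=best_f,
                              n_evaluations=n_evals, seed=seed, trace=trace,
                              feasibility=flags, message=message)
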