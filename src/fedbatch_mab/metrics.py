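"""Raw-material accounting and reactor performance indices.

Consumption is the closed-form sum of (feed rate x inlet concentration x arc
length) over the arcs of a policy — i.e. what was *fed*, excluding the
initial in-vessel load (which is reported separately).  Performance is the
maximum mAb titer over the batch and the specific productivity
max[mAb]/(biomass basis x t_f), where the basis is the initial cell load for
a batch run and the fed cells for a fed-batch run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .reactor import FeedPolicy, ScenarioDefinition, Trajectory

__all__ = [
    "ScenarioReport",
    "substrate_consumption",
    "biomass_fed",
    "final_volume",
    "max_mab",
    "specific_productivity",
    "build_report",
    "reports_to_table",
]

_INLET_FIELD = {"GLC": "GLC_in", "GLN": "GLN_in"}


def substrate_consumption(policy: FeedPolicy, species: str) -> float:
    """Total substrate fed over the batch, mmol: sum_j F_L,j * C_in,j * dt_j."""
    try:
        field = _INLET_FIELD[species]
    except KeyError:
        raise ValueError(f"species must be one of {sorted(_INLET_FIELD)}, "
                         f"got {species!r}") from None
    return sum(arc.F_L * getattr(arc, field) * dt
               for arc, dt in zip(policy.arcs, policy.arc_durations))


def biomass_fed(policy: FeedPolicy) -> float:
    """Total viable cells fed over the batch: sum_j F_L,j * Xv_in,j * dt_j."""
    return sum(arc.F_L * arc.Xv_in * dt
               for arc, dt in zip(policy.arcs, policy.arc_durations))


def final_volume(policy: FeedPolicy, V_L0: float) -> float:
    """End-of-batch liquid volume, L (no outflow): V_L0 + sum_j F_L,j dt_j."""
    return V_L0 + sum(arc.F_L * dt
                      for arc, dt in zip(policy.arcs, policy.arc_durations))


def max_mab(traj: Trajectory) -> tuple[float, float]:
    """Maximum mAb titer over the trajectory and the time it is reached.

    The dense-grid argmax is refined by a parabola through the three
    neighbouring samples (exact for the locally quadratic titer curve).
    """
    y = traj.mab
    t = traj.times
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(y[i]), float(t[i])
    # parabolic refinement on a possibly non-uniform grid
    coeffs = np.polyfit(t[i - 1:i + 2], y[i - 1:i + 2], 2)
    a, b, _ = coeffs
    if a < 0:
        t_star = -b / (2 * a)
        if t[i - 1] <= t_star <= t[i + 1]:
            y_star = float(np.polyval(coeffs, t_star))
            if y_star >= y[i]:
                return y_star, float(t_star)
    return float(y[i]), float(t[i])


def specific_productivity(max_mab_value: float, biomass_basis: float,
                          t_f: float) -> float:
    """Specific productivity max[mAb]/(basis * t_f), mg/(cell*h)."""
    if biomass_basis <= 0:
        raise ValueError("biomass basis must be positive")
    if t_f <= 0:
        raise ValueError("t_f must be positive")
    return max_mab_value / (biomass_basis * t_f)


@dataclass(frozen=True)
class ScenarioReport:
    """One-row summary of a reactor run (consumption + performance)."""

    name: str
    consumed_GLC: float          # mmol fed
    consumed_GLN: float          # mmol fed
    biomass_fed: float           # cells fed
    initial_GLC_load: float      # mmol in the vessel at t = 0
    initial_GLN_load: float      # mmol
    initial_biomass_load: float  # cells
    max_mab: float               # mg/L
    time_of_max: float           # h
    specific_productivity: float  # mg/(cell*h)
    final_volume: float          # L
    dilution_pct: float          # 100*(V_f - V_0)/V_0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def build_report(scenario: ScenarioDefinition,
                 traj: Trajectory) -> ScenarioReport:
    """Summarize a simulated scenario.

    The specific-productivity biomass basis is the fed cells for a fed-batch
    policy and the initial cell load for a batch (zero-feed) policy.
    """
    policy = scenario.policy
    mab, t_at = max_mab(traj)
    fed = biomass_fed(policy)
    v0 = scenario.V_L0
    initial_xv = policy.arcs[0].Xv_in * v0
    basis = fed if fed > 0 else initial_xv
    v_f = final_volume(policy, v0)
    return ScenarioReport(
        name=scenario.name,
        consumed_GLC=substrate_consumption(policy, "GLC"),
        consumed_GLN=substrate_consumption(policy, "GLN"),
        biomass_fed=fed,
        initial_GLC_load=policy.arcs[0].GLC_in * v0,
        initial_GLN_load=policy.arcs[0].GLN_in * v0,
        initial_biomass_load=initial_xv,
        max_mab=mab,
        time_of_max=t_at,
        specific_productivity=specific_productivity(mab, basis, policy.t_f),
        final_volume=v_f,
        dilution_pct=100.0 * (v_f - v0) / v0,
    )


def reports_to_table(reports) -> pd.DataFrame:
    """Stack reports into a comparison table (one scenario per row)."""
    return pd.DataFrame([r.to_dict() for r in reports])
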