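"""Hybridoma culture kinetics: growth, death, uptake and mAb-synthesis rate laws.

The kinetic model describes a mammalian hybridoma culture producing a
monoclonal antibody (mAb).  Growth follows dual-substrate Monod kinetics on
glucose (GLC) and glutamine (GLN), inhibited by the metabolic by-products
lactate (LAC) and ammonia (AMM).  Cell death is driven by ammonia, dead cells
lyse at a first-order rate, substrate uptake combines a growth-associated
yield with maintenance, by-products are formed in fixed stoichiometric
proportion to uptake, and mAb synthesis is partially growth-decoupled (the
``(2 - gamma*mu)`` modulation factor).

All functions are pure, operate on scalar floats and are shared between the
batch and fed-batch reactor balances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, fields
from importlib import resources

import numpy as np

__all__ = [
    "SPECIES",
    "KineticParameters",
    "CultureState",
    "load_default_parameters",
    "specific_growth_rate",
    "specific_death_rate",
    "glucose_uptake_rate",
    "glutamine_uptake_rate",
    "lactate_production_rate",
    "ammonia_production_rate",
    "mab_production_rate",
    "reaction_terms",
]

#: Canonical species ordering used throughout the package.
SPECIES = ("Xv", "Xt", "GLC", "GLN", "LAC", "AMM", "mAb")

# Negative maintenance coefficients are accepted only while they remain a
# small correction: |m_gln| may not exceed this fraction of mu_max/Y_x_gln,
# which keeps glutamine uptake non-negative for mu >= 0.05*mu_max.
_M_GLN_NEG_FRACTION = 0.05


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the reduced hybridoma kinetic model.

    Units: rates in 1/h, saturation/inhibition constants in mM, yields in
    cell/mmol, maintenance in mmol/(cell*h), ``gamma`` in h and
    ``lambda_mab`` in mg/(cell*h).  ``Y_lac_glc`` / ``Y_amm_gln`` are
    dimensionless mol-per-mol by-product yields.
    """

    mu_max: float = 0.058
    K_glc: float = 0.75
    K_gln: float = 0.075
    KI_lac: float = 172.0
    KI_amm: float = 28.5
    mu_d_max: float = 0.03
    K_d_amm: float = 1.76
    K_lysis: float = 0.0551
    Y_x_glc: float = 1.06e8
    m_glc: float = 4.85e-14
    Y_x_gln: float = 5.57e8
    m_gln: float = -6.7e-13
    K_d_gln: float = 0.0096
    Y_lac_glc: float = 1.4
    Y_amm_gln: float = 0.427
    gamma: float = 0.1
    lambda_mab: float = 7.21e-9

    def __post_init__(self) -> None:
        for name in ("K_glc", "K_gln", "KI_lac", "KI_amm", "K_d_amm",
                     "Y_x_glc", "Y_x_gln", "Y_lac_glc", "Y_amm_gln"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("mu_max", "mu_d_max", "K_lysis", "K_d_gln", "m_glc",
                     "gamma", "lambda_mab"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not all(math.isfinite(getattr(self, f.name)) for f in fields(self)):
            raise ValueError("all kinetic parameters must be finite")
        if not self.gamma * self.mu_max < 2:
            raise ValueError(
                "gamma*mu_max must be < 2 so the mAb synthesis factor "
                "(2 - gamma*mu) stays positive")
        # Glutamine uptake Q_gln = mu/Y_x_gln + m_gln is linear in mu; a
        # negative maintenance term is tolerated only as a small correction.
        if self.m_gln < 0:
            growth_term = self.mu_max / self.Y_x_gln
            if abs(self.m_gln) > _M_GLN_NEG_FRACTION * growth_term:
                raise ValueError(
                    f"m_gln = {self.m_gln:g} would drive glutamine uptake "
                    f"negative over most of mu in [0, mu_max] "
                    f"(|m_gln| > {_M_GLN_NEG_FRACTION:g}*mu_max/Y_x_gln); "
                    "check its scale (expected mmol/(cell*h))")

    @classmethod
    def from_json(cls, path_or_dict) -> "KineticParameters":
        if isinstance(path_or_dict, dict):
            return cls(**path_or_dict)
        with open(path_or_dict) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


def load_default_parameters() -> KineticParameters:
    """Load the packaged default rate-constant set (``lgm_params.json``)."""
    text = resources.files("fedbatch_mab.data").joinpath(
        "lgm_params.json").read_text()
    return KineticParameters(**json.loads(text))


@dataclass(frozen=True)
class CultureState:
    """Culture composition at one instant.

    Xv/Xt are viable/total cell densities (cells/L), GLC/GLN/LAC/AMM are in
    mM and mAb in mg/L.  ``Xt >= Xv`` is *not* required: when viable cells
    are fed with zero total-cell inlet the total-cell balance can fall below
    the viable one.
    """

    Xv: float
    Xt: float
    GLC: float
    GLN: float
    LAC: float
    AMM: float
    mAb: float

    def __post_init__(self) -> None:
        vals = (self.Xv, self.Xt, self.GLC, self.GLN, self.LAC, self.AMM,
                self.mAb)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite culture state: {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.Xv, self.Xt, self.GLC, self.GLN, self.LAC,
                         self.AMM, self.mAb], dtype=float)

    @classmethod
    def from_array(cls, y) -> "CultureState":
        return cls(*(float(v) for v in y))


def _clamp(c: float) -> float:
    # Exact clamp at zero: tiny negative integrator excursions must not
    # produce negative rates.
    return c if c > 0.0 else 0.0


def specific_growth_rate(state: CultureState, p: KineticParameters) -> float:
    """Specific growth rate mu (1/h).

    Product of two Monod saturation factors (GLC, GLN) and two inhibition
    factors (LAC, AMM), scaled by ``mu_max``.
    """
    glc = _clamp(state.GLC)
    gln = _clamp(state.GLN)
    lac = _clamp(state.LAC)
    amm = _clamp(state.AMM)
    return (p.mu_max
            * glc / (p.K_glc + glc)
            * gln / (p.K_gln + gln)
            * p.KI_lac / (p.KI_lac + lac)
            * p.KI_amm / (p.KI_amm + amm))


def specific_death_rate(state: CultureState, p: KineticParameters) -> float:
    """Ammonia-driven specific death rate mu_d (1/h).

    ``mu_d = mu_d_max / (1 + (K_d_amm/AMM)^2)``; the AMM -> 0 limit is 0 and
    is returned without evaluating the singular quotient.
    """
    amm = _clamp(state.AMM)
    if amm == 0.0:
        return 0.0
    ratio = p.K_d_amm / amm
    return p.mu_d_max / (1.0 + ratio * ratio)


def glucose_uptake_rate(mu: float, p: KineticParameters) -> float:
    """Specific glucose uptake Q_glc = mu/Y_x_glc + m_glc, mmol/(cell*h)."""
    return mu / p.Y_x_glc + p.m_glc


def glutamine_uptake_rate(mu: float, p: KineticParameters) -> float:
    """Specific glutamine uptake Q_gln = mu/Y_x_gln + m_gln, mmol/(cell*h).

    The maintenance coefficient ``m_gln`` may be slightly negative, so
    Q_gln(0) = m_gln < 0 is possible; parameter validation bounds the
    magnitude so that uptake is non-negative everywhere above 5% of mu_max.
    """
    return mu / p.Y_x_gln + p.m_gln


def lactate_production_rate(q_glc: float, p: KineticParameters) -> float:
    """Specific lactate production Q_lac = Y_lac_glc * Q_glc."""
    return p.Y_lac_glc * q_glc


def ammonia_production_rate(q_gln: float, p: KineticParameters) -> float:
    """Specific ammonia production Q_amm = Y_amm_gln * Q_gln."""
    return p.Y_amm_gln * q_gln


def mab_production_rate(state: CultureState, mu: float,
                        p: KineticParameters) -> float:
    """Volumetric mAb synthesis rate (2 - gamma*mu)*lambda*Xv, mg/(L*h)."""
    return (2.0 - p.gamma * mu) * p.lambda_mab * _clamp(state.Xv)


def reaction_terms(state: CultureState, p: KineticParameters) -> np.ndarray:
    """Per-species reaction rates, ordered as :data:`SPECIES`.

    These are the source/sink terms of the mass balances with every dilution
    term removed; the batch reactor integrates exactly this vector.
    """
    mu = specific_growth_rate(state, p)
    mu_d = specific_death_rate(state, p)
    q_glc = glucose_uptake_rate(mu, p)
    q_gln = glutamine_uptake_rate(mu, p)
    xv = _clamp(state.Xv)
    gln = _clamp(state.GLN)
    decomp = p.K_d_gln * gln  # abiotic glutamine decomposition -> ammonia
    return np.array([
        (mu - mu_d) * state.Xv,
        mu * state.Xv - p.K_lysis * (state.Xt - state.Xv),
        -q_glc * xv,
        -q_gln * xv - decomp,
        lactate_production_rate(q_glc, p) * xv,
        ammonia_production_rate(q_gln, p) * xv + decomp,
        mab_production_rate(state, mu, p),
    ])
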