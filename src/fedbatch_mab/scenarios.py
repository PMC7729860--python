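"""Packaged reference scenarios (SPBR, SP1, SP2, SP3) and their search spaces.

Each fixture is a JSON file shipped with the package carrying the per-arc
feed policy, the initial-state overrides, the search ranges used to derive
it, provenance notes and any known internal inconsistencies of the source
figures.
"""

from __future__ import annotations

import copy
import json
from importlib import resources

from .kinetics import KineticParameters, load_default_parameters
from .optimizer import SearchSpace
from .reactor import FeedArc, FeedPolicy, ScenarioDefinition

__all__ = [
    "FIXTURE_NAMES",
    "available_fixtures",
    "fixture_record",
    "load_fixture",
    "fixture_search_space",
]

FIXTURE_NAMES = ("SPBR", "SP1", "SP2", "SP3")

_cache: dict[str, dict] = {}


def available_fixtures() -> tuple:
    return FIXTURE_NAMES


def fixture_record(name: str) -> dict:
    """Raw fixture JSON (deep-copied), including provenance metadata."""
    key = name.upper()
    if key not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{', '.join(FIXTURE_NAMES)}")
    if key not in _cache:
        text = resources.files("fedbatch_mab.data.fixtures").joinpath(
            f"{key.lower()}.json").read_text()
        _cache[key] = json.loads(text)
    return copy.deepcopy(_cache[key])


def _policy_from_record(rec: dict) -> FeedPolicy:
    arcs = [FeedArc(F_L=a["F_L"], GLC_in=a["GLC_in"], GLN_in=a["GLN_in"],
                    Xv_in=a["Xv_in"]) for a in rec["arcs"]]
    return FeedPolicy.equal_arcs(rec["t_f"], arcs)


def load_fixture(name: str,
                 params: KineticParameters | None = None
                 ) -> ScenarioDefinition:
    """Build a :class:`ScenarioDefinition` for a packaged fixture.

    ``params`` defaults to the packaged rate-constant set.
    """
    rec = fixture_record(name)
    init = rec["initial"]
    return ScenarioDefinition(
        name=rec["name"],
        params=params or load_default_parameters(),
        policy=_policy_from_record(rec),
        mAb_0=init["mAb_0"], AMM_0=init["AMM_0"], LAC_0=init["LAC_0"],
        V_L0=init["V_L0"])


def fixture_search_space(name: str) -> SearchSpace:
    """The search ranges a fixture's policy was derived under."""
    rec = fixture_record(name)
    ss = rec.get("search_space")
    if ss is None:
        raise ValueError(f"fixture {name!r} has no search space "
                         "(batch reference run)")
    return SearchSpace(
        n_div=len(rec["arcs"]), t_f=rec["t_f"],
        F_L=tuple(ss["F_L"]), GLC_in=tuple(ss["GLC_in"]),
        GLN_in=tuple(ss["GLN_in"]), Xv_in=tuple(ss["Xv_in"]),
        V_L0=rec["initial"]["V_L0"],
        max_dilution_fraction=ss["max_dilution_fraction"])
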