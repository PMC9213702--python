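"""Diet-constrained flux balance analysis (FBA) for single species models.

FBA maximizes a flux objective (by default the biomass reaction) subject to
steady-state mass balance ``S v = 0`` and flux bounds.  Diet constraints are
applied to exchange reactions only: the uptake (lower) bound of each exchange
is opened to minus the diet's maximal uptake rate for that metabolite, while
secretion stays open at the default cap.  Under an anaerobic diet the oxygen
exchange is closed for uptake regardless of the diet table.

The linear programs are solved with the HiGHS solvers behind
:func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gem import DEFAULT_BOUND, GEM, GEMValidationError

__all__ = [
    "Diet",
    "FluxResult",
    "ExchangeProfile",
    "read_diet",
    "write_diet",
    "apply_diet",
    "fba",
    "exchange_profile",
    "group_average_flux",
    "validate_functional",
]

log = logging.getLogger(__name__)

#: flux magnitude below which an exchange is classified as inactive
DEFAULT_EPS = 1e-6
#: numerical tolerance handed to the LP solver
SOLVER_TOL = 1e-9


def _is_oxygen(met_id: str) -> bool:
    return met_id == "o2" or met_id.startswith("o2_")


@dataclass(frozen=True)
class Diet:
    """Maximal uptake rates (mmol/gDW/h) for external metabolites.

    A diet is deliberately a superset of any one model's exchanges: entries
    with no matching exchange in a given model are ignored (with a warning at
    application time).  ``anaerobic`` closes oxygen uptake and takes
    precedence over an oxygen entry in ``uptake_limits``.
    """

    uptake_limits: dict[str, float] = field(default_factory=dict)
    anaerobic: bool = True

    def __post_init__(self) -> None:
        for met, rate in self.uptake_limits.items():
            if rate < 0:
                raise ValueError(f"diet rate for {met!r} must be >= 0, got {rate}")


def read_diet(path: str | Path, anaerobic: bool = True) -> Diet:
    """Read a diet TSV with columns ``metabolite_id``, ``max_uptake_mmol_gDW_h``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"metabolite_id", "max_uptake_mmol_gDW_h"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: diet file must have columns {sorted(expected)}")
    limits = dict(zip(df["metabolite_id"], df["max_uptake_mmol_gDW_h"].astype(float)))
    return Diet(uptake_limits=limits, anaerobic=anaerobic)


def write_diet(diet: Diet, path: str | Path) -> None:
    rows = [{"metabolite_id": m, "max_uptake_mmol_gDW_h": r} for m, r in sorted(diet.uptake_limits.items())]
    pd.DataFrame(rows, columns=["metabolite_id", "max_uptake_mmol_gDW_h"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class FluxResult:
    """Outcome of one FBA solve."""

    status: str  # optimal | infeasible | unbounded
    growth_rate: float = float("nan")
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ExchangeProfile:
    """Sign-classified exchange fluxes: negative = uptake, positive = secretion."""

    produced: set[str]
    consumed: set[str]
    flux_by_metabolite: dict[str, float]


def apply_diet(gem: GEM, diet: Diet, secretion_cap: float = DEFAULT_BOUND) -> GEM:
    """Return a copy of ``gem`` with exchange bounds set from ``diet``.

    For the exchange of metabolite m: lower bound -diet.uptake_limits[m] if m
    is in the diet, else 0 (no uptake); upper bound ``secretion_cap``.  Diet
    metabolites without an exchange in this model are skipped.
    """
    bounded = gem.copy()
    model_mets = {bounded.exchanged_metabolite(rid): rid for rid in bounded.exchange_reaction_ids}
    for rid in bounded.exchange_reaction_ids:
        met = bounded.exchanged_metabolite(rid)
        rxn = bounded.reaction(rid)
        limit = diet.uptake_limits.get(met, 0.0)
        if diet.anaerobic and _is_oxygen(met):
            limit = 0.0
        rxn.lower_bound = -float(limit)
        rxn.upper_bound = secretion_cap
    missing = sorted(set(diet.uptake_limits) - set(model_mets))
    if missing:
        # diets are supersets of any one model's exchanges: warn, don't fail
        log.warning("model %r: diet metabolites with no exchange: %s", gem.id, missing)
    return bounded


def _solve_lp(
    S: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    objective_index: int,
) -> tuple[str, float, np.ndarray | None]:
    c = np.zeros(S.shape[1])
    c[objective_index] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lower, upper)),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL, "dual_feasibility_tolerance": SOLVER_TOL},
    )
    if res.status == 0:
        return "optimal", -res.fun, res.x
    if res.status == 2:
        return "infeasible", float("nan"), None
    if res.status == 3:
        return "unbounded", float("inf"), None
    raise RuntimeError(f"LP solver failed: {res.message}")


def fba(gem: GEM, diet: Diet | None = None, objective: str | None = None) -> FluxResult:
    """Maximize ``objective`` (default: biomass) under steady state and bounds.

    When a diet is given, exchange bounds are first set with
    :func:`apply_diet`; with ``diet=None`` the model's stored bounds are used
    as-is.  Returns one optimal vertex solution; the objective value is
    solver-deterministic, the flux vector need not be unique.
    """
    model = apply_diet(gem, diet) if diet is not None else gem
    objective = objective or model.biomass_reaction_id
    if objective not in model.reaction_ids:
        raise ValueError(f"objective reaction {objective!r} not in model {model.id!r}")
    rxns = model.reactions
    S = model.stoichiometric_matrix().to_numpy()
    lower = np.array([r.lower_bound for r in rxns])
    upper = np.array([r.upper_bound for r in rxns])
    obj_idx = [r.id for r in rxns].index(objective)
    status, value, x = _solve_lp(S, lower, upper, obj_idx)
    if status != "optimal":
        return FluxResult(status=status)
    fluxes = {r.id: float(v) for r, v in zip(rxns, x)}
    return FluxResult(status="optimal", growth_rate=float(value), fluxes=fluxes)


def exchange_profile(gem: GEM, result: FluxResult, eps: float = DEFAULT_EPS) -> ExchangeProfile:
    """Classify each exchanged metabolite as produced, consumed, or inactive.

    Produced iff exchange flux > eps, consumed iff flux < -eps; fluxes within
    [-eps, eps] are classified as neither, so the two sets are disjoint for
    any eps > 0.
    """
    if not result.optimal:
        raise ValueError("exchange_profile requires an optimal FBA result")
    produced, consumed, by_met = set(), set(), {}
    for rid in sorted(gem.exchange_reaction_ids):
        met = gem.exchanged_metabolite(rid)
        v = result.fluxes.get(rid, 0.0)
        by_met[met] = v
        if v > eps:
            produced.add(met)
        elif v < -eps:
            consumed.add(met)
    return ExchangeProfile(produced=produced, consumed=consumed, flux_by_metabolite=by_met)


def group_average_flux(
    profiles: dict[str, ExchangeProfile],
    groups: dict[str, str],
    carriers_only: bool = False,
) -> pd.DataFrame:
    """Mean exchange flux per metabolite within each model group.

    Rows are metabolites (union over models), columns the group labels.  By
    default a model lacking an exchange for a metabolite contributes flux 0,
    keeping group means comparable across the full metabolite panel;
    ``carriers_only=True`` averages over carrying models instead.
    """
    if set(profiles) - set(groups):
        raise ValueError("every profile needs a group label")
    labels = sorted(set(groups[m] for m in profiles))
    members = {g: [m for m in profiles if groups[m] == g] for g in labels}
    for g, ms in members.items():
        if not ms:
            raise ValueError(f"empty group {g!r}")
    mets = sorted(set().union(*(p.flux_by_metabolite for p in profiles.values())))
    out = pd.DataFrame(index=mets, columns=labels, dtype=float)
    for g in labels:
        for met in mets:
            vals = [
                profiles[m].flux_by_metabolite[met]
                for m in members[g]
                if met in profiles[m].flux_by_metabolite
            ]
            if carriers_only:
                out.loc[met, g] = float(np.mean(vals)) if vals else np.nan
            else:
                out.loc[met, g] = float(np.sum(vals)) / len(members[g])
    return out


def validate_functional(
    gem: GEM, rich_medium: Diet, tol: float = DEFAULT_EPS
) -> tuple[bool, dict]:
    """Check that a model can grow under a rich medium.

    A model is functional when FBA growth exceeds the feasibility tolerance
    with every exchange uptake opened.  When it cannot grow, the report lists
    the biomass precursors whose supply is blocked (no feasible drain flux).
    """
    if gem.biomass_reaction_id not in gem.reaction_ids:  # pragma: no cover
        raise GEMValidationError(f"model {gem.id!r} lacks a biomass reaction")
    result = fba(gem, rich_medium)
    report: dict = {"growth_rate": result.growth_rate, "status": result.status, "blocked_precursors": []}
    if result.optimal and result.growth_rate > tol:
        return True, report

    # probe each biomass substrate with a temporary drain reaction
    from .gem import Reaction  # local import keeps module top light

    biomass = gem.reaction(gem.biomass_reaction_id)
    bounded = apply_diet(gem, rich_medium)
    for met, coef in sorted(biomass.stoichiometry.items()):
        if coef >= 0:
            continue
        probe = bounded.copy()
        probe.reactions.append(
            Reaction(id="__drain__", stoichiometry={met: -1.0}, lower_bound=0.0, upper_bound=DEFAULT_BOUND)
        )
        probe.validate()
        drain = fba(probe, None, objective="__drain__")
        if not drain.optimal or drain.growth_rate <= tol:
            report["blocked_precursors"].append(met)
    return False, report
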