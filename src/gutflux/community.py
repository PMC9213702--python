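"""Personalized multi-species community models and community FBA.

A community model merges the top-N most abundant species of one sample into a
single stoichiometric system with three new compartments:

* ``u`` — a shared lumen through which species exchange metabolites;
* ``d`` — the diet side: one diet-uptake reaction per lumen metabolite
  (``DUt_<met>``, flux d -> u, capped by the diet);
* ``f`` — the output side: one removal reaction per lumen metabolite
  (``UFEx_<met>``, flux u -> f, representing loss to faeces/blood).

Each species keeps all of its reactions: internal metabolites are relabelled
into a private compartment ``c_<i>``, and every single-metabolite exchange
reaction becomes a transport between the species and the lumen with the same
bounds and sign convention (positive flux = secretion into the lumen).

Species abundances enter as renormalized weights.  Under the default
equality coupling, each species' biomass reaction produces one unit of a
species-biomass metabolite and the community biomass reaction consumes these
at the weight coefficients, so mass balance forces

    v_bio,i = weight_i * v_community.

A proportional-bound variant (``coupling="bound"``: v_bio,i <= weight_i *
v_max, total biomass maximized) is available for sensitivity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fba import DEFAULT_EPS, Diet, ExchangeProfile, FluxResult, _is_oxygen, _solve_lp
from .gem import DEFAULT_BOUND, GEM, Metabolite, Reaction, load_gem, save_gem

__all__ = [
    "CommunityModel",
    "CommunityFluxResult",
    "select_top_n",
    "make_community",
    "community_fba",
    "net_exchange_profile",
    "save_community",
    "load_community",
]

WEIGHT_TOL = 1e-6


@dataclass
class CommunityModel:
    """A merged multi-species model plus its community bookkeeping."""

    model: GEM
    species: list[str]
    weights: dict[str, float]
    lumen_metabolites: list[str]  # original external metabolite ids
    coupling: str = "equality"
    biomass_flux_ids: dict[str, str] = field(default_factory=dict)

    def diet_reaction(self, met: str) -> str:
        return f"DUt_{met}"

    def output_reaction(self, met: str) -> str:
        return f"UFEx_{met}"


@dataclass
class CommunityFluxResult:
    status: str
    community_growth: float = float("nan")
    species_growth: dict[str, float] = field(default_factory=dict)
    net_exchange: dict[str, float] = field(default_factory=dict)
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def select_top_n(
    abundance_row: dict[str, float] | pd.Series,
    n: int = 10,
    gems_available: set[str] | None = None,
) -> list[tuple[str, float]]:
    """Top-``n`` species of one sample with renormalized weights.

    Only species with positive abundance and (when given) an available model
    are eligible; ties at the cutoff are broken lexicographically by id.
    """
    if isinstance(abundance_row, pd.Series):
        abundance_row = abundance_row.to_dict()
    eligible = [
        (msp, a)
        for msp, a in abundance_row.items()
        if a > 0 and (gems_available is None or msp in gems_available)
    ]
    if not eligible:
        raise ValueError("no species with positive abundance and an available model")
    eligible.sort(key=lambda item: (-item[1], item[0]))
    top = eligible[:n]
    total = sum(a for _, a in top)
    return [(msp, a / total) for msp, a in top]


def _species_met(met: str, index: int) -> str:
    return f"{met}_c_{index}"


def _lumen_met(met: str) -> str:
    return f"{met}_u"


def make_community(
    gems: list[GEM],
    weights: dict[str, float],
    coupling: str = "equality",
    community_id: str = "community",
) -> CommunityModel:
    """Merge species models into one community model with abundance weights."""
    if coupling not in ("equality", "bound"):
        raise ValueError(f"unknown coupling mode {coupling!r}")
    ids = [g.id for g in gems]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids in community")
    if set(weights) != set(ids):
        raise ValueError("weights must cover exactly the community species")
    total = sum(weights.values())
    if abs(total - 1.0) > WEIGHT_TOL:
        raise ValueError(f"weights must sum to 1 (got {total})")

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    lumen_bases: dict[str, None] = {}  # ordered set of original external met ids
    biomass_flux_ids: dict[str, str] = {}

    for index, gem in enumerate(gems, start=1):
        rename = {m.id: _species_met(m.id, index) for m in gem.metabolites}
        for m in gem.metabolites:
            metabolites.append(
                Metabolite(
                    id=rename[m.id],
                    name=m.name,
                    compartment=f"c_{index}",
                    formula=m.formula,
                    kegg_id=m.kegg_id,
                )
            )
        for r in gem.reactions:
            rid = f"{r.id}__{gem.id}"
            if r.id in gem.exchange_reaction_ids:
                # exchange -> species/lumen transport, same bounds and sign
                met = gem.exchanged_metabolite(r.id)
                lumen_bases.setdefault(met, None)
                stoich = {rename[met]: -1.0, _lumen_met(met): 1.0}
            else:
                stoich = {rename[k]: v for k, v in r.stoichiometry.items()}
                if r.id == gem.biomass_reaction_id:
                    target = (
                        f"biomass__{gem.id}" if coupling == "equality" else "biomass_total_u"
                    )
                    stoich[target] = stoich.get(target, 0.0) + 1.0
                    biomass_flux_ids[gem.id] = rid
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    ko_ids=r.ko_ids,
                    subsystem=r.subsystem,
                )
            )

    for met in lumen_bases:
        metabolites.append(Metabolite(id=_lumen_met(met), name=met, compartment="u"))
        # diet side (d -> u): closed until a diet is applied
        reactions.append(
            Reaction(id=f"DUt_{met}", stoichiometry={_lumen_met(met): 1.0}, lower_bound=0.0, upper_bound=0.0)
        )
        # output side (u -> f)
        reactions.append(
            Reaction(id=f"UFEx_{met}", stoichiometry={_lumen_met(met): -1.0}, lower_bound=0.0, upper_bound=DEFAULT_BOUND)
        )

    if coupling == "equality":
        biomass_mets = {}
        for gem in gems:
            bid = f"biomass__{gem.id}"
            metabolites.append(Metabolite(id=bid, name=f"biomass of {gem.id}", compartment="u"))
            biomass_mets[bid] = -float(weights[gem.id])
        community_biomass = Reaction(
            id="community_biomass", stoichiometry=biomass_mets, lower_bound=0.0, upper_bound=DEFAULT_BOUND
        )
    else:
        metabolites.append(Metabolite(id="biomass_total_u", name="total biomass", compartment="u"))
        community_biomass = Reaction(
            id="community_biomass",
            stoichiometry={"biomass_total_u": -1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
        # proportional caps on each species' biomass flux
        for gem in gems:
            rid = biomass_flux_ids[gem.id]
            for r in reactions:
                if r.id == rid:
                    r.upper_bound = min(r.upper_bound, weights[gem.id] * DEFAULT_BOUND)
    reactions.append(community_biomass)

    merged = GEM(
        id=community_id,
        taxonomy={"phylum": "community"},
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id="community_biomass",
        exchange_reaction_ids={f"DUt_{m}" for m in lumen_bases}
        | {f"UFEx_{m}" for m in lumen_bases},
    )
    return CommunityModel(
        model=merged,
        species=list(ids),
        weights={k: float(v) for k, v in weights.items()},
        lumen_metabolites=list(lumen_bases),
        coupling=coupling,
        biomass_flux_ids=biomass_flux_ids,
    )


def community_fba(cm: CommunityModel, diet: Diet) -> CommunityFluxResult:
    """Maximize community biomass under the diet, steady state, and coupling.

    Diet limits are applied to the ``d -> u`` reactions only (community-level
    totals); species-internal bounds are left unscaled.
    """
    model = cm.model.copy()
    for met in cm.lumen_metabolites:
        rxn = model.reaction(cm.diet_reaction(met))
        limit = diet.uptake_limits.get(met, 0.0)
        if diet.anaerobic and _is_oxygen(met):
            limit = 0.0
        rxn.lower_bound, rxn.upper_bound = 0.0, float(limit)

    rxns = model.reactions
    S = model.stoichiometric_matrix().to_numpy()
    lower = np.array([r.lower_bound for r in rxns])
    upper = np.array([r.upper_bound for r in rxns])
    obj_idx = [r.id for r in rxns].index("community_biomass")
    status, value, x = _solve_lp(S, lower, upper, obj_idx)
    if status != "optimal":
        return CommunityFluxResult(status=status)
    fluxes = {r.id: float(v) for r, v in zip(rxns, x)}
    species_growth = {sp: fluxes[rid] for sp, rid in cm.biomass_flux_ids.items()}
    net = {
        met: fluxes[cm.output_reaction(met)] - fluxes[cm.diet_reaction(met)]
        for met in cm.lumen_metabolites
    }
    return CommunityFluxResult(
        status="optimal",
        community_growth=float(value),
        species_growth=species_growth,
        net_exchange=net,
        fluxes=fluxes,
    )


def net_exchange_profile(result: CommunityFluxResult, eps: float = DEFAULT_EPS) -> ExchangeProfile:
    """Classify the community's net lumen exchange: positive = exported to f."""
    if not result.optimal:
        raise ValueError("net_exchange_profile requires an optimal result")
    produced = {m for m, v in result.net_exchange.items() if v > eps}
    consumed = {m for m, v in result.net_exchange.items() if v < -eps}
    return ExchangeProfile(produced=produced, consumed=consumed, flux_by_metabolite=dict(result.net_exchange))


# -- serialization ----------------------------------------------------------


def save_community(cm: CommunityModel, path: str | Path) -> None:
    """GEM JSON dialect plus a ``community`` block (species, weights, coupling)."""
    path = Path(path)
    save_gem(cm.model, path)
    doc = json.loads(path.read_text())
    doc["community"] = {
        "species": cm.species,
        "weights": {k: cm.weights[k] for k in cm.species},
        "coupling": cm.coupling,
        "lumen_metabolites": cm.lumen_metabolites,
        "biomass_flux_ids": cm.biomass_flux_ids,
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


def load_community(path: str | Path) -> CommunityModel:
    doc = json.loads(Path(path).read_text())
    block = doc.pop("community")
    model = load_gem(path)
    return CommunityModel(
        model=model,
        species=list(block["species"]),
        weights={k: float(v) for k, v in block["weights"].items()},
        lumen_metabolites=list(block["lumen_metabolites"]),
        coupling=block.get("coupling", "equality"),
        biomass_flux_ids=dict(block["biomass_flux_ids"]),
    )
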