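"""Genome-scale metabolic model (GEM) containers, JSON I/O, and model comparison.

A GEM here is a species-level stoichiometric reconstruction: metabolites with
compartment labels, reactions with flux bounds and optional KEGG-ortholog (KO)
annotations, a biomass objective, and a set of single-metabolite exchange
(boundary) reactions.  Metabolite identity is by string id in a namespace
shared across models, which is what makes diet application, reaction-presence
profiling and community merging possible without an id-mapping layer.

Exchange convention: an exchange reaction has exactly one metabolite with
coefficient -1 on the external species; negative flux is uptake, positive flux
is secretion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "GEM",
    "GEMFormatError",
    "GEMValidationError",
    "load_gem",
    "save_gem",
    "load_gem_directory",
    "reaction_presence",
    "jaccard_distance",
    "jaccard_index",
]

#: default magnitude used for unconstrained flux bounds (mmol/gDW/h)
DEFAULT_BOUND = 1000.0

#: version of the on-disk GEM JSON dialect
GEM_DIALECT_VERSION = "1.0"


class GEMFormatError(ValueError):
    """Raised when a model file does not conform to the GEM JSON dialect."""


class GEMValidationError(ValueError):
    """Raised when a structurally parseable model violates a GEM invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species located in one compartment of a model."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    kegg_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise GEMValidationError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient: negative
    for substrates, positive for products.  Bounds are in mmol/gDW/h.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    ko_ids: frozenset[str] = frozenset()
    subsystem: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise GEMValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise GEMValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if not np.isfinite(coef) or coef == 0:
                raise GEMValidationError(
                    f"reaction {self.id!r}: coefficient for {met!r} must be "
                    f"finite and nonzero, got {coef!r}"
                )
        if self.lower_bound > self.upper_bound:
            raise GEMValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        self.ko_ids = frozenset(self.ko_ids)


@dataclass
class GEM:
    """A species genome-scale metabolic model."""

    id: str
    taxonomy: dict[str, str]
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    exchange_reaction_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    # -- views -------------------------------------------------------------

    @property
    def reaction_ids(self) -> set[str]:
        """The reaction-id set R_i used for model comparison."""
        return {r.id for r in self.reactions}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except AttributeError:
            self._rxn_index = {r.id: r for r in self.reactions}
            return self._rxn_index[rid]

    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    def exchanged_metabolite(self, rid: str) -> str:
        """The single external metabolite of exchange reaction ``rid``."""
        (met,) = self.reaction(rid).stoichiometry
        return met

    def exchange_for_metabolite(self, met_id: str) -> str | None:
        """Id of the exchange reaction moving ``met_id``, if any."""
        for rid in self.exchange_reaction_ids:
            if self.exchanged_metabolite(rid) == met_id:
                return rid
        return None

    def stoichiometric_matrix(self) -> pd.DataFrame:
        """Dense S matrix as a metabolites x reactions DataFrame."""
        mets = [m.id for m in self.metabolites]
        rxns = [r.id for r in self.reactions]
        S = pd.DataFrame(0.0, index=mets, columns=rxns)
        for r in self.reactions:
            for met, coef in r.stoichiometry.items():
                S.loc[met, r.id] = coef
        return S

    def copy(self) -> "GEM":
        return GEM(
            id=self.id,
            taxonomy=dict(self.taxonomy),
            metabolites=list(self.metabolites),
            reactions=[
                Reaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    ko_ids=r.ko_ids,
                    subsystem=r.subsystem,
                )
                for r in self.reactions
            ],
            biomass_reaction_id=self.biomass_reaction_id,
            exchange_reaction_ids=set(self.exchange_reaction_ids),
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if "phylum" not in self.taxonomy:
            raise GEMValidationError(f"model {self.id!r}: taxonomy lacks a phylum")
        declared = {m.id for m in self.metabolites}
        if len(declared) != len(self.metabolites):
            dupes = pd.Series([m.id for m in self.metabolites])
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise GEMValidationError(f"model {self.id!r}: duplicate metabolites {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = pd.Series(rxn_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise GEMValidationError(f"model {self.id!r}: duplicate reactions {dupes}")
        dangling = sorted(
            {met for r in self.reactions for met in r.stoichiometry if met not in declared}
        )
        if dangling:
            raise GEMValidationError(
                f"model {self.id!r}: reactions cite undeclared metabolites {dangling}"
            )
        if self.biomass_reaction_id not in set(rxn_ids):
            raise GEMValidationError(
                f"model {self.id!r}: biomass reaction "
                f"{self.biomass_reaction_id!r} not among reactions"
            )
        self._rxn_index = {r.id: r for r in self.reactions}
        for rid in self.exchange_reaction_ids:
            if rid not in self._rxn_index:
                raise GEMValidationError(
                    f"model {self.id!r}: exchange {rid!r} not among reactions"
                )
            if len(self._rxn_index[rid].stoichiometry) != 1:
                raise GEMValidationError(
                    f"model {self.id!r}: exchange {rid!r} must carry exactly one "
                    "metabolite"
                )


# -- JSON dialect -----------------------------------------------------------


def _reaction_to_json(r: Reaction) -> dict:
    out: dict = {
        "id": r.id,
        "stoich": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
        "lb": r.lower_bound,
        "ub": r.upper_bound,
    }
    if r.ko_ids:
        out["ko"] = sorted(r.ko_ids)
    if r.subsystem is not None:
        out["subsystem"] = r.subsystem
    return out


def save_gem(gem: GEM, path: str | Path) -> None:
    """Write a model in the GEM JSON dialect with canonical key ordering."""
    doc = {
        "id": gem.id,
        "taxonomy": {k: gem.taxonomy[k] for k in sorted(gem.taxonomy)},
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
                **({"kegg": m.kegg_id} if m.kegg_id else {}),
            }
            for m in gem.metabolites
        ],
        "reactions": [_reaction_to_json(r) for r in gem.reactions],
        "biomass_reaction": gem.biomass_reaction_id,
        "exchanges": sorted(gem.exchange_reaction_ids),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


def _require(doc: Mapping, key: str, path: Path) -> object:
    if key not in doc:
        raise GEMFormatError(f"{path}: missing required field {key!r}")
    return doc[key]


def load_gem(path: str | Path) -> GEM:
    """Read and validate a model from the GEM JSON dialect.

    Raises :class:`GEMFormatError` for malformed files (naming the offending
    field) and :class:`GEMValidationError` for invariant violations such as
    dangling metabolite references.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GEMFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, Mapping):
        raise GEMFormatError(f"{path}: top level must be an object")

    mets = []
    for entry in _require(doc, "metabolites", path):
        try:
            mets.append(
                Metabolite(
                    id=entry["id"],
                    name=entry.get("name", ""),
                    compartment=entry.get("compartment", "c"),
                    formula=entry.get("formula"),
                    kegg_id=entry.get("kegg"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise GEMFormatError(f"{path}: malformed metabolite entry {entry!r}") from exc
    rxns = []
    for entry in _require(doc, "reactions", path):
        try:
            rxns.append(
                Reaction(
                    id=entry["id"],
                    stoichiometry={k: float(v) for k, v in entry["stoich"].items()},
                    lower_bound=float(entry["lb"]),
                    upper_bound=float(entry["ub"]),
                    ko_ids=frozenset(entry.get("ko", ())),
                    subsystem=entry.get("subsystem"),
                )
            )
        except (KeyError, TypeError, AttributeError) as exc:
            raise GEMFormatError(
                f"{path}: malformed reaction entry "
                f"{entry.get('id', entry) if isinstance(entry, Mapping) else entry!r}"
            ) from exc
    return GEM(
        id=str(_require(doc, "id", path)),
        taxonomy=dict(_require(doc, "taxonomy", path)),
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=str(_require(doc, "biomass_reaction", path)),
        exchange_reaction_ids=set(_require(doc, "exchanges", path)),
    )


def load_gem_directory(path: str | Path) -> dict[str, GEM]:
    """Load every ``*.json`` model under ``path``, keyed by model id."""
    gems = {}
    for fp in sorted(Path(path).glob("*.json")):
        gem = load_gem(fp)
        gems[gem.id] = gem
    return gems


# -- model comparison -------------------------------------------------------


def reaction_presence(gems: Sequence[GEM]) -> pd.DataFrame:
    """Binary presence matrix, species x reaction-id universe.

    The universe is the union of all models' reaction-id sets; columns are
    sorted lexicographically so repeated runs produce identical matrices.
    """
    if not gems:
        raise ValueError("at least one model is required")
    universe = sorted(set().union(*(g.reaction_ids for g in gems)))
    rows = []
    for g in gems:
        rset = g.reaction_ids
        rows.append([1 if rid in rset else 0 for rid in universe])
    return pd.DataFrame(rows, index=[g.id for g in gems], columns=universe, dtype=np.int8)


def _as_reaction_set(obj: GEM | Iterable[str]) -> frozenset[str]:
    if isinstance(obj, GEM):
        return frozenset(obj.reaction_ids)
    return frozenset(obj)


def jaccard_distance(gem_a: GEM | Iterable[str], gem_b: GEM | Iterable[str]) -> float:
    """D = 1 - |Ra n Rb| / |Ra u Rb| on reaction-id sets.

    D = 0 means identical reaction content, D = 1 completely dissimilar.
    Accepts models or bare reaction-id sets.
    """
    ra, rb = _as_reaction_set(gem_a), _as_reaction_set(gem_b)
    union = ra | rb
    if not union:
        raise ValueError("Jaccard distance undefined for two empty reaction sets")
    return 1.0 - len(ra & rb) / len(union)


def jaccard_index(gem_a: GEM | Iterable[str], gem_b: GEM | Iterable[str]) -> float:
    """Similarity 1 - D: 1 for identical reaction sets, 0 for disjoint ones."""
    return 1.0 - jaccard_distance(gem_a, gem_b)
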