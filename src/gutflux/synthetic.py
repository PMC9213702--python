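"""Synthetic cohorts, toy species models, and plasma metabolomes.

Everything downstream of raw metagenome processing can be exercised offline
on data generated here.  The generator emulates the statistical structure the
analysis assumes rather than real gut communities:

* **Toy species models** share one metabolite namespace and follow a common
  template — sugar uptake, a central catabolic route to pyruvate, and a
  biomass reaction consuming pyruvate and glutamate.  Disease-designated
  species carry an acetogenic fermentation route (obligate acetate, proline
  and ammonia by-products, extra glutamate consumption) or a propionigenic
  one; control-designated species ferment to butyrate.  A marker subsystem of
  tartrate/glyoxylate-style reactions (annotated to two KEGG orthologs) is
  preferentially placed in disease-designated species, with presence
  fractions set so the expected enriched-vs-depleted gap equals
  ``marker_presence_gap``.  Accessory dead-end reactions give every model a
  distinct reaction complement.

* **Abundance tables** draw long-tailed (log-normal) baselines, renormalize
  per sample, and plant differential species with a multiplicative
  ``effect_size`` in their enriched group and zero-inflation in the other, so
  the two-step median selection rule is satisfiable.  BMI is drawn with a
  planted upward shift in disease cases of the obesity cohort.

* **Plasma metabolomes** plant linear reaction-metabolite associations
  (standardized log reaction abundance times ``association_effect``, plus
  covariate terms and Gaussian noise); remaining metabolites are covariate
  structure plus noise.

All outputs are deterministic functions of (config, seed); the returned
truth manifest records every planted effect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fba import Diet, validate_functional, write_diet
from .gem import GEM, Metabolite, Reaction, save_gem

__all__ = [
    "SyntheticConfig",
    "GenerationError",
    "MARKER_REACTIONS",
    "default_diet",
    "planted_species",
    "generate_toy_gems",
    "generate_abundance",
    "generate_metabolome",
    "generate_study",
]

DISEASES = ("obesity", "T2D", "ACVD")

#: marker ("tartrate-like") subsystem: five reactions from two KEGG orthologs
MARKER_REACTIONS: dict[str, tuple[dict[str, float], str]] = {
    "TARTDH": ({"tar_c": -1.0, "mal_c": 1.0}, "K07246"),
    "TARTDC": ({"tar_c": -1.0, "glr_c": 1.0}, "K07246"),
    "GLRD": ({"glr_c": -1.0, "pyr_c": 1.0}, "K07246"),
    "MALDH": ({"mal_c": -1.0, "oaa_c": 1.0}, "K00116"),
    "OAADC": ({"oaa_c": -1.0, "pyr_c": 1.0}, "K00116"),
}
MARKER_SUBSYSTEM = "glyoxylate and dicarboxylate metabolism"

# catabolic route variants per sugar; by-products are obligate, so growth
# forces their secretion (a species has exactly one route type for all sugars)
_ROUTES = {
    "plain": Reaction("CAT_glc", {"glc_c": -1.0, "pyr_c": 2.5}, 0.0, 1000.0),
    "acetogenic": Reaction(
        "CAT_glc_ac",
        {"glc_c": -1.0, "glu_c": -0.5, "pyr_c": 2.0, "ac_c": 2.0, "pro_c": 0.5, "nh3_c": 0.5},
        0.0,
        1000.0,
    ),
    "propionigenic": Reaction("CAT_glc_ppa", {"glc_c": -1.0, "pyr_c": 2.0, "ppa_c": 1.5}, 0.0, 1000.0),
    "butyrogenic": Reaction("CAT_glc_but", {"glc_c": -1.0, "pyr_c": 2.2, "but_c": 1.0}, 0.0, 1000.0),
}
_FRU_ROUTES = {
    "plain": Reaction("CAT_fru", {"fru_c": -1.0, "pyr_c": 2.4}, 0.0, 1000.0),
    "acetogenic": Reaction(
        "CAT_fru_ac",
        {"fru_c": -1.0, "glu_c": -0.4, "pyr_c": 1.9, "ac_c": 1.8, "pro_c": 0.4, "nh3_c": 0.4},
        0.0,
        1000.0,
    ),
    "propionigenic": Reaction("CAT_fru_ppa", {"fru_c": -1.0, "pyr_c": 1.9, "ppa_c": 1.4}, 0.0, 1000.0),
    "butyrogenic": Reaction("CAT_fru_but", {"fru_c": -1.0, "pyr_c": 2.1, "but_c": 0.9}, 0.0, 1000.0),
}
_ROUTE_BYPRODUCTS = {"acetogenic": ["ac", "pro", "nh3"], "propionigenic": ["ppa"], "butyrogenic": ["but"]}

_BMI_MEANS = {  # (case, control) group means per cohort, kg/m^2
    "obesity": (33.5, 23.5),
    "T2D": (25.6, 23.5),
    "ACVD": (24.8, 24.7),
}


class GenerationError(RuntimeError):
    """Raised when a configuration cannot yield functional models."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic data.

    Defaults are the conditions the package's end-to-end checks run under:
    60 case + 60 control samples per cohort, 40 species (~50 reactions per
    model), 10 planted differential species (half enriched in disease, half
    in controls) with an 8-fold abundance shift and 0.7 zero-inflation, a
    0.9 marker presence gap, and a 500-metabolite plasma panel with 10
    planted associations of effect 1.5 against unit noise.
    """

    n_species: int = 40
    n_samples_case: int = 60
    n_samples_control: int = 60
    n_planted_differential: int = 10
    effect_size: float = 8.0
    zero_inflation_prob: float = 0.7
    marker_reaction_set: tuple[str, ...] = tuple(MARKER_REACTIONS)
    marker_presence_gap: float = 0.9
    n_metabolites: int = 500
    n_planted_associations: int = 10
    association_effect: float = 1.5
    noise_sd: float = 1.0
    n_accessory_reactions: int = 60
    accessory_presence_prob: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("zero_inflation_prob", "marker_presence_gap", "accessory_presence_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_species", "n_samples_case", "n_samples_control", "n_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_differential > self.n_species:
            raise ValueError("cannot plant more differential species than species")


def default_diet() -> Diet:
    """The shipped synthetic high-fibre omnivore diet (anaerobic).

    Sugars dominate; glutamate and tryptophan are the amino-acid inputs,
    tartrate the marker substrate.  Oxygen is listed but overridden by the
    anaerobic flag.
    """
    return Diet(
        uptake_limits={
            "glc_e": 10.0,
            "fru_e": 8.0,
            "sucr_e": 5.0,
            "starch_e": 5.0,
            "glu_e": 2.0,
            "trp_e": 1.0,
            "tar_e": 1.0,
            "o2_e": 10.0,
        },
        anaerobic=True,
    )


def _species_ids(config: SyntheticConfig) -> list[str]:
    return [f"msp_{i:04d}" for i in range(1, config.n_species + 1)]


def planted_species(config: SyntheticConfig) -> dict[str, str]:
    """Planted differential species and their enrichment direction.

    The first half of the planted block is disease-enriched, the second half
    control-enriched (deterministic in the config, independent of the rng).
    """
    ids = _species_ids(config)
    n = config.n_planted_differential
    n_dis = (n + 1) // 2
    out = {}
    for i, sp in enumerate(ids[:n]):
        out[sp] = "disease-enriched" if i < n_dis else "control-enriched"
    return out


_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria", "Verrucomicrobia")


def _ext(met: str) -> tuple[str, str]:
    return f"{met}_e", f"{met}_c"


def _add_exchange_pair(mets: dict, rxns: list, exchanges: set, met: str, reversible: bool = True) -> None:
    """Declare met_e/met_c, the exchange EX_met_e, and the e<->c transport."""
    e, c = _ext(met)
    mets.setdefault(e, Metabolite(id=e, name=met, compartment="e"))
    mets.setdefault(c, Metabolite(id=c, name=met, compartment="c"))
    ex_id = f"EX_{e}"
    if ex_id not in {r.id for r in rxns}:
        rxns.append(Reaction(ex_id, {e: -1.0}, -1000.0, 1000.0))
        exchanges.add(ex_id)
        lb = -1000.0 if reversible else 0.0
        rxns.append(Reaction(f"T_{met}", {e: -1.0, c: 1.0}, lb, 1000.0))


def _build_species(
    sp_id: str,
    phylum: str,
    route: str,
    extra_sugars: set[str],
    has_indole: bool,
    has_marker: bool,
    accessory: list[int],
    accessory_kos: dict[int, str | None],
) -> GEM:
    mets: dict[str, Metabolite] = {}
    rxns: list[Reaction] = []
    exchanges: set[str] = set()

    def declare_c(met: str) -> None:
        mets.setdefault(f"{met}_c", Metabolite(id=f"{met}_c", name=met, compartment="c"))

    # core: glucose uptake, catabolism, biomass on pyruvate + glutamate
    _add_exchange_pair(mets, rxns, exchanges, "glc")
    _add_exchange_pair(mets, rxns, exchanges, "glu")
    declare_c("pyr")
    r = _ROUTES[route]
    for met in r.stoichiometry:
        declare_c(met.removesuffix("_c"))
    rxns.append(Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound, subsystem="central carbon"))
    for by in _ROUTE_BYPRODUCTS.get(route, []):
        _add_exchange_pair(mets, rxns, exchanges, by)
    rxns.append(
        Reaction("BIOMASS", {"pyr_c": -1.0, "glu_c": -0.3}, 0.0, 1000.0, subsystem="biomass")
    )
    # unused oxygen exchange: anaerobic handling applies to every model
    e = "o2_e"
    mets.setdefault(e, Metabolite(id=e, name="o2", compartment="e"))
    rxns.append(Reaction("EX_o2_e", {e: -1.0}, -1000.0, 1000.0))
    exchanges.add("EX_o2_e")

    if "fru" in extra_sugars or "sucr" in extra_sugars:
        _add_exchange_pair(mets, rxns, exchanges, "fru")
        fr = _FRU_ROUTES[route]
        for met in fr.stoichiometry:
            declare_c(met.removesuffix("_c"))
        rxns.append(Reaction(fr.id, dict(fr.stoichiometry), fr.lower_bound, fr.upper_bound, subsystem="central carbon"))
    if "sucr" in extra_sugars:
        _add_exchange_pair(mets, rxns, exchanges, "sucr")
        rxns.append(Reaction("SUC_H", {"sucr_c": -1.0, "glc_c": 1.0, "fru_c": 1.0}, 0.0, 1000.0))
    if "starch" in extra_sugars:
        _add_exchange_pair(mets, rxns, exchanges, "starch")
        rxns.append(Reaction("AMY", {"starch_c": -1.0, "glc_c": 3.0}, 0.0, 1000.0))
    if has_indole:
        _add_exchange_pair(mets, rxns, exchanges, "trp")
        _add_exchange_pair(mets, rxns, exchanges, "ind")
        rxns.append(Reaction("TRP_D", {"trp_c": -1.0, "ind_c": 1.0, "pyr_c": 1.0}, 0.0, 1000.0))
    if has_marker:
        _add_exchange_pair(mets, rxns, exchanges, "tar")
        for rid, (stoich, ko) in MARKER_REACTIONS.items():
            for met in stoich:
                declare_c(met.removesuffix("_c"))
            rxns.append(
                Reaction(rid, dict(stoich), 0.0, 1000.0, ko_ids=frozenset({ko}), subsystem=MARKER_SUBSYSTEM)
            )
    for k in accessory:
        a, b = f"acc{k:03d}a_c", f"acc{k:03d}b_c"
        mets.setdefault(a, Metabolite(id=a, name=a, compartment="c"))
        mets.setdefault(b, Metabolite(id=b, name=b, compartment="c"))
        ko = accessory_kos[k]
        rxns.append(
            Reaction(
                f"ACC_{k:03d}",
                {a: -1.0, b: 1.0},
                -1000.0,
                1000.0,
                ko_ids=frozenset({ko}) if ko else frozenset(),
                subsystem="accessory",
            )
        )

    return GEM(
        id=sp_id,
        taxonomy={"phylum": phylum},
        metabolites=list(mets.values()),
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
        exchange_reaction_ids=exchanges,
    )


def generate_toy_gems(config: SyntheticConfig) -> tuple[list[GEM], dict]:
    """Generate one functional toy model per species, plus a truth manifest."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = _species_ids(config)
    planted = planted_species(config)
    gap = config.marker_presence_gap
    p_disease = (1.0 + gap) / 2.0
    p_other = (1.0 - gap) / 2.0

    # accessory KO annotations are a property of the pan-reaction universe
    accessory_kos = {
        k: (f"K1{k:04d}" if rng.random() < 0.7 else None)
        for k in range(config.n_accessory_reactions)
    }

    gems: list[GEM] = []
    marker_carriers: list[str] = []
    for sp in ids:
        direction = planted.get(sp)
        if direction == "disease-enriched":
            route = "acetogenic" if rng.random() < 0.7 else "propionigenic"
            p_marker = p_disease
        elif direction == "control-enriched":
            route = "butyrogenic"
            p_marker = p_other
        else:
            route = str(rng.choice(["plain", "butyrogenic", "acetogenic", "propionigenic"]))
            p_marker = p_other
        has_marker = bool(rng.random() < p_marker)
        if has_marker:
            marker_carriers.append(sp)
        extra_sugars = {s for s in ("fru", "sucr", "starch") if rng.random() < 0.5}
        has_indole = bool(rng.random() < 0.3)
        accessory = sorted(
            int(k)
            for k in np.flatnonzero(rng.random(config.n_accessory_reactions) < config.accessory_presence_prob)
        )
        phylum = str(rng.choice(_PHYLA, p=[0.5, 0.25, 0.1, 0.1, 0.05]))
        gems.append(
            _build_species(sp, phylum, route, extra_sugars, has_indole, has_marker, accessory, accessory_kos)
        )

    diet = default_diet()
    for gem in gems:
        ok, report = validate_functional(gem, diet)
        if not ok:
            raise GenerationError(
                f"generated model {gem.id} is not functional under the shipped diet: {report}"
            )

    manifest = {
        "planted_species": planted,
        "marker_reactions": list(config.marker_reaction_set),
        "marker_carriers": marker_carriers,
        "marker_kos": sorted({MARKER_REACTIONS[r][1] for r in config.marker_reaction_set}),
        "routes": {g.id: next(r.id for r in g.reactions if r.id.startswith("CAT_glc")) for g in gems},
    }
    return gems, manifest


def generate_abundance(
    config: SyntheticConfig, disease: str = "obesity"
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """One cohort's abundance table, sample metadata, and truth manifest."""
    disease_index = DISEASES.index(disease) if disease in DISEASES else 99
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, disease_index]))
    ids = _species_ids(config)
    planted = planted_species(config)

    baseline = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_species)
    for i, sp in enumerate(ids):
        if sp in planted:
            baseline[i] = 0.5  # low, equal baselines keep group totals balanced

    n_case, n_ctrl = config.n_samples_case, config.n_samples_control
    n = n_case + n_ctrl
    is_case = np.array([True] * n_case + [False] * n_ctrl)
    values = baseline[None, :] * rng.lognormal(mean=0.0, sigma=0.7, size=(n, config.n_species))
    for i, sp in enumerate(ids):
        direction = planted.get(sp)
        if direction is None:
            continue
        enriched_in_case = direction == "disease-enriched"
        boost = is_case if enriched_in_case else ~is_case
        values[boost, i] *= config.effect_size
        zeroed = (~boost) & (rng.random(n) < config.zero_inflation_prob)
        values[zeroed, i] = 0.0
    row_sums = values.sum(axis=1, keepdims=True)
    values = values / row_sums

    sample_ids = [
        f"{disease}_{'case' if c else 'ctrl'}_{k:03d}"
        for k, c in zip(
            list(range(1, n_case + 1)) + list(range(1, n_ctrl + 1)), is_case
        )
    ]
    table = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=ids)

    bmi_case, bmi_ctrl = _BMI_MEANS.get(disease, (25.0, 24.0))
    bmi = np.where(is_case, rng.normal(bmi_case, 3.0, n), rng.normal(bmi_ctrl, 2.5, n))
    bmi = np.clip(bmi, 15.0, 60.0)
    age = np.clip(np.where(is_case, rng.normal(58.0, 8.0, n), rng.normal(52.0, 8.0, n)), 18, 90)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(is_case, "case", "control"),
            "disease": np.where(is_case, disease, "none"),
            "cohort": f"synthetic-{disease}",
            "bmi": np.round(bmi, 2),
            "age": np.round(age, 1),
            "sex": rng.choice(["F", "M"], size=n),
        }
    )
    manifest = {"disease": disease, "planted_species": planted, "effect_size": config.effect_size,
                "zero_inflation_prob": config.zero_inflation_prob}
    return table, meta, manifest


def generate_metabolome(
    config: SyntheticConfig, ra: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Plasma metabolite table with planted linear reaction associations.

    Planted pairs cycle through the marker reactions (several metabolites per
    marker when more pairs are requested than markers exist; high-variance
    reactions are the fallback when no marker is in the matrix); signs
    alternate positive/negative.  Every metabolite carries small age, sex,
    and BMI effects so covariate adjustment is exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    meta_ix = meta.set_index("sample_id").loc[ra.index]
    n = len(ra.index)

    markers = [r for r in config.marker_reaction_set if r in ra.columns]
    by_var = [c for c in ra.columns[np.argsort(-ra.to_numpy().var(axis=0))] if c not in markers]
    # planted effects live on the marker subsystem (cycled when more pairs
    # than markers are requested); high-variance reactions are the fallback
    candidates = markers if markers else by_var
    planted_pairs = []
    for k in range(config.n_planted_associations):
        rid = candidates[k % len(candidates)]
        sign = 1.0 if k % 2 == 0 else -1.0
        planted_pairs.append((rid, f"met_{k + 1:04d}", sign))

    age = meta_ix["age"].to_numpy(dtype=float)
    sex = (meta_ix["sex"] == "M").to_numpy(dtype=float)
    bmi = meta_ix["bmi"].to_numpy(dtype=float)

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    covar_part = 0.3 * z(age) + 0.2 * sex + 0.25 * z(bmi)
    values = np.empty((n, config.n_metabolites))
    planted_by_met = {m: (r, s) for r, m, s in planted_pairs}
    from .association import log_transform

    logra = log_transform(ra)
    col_of = {c: i for i, c in enumerate(ra.columns)}
    for j in range(config.n_metabolites):
        met_id = f"met_{j + 1:04d}"
        y = covar_part + rng.normal(0.0, config.noise_sd, n)
        if met_id in planted_by_met:
            rid, sign = planted_by_met[met_id]
            y = y + sign * config.association_effect * z(logra[:, col_of[rid]])
        values[:, j] = y
    table = pd.DataFrame(
        values,
        index=pd.Index(ra.index, name="sample_id"),
        columns=[f"met_{j + 1:04d}" for j in range(config.n_metabolites)],
    )
    manifest = {
        "planted_associations": [
            {"reaction_id": r, "metabolite_id": m, "sign": "positive" if s > 0 else "negative"}
            for r, m, s in planted_pairs
        ],
        "association_effect": config.association_effect,
        "noise_sd": config.noise_sd,
    }
    return table, manifest


def generate_study(config: SyntheticConfig, out_dir: str | Path | None = None) -> dict:
    """Generate models, all three disease cohorts, the diet, a metabolome for
    the obesity cohort, and a combined truth manifest; optionally write all
    of it under ``out_dir``.
    """
    from .gem import reaction_presence
    from .reactobiome import compute_reaction_abundance

    gems, gem_manifest = generate_toy_gems(config)
    cohorts = {}
    for disease in DISEASES:
        table, meta, _ = generate_abundance(config, disease)
        cohorts[disease] = {"abundance": table, "metadata": meta}
    presence = reaction_presence(gems)
    ra = compute_reaction_abundance(presence, cohorts["obesity"]["abundance"])
    metabolome, met_manifest = generate_metabolome(config, ra, cohorts["obesity"]["metadata"])
    truth = {
        "config": asdict(config),
        **gem_manifest,
        **met_manifest,
        "metabolome_cohort": "obesity",
    }

    study = {
        "gems": gems,
        "cohorts": cohorts,
        "diet": default_diet(),
        "metabolome": metabolome,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        (out / "gems").mkdir(parents=True, exist_ok=True)
        for gem in gems:
            save_gem(gem, out / "gems" / f"{gem.id}.json")
        for disease, parts in cohorts.items():
            parts["abundance"].to_csv(out / f"abundance_{disease}.tsv", sep="\t")
            parts["metadata"].to_csv(out / f"metadata_{disease}.tsv", sep="\t", index=False)
        metabolome.to_csv(out / "metabolome.tsv", sep="\t")
        write_diet(study["diet"], out / "diet.tsv")
        (out / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    return study
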