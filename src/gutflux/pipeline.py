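"""End-to-end orchestration: inputs -> species selection -> FBA -> reactobiome
-> community models -> metabolome association, with a run manifest.

Every stage writes its result as a TSV under the output directory; no stage
mutates another stage's outputs.  Re-running with an identical config (and
seed) reproduces byte-identical outputs.  Structured progress goes to the
module logger (stderr under the CLI); results only to files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import association as assoc
from . import community as comm
from . import reactobiome as rb
from . import stats
from .fba import Diet, exchange_profile, fba, group_average_flux, read_diet
from .gem import jaccard_distance, load_gem_directory, reaction_presence
from .synthetic import DISEASES, SyntheticConfig, default_diet, generate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable stage name and code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run; defaults are the analysis
    thresholds (FDR 0.01 at species, reaction, and association level; raw
    alpha 0.05 for the BMI split at cut 30 kg/m^2; communities of the top 10
    species)."""

    out_dir: str | Path = "pipeline_out"
    seed: int = 17
    input_dir: str | Path | None = None  # pre-generated study; None -> synthesize
    diet_path: str | Path | None = None  # None -> shipped synthetic diet
    anaerobic: bool = True
    msp_fdr: float = 0.01
    reaction_fdr: float = 0.01
    association_fdr: float = 0.01
    bmi_alpha: float = 0.05
    bmi_cut: float = 30.0
    top_n: int = 10
    presence_gap: float = 0.2
    n_community_samples: int = 16  # per group, in the community-model stage
    synthetic: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        for name in ("msp_fdr", "reaction_fdr", "association_fdr", "bmi_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        synth_keys = {f.name for f in fields(SyntheticConfig)}
        own_keys = {f.name for f in fields(cls)} - {"synthetic"}
        synth = {k: v for k, v in doc.items() if k in synth_keys and k != "seed"}
        own = {k: v for k, v in doc.items() if k in own_keys}
        unknown = set(doc) - synth_keys - own_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**own)
        if synth:
            cfg.synthetic = SyntheticConfig(seed=cfg.seed, **synth)
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 0: inputs ---------------------------------------------------
    if config.diet_path is not None and not Path(config.diet_path).exists():
        raise PipelineError("inputs", "missing-diet", f"diet file not found: {config.diet_path}")
    if config.input_dir is not None:
        indir = Path(config.input_dir)
        if not indir.exists():
            raise PipelineError("inputs", "missing-input-dir", f"input directory not found: {indir}")
        log.info("loading study inputs from %s", indir)
        gems = list(load_gem_directory(indir / "gems").values())
        cohorts = {}
        for disease in DISEASES:
            cohorts[disease] = {
                "abundance": stats.read_abundance(indir / f"abundance_{disease}.tsv"),
                "metadata": stats.read_metadata(indir / f"metadata_{disease}.tsv"),
            }
        metabolome = assoc.read_metabolite_table(indir / "metabolome.tsv")
        truth_path = indir / "truth.json"
        truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    else:
        log.info("generating synthetic study (seed=%d)", config.synthetic.seed)
        study = generate_study(config.synthetic, out_dir=out / "inputs")
        gems = study["gems"]
        cohorts = study["cohorts"]
        metabolome = study["metabolome"]
        truth = study["truth"]
    diet = read_diet(config.diet_path, anaerobic=config.anaerobic) if config.diet_path else default_diet()
    gem_by_id = {g.id: g for g in gems}

    manifest: dict = {
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "n_models": len(gems),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, path: Path, rows: int) -> None:
        manifest["stages"].setdefault(stage, {})[path.name] = rows
        manifest["outputs"][path.name] = _checksum(path)

    # -- stage 1: differential species selection ---------------------------
    selected_by_disease: dict[str, pd.DataFrame] = {}
    for disease, parts in cohorts.items():
        try:
            sel = stats.select_significant_msps(parts["abundance"], parts["metadata"], config.msp_fdr)
        except ValueError as exc:
            raise PipelineError("msp-diff", "bad-groups", str(exc)) from exc
        sel = sel.sort_values("feature_id").reset_index(drop=True)
        selected_by_disease[disease] = sel
        p = out / f"msp_diff_{disease}.tsv"
        _write_tsv(sel, p)
        record("msp-diff", p, len(sel))
        log.info("%s: %d selected MSPs", disease, len(sel))
    union = stats.unique_union(
        {d: set(sel["feature_id"]) for d, sel in selected_by_disease.items()}
    )
    manifest["n_selected_msps_union"] = len(union)

    # enrichment direction per selected species: taken from the disease(s)
    # where it was selected; first-listed disease wins on conflict
    model_groups: dict[str, str] = {}
    for disease in DISEASES:
        sel = selected_by_disease.get(disease)
        if sel is None:
            continue
        for _, row in sel.iterrows():
            model_groups.setdefault(row["feature_id"], row["direction"])

    # -- stage 2: individual FBA of selected models ------------------------
    selected_models = [gem_by_id[m] for m in sorted(union) if m in gem_by_id]
    if not selected_models:
        raise PipelineError("fba", "no-models", "no selected species has a model")
    profiles, growths = {}, {}
    for gem in selected_models:
        res = fba(gem, diet)
        if not res.optimal:
            raise PipelineError("fba", "solver", f"FBA {res.status} for model {gem.id}")
        growths[gem.id] = res.growth_rate
        profiles[gem.id] = exchange_profile(gem, res)
    groups_for_avg = {m: model_groups[m] for m in profiles}
    avg_flux = group_average_flux(profiles, groups_for_avg)
    p = out / "group_average_flux.tsv"
    _write_tsv(avg_flux.rename_axis("metabolite_id"), p, index=True)
    record("fba", p, len(avg_flux))
    growth_df = pd.DataFrame(
        sorted(growths.items()), columns=["model_id", "growth_rate_per_h"]
    )
    p = out / "model_growth.tsv"
    _write_tsv(growth_df, p)
    record("fba", p, len(growth_df))
    manifest["mean_growth_rate_per_h"] = float(growth_df["growth_rate_per_h"].mean())

    pairs = [
        (a.id, b.id, jaccard_distance(a, b))
        for i, a in enumerate(selected_models)
        for b in selected_models[i + 1 :]
    ]
    if pairs:
        dist = [d for _, _, d in pairs]
        manifest["mean_jaccard_distance"] = float(pd.Series(dist).mean())
        manifest["mean_jaccard_index"] = 1.0 - manifest["mean_jaccard_distance"]

    # -- stage 3: reactobiome ----------------------------------------------
    presence = reaction_presence(gems)
    diffs: dict[str, pd.DataFrame] = {}
    for disease, parts in cohorts.items():
        ra = rb.compute_reaction_abundance(presence, parts["abundance"])
        diff = rb.differential_reactions(ra, parts["metadata"], config.reaction_fdr)
        diff = diff.sort_values("feature_id").reset_index(drop=True)
        diffs[disease] = diff
        p = out / f"reaction_diff_{disease}.tsv"
        _write_tsv(diff, p)
        record("reaction-diff", p, len(diff))
        manifest["stages"].setdefault("reaction-sig", {})[disease] = len(
            rb.significant_set(diff, config.reaction_fdr)
        )
    shared = rb.intersect_significant(diffs, config.reaction_fdr)
    consistent = rb.consistent_direction(diffs, shared)
    gap_kept = rb.presence_gap_filter(presence, model_groups, config.presence_gap, reactions=shared)
    komap = rb.ko_map_from_gems(gems)
    kos, unmapped = rb.map_to_kos(shared, komap)
    summary = pd.DataFrame(
        {
            "reaction_id": sorted(shared),
            "consistent_direction": [r in consistent for r in sorted(shared)],
            "passes_presence_gap": [r in gap_kept for r in sorted(shared)],
            "kos": [",".join(sorted(komap.get(r, set()))) for r in sorted(shared)],
        }
    )
    p = out / "shared_reactions.tsv"
    _write_tsv(summary, p)
    record("intersect", p, len(summary))
    manifest["n_shared_significant_reactions"] = len(shared)
    manifest["n_consistent_reactions"] = len(consistent)
    manifest["n_presence_gap_reactions"] = len(gap_kept)
    manifest["n_kos"] = len(kos)
    manifest["n_unmapped_reactions"] = len(unmapped)

    # -- stage 4: community models ----------------------------------------
    com_cohort = cohorts[truth["metabolome_cohort"]] if truth else cohorts["obesity"]
    meta_ix = com_cohort["metadata"].set_index("sample_id")
    by_group = {g: [s for s in com_cohort["abundance"].index if meta_ix.loc[s, "group"] == g] for g in ("case", "control")}
    chosen = by_group["case"][: config.n_community_samples] + by_group["control"][: config.n_community_samples]
    available = set(gem_by_id)
    rows, growth_rows = [], []
    for sample in chosen:
        top = comm.select_top_n(com_cohort["abundance"].loc[sample], config.top_n, available)
        cm = comm.make_community([gem_by_id[m] for m, _ in top], dict(top), community_id=f"community_{sample}")
        res = comm.community_fba(cm, diet)
        if not res.optimal:
            raise PipelineError("community", "solver", f"community FBA {res.status} for {sample}")
        growth_rows.append(
            {"sample_id": sample, "group": meta_ix.loc[sample, "group"], "community_growth": res.community_growth}
        )
        for met, v in sorted(res.net_exchange.items()):
            rows.append({"sample_id": sample, "group": meta_ix.loc[sample, "group"], "metabolite_id": met, "net_flux": v})
    growth_df = pd.DataFrame(growth_rows)
    p = out / "community_growth.tsv"
    _write_tsv(growth_df, p)
    record("community", p, len(growth_df))
    net_df = pd.DataFrame(rows)
    group_net = (
        net_df.pivot_table(index="metabolite_id", columns="group", values="net_flux", aggfunc="mean")
        .rename_axis(columns=None)
        .sort_index()
    )
    p = out / "community_group_net_flux.tsv"
    _write_tsv(group_net.rename_axis("metabolite_id"), p, index=True)
    record("community", p, len(group_net))
    manifest["mean_community_growth"] = float(growth_df["community_growth"].mean())
    manifest["n_community_models"] = len(growth_df)

    # -- stage 5: metabolome association -----------------------------------
    # focus on the cross-disease significant reactions (the pathway of
    # interest), falling back to the full matrix when the intersection is empty
    ra_met = rb.compute_reaction_abundance(presence, com_cohort["abundance"])
    focus = sorted(shared) if shared else list(ra_met.columns)
    try:
        assoc_df = assoc.fit_associations(
            ra_met[focus], metabolome, com_cohort["metadata"], fdr=config.association_fdr
        )
    except ValueError as exc:
        raise PipelineError("associate", "bad-input", str(exc)) from exc
    sig = assoc_df[assoc_df["significant"]].sort_values(["reaction_id", "metabolite_id"])
    p = out / "associations.tsv"
    _write_tsv(sig, p)
    record("associate", p, len(sig))
    manifest["n_significant_associations"] = len(sig)
    manifest["n_associated_reactions"] = int(sig["reaction_id"].nunique())
    manifest["n_associated_metabolites"] = int(sig["metabolite_id"].nunique())

    bmi_reactions = set(sig["reaction_id"]) or set(ra_met.columns)
    bmi_df = assoc.bmi_stratified_test(
        ra_met, com_cohort["metadata"], reactions=bmi_reactions,
        bmi_cut=config.bmi_cut, alpha=config.bmi_alpha,
    )
    p = out / "bmi_split.tsv"
    _write_tsv(bmi_df, p)
    record("bmi-split", p, len(bmi_df))
    manifest["n_bmi_significant_reactions"] = int(bmi_df["significant"].sum())

    # -- recovery against the truth manifest --------------------------------
    if truth is not None:
        planted = truth["planted_species"]
        recovered = {
            d: set(sel["feature_id"]) & set(planted) for d, sel in selected_by_disease.items()
        }
        marker = set(truth["marker_reactions"])
        planted_assoc = {
            (a["reaction_id"], a["metabolite_id"], a["sign"]) for a in truth["planted_associations"]
        }
        found_assoc = {
            (r.reaction_id, r.metabolite_id, r.sign) for r in sig.itertuples()
        }
        manifest["recovery"] = {
            "planted_species": len(planted),
            "recovered_species_union": len(set().union(*recovered.values())),
            "recovered_species_min_disease": min(len(v) for v in recovered.values()),
            "marker_reactions": len(marker),
            "markers_in_shared": len(marker & shared),
            "markers_consistent": len(marker & consistent),
            "markers_pass_gap": len(marker & gap_kept),
            "markers_pass_all_filters": len(marker & consistent & gap_kept),
            "planted_associations": len(planted_assoc),
            "recovered_associations_sign_correct": len(planted_assoc & found_assoc),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    log.info("pipeline complete: %s", out / "manifest.json")
    return manifest
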