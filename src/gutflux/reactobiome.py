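"""Per-sample reaction-abundance ("reactobiome") profiling.

The reaction abundance of reaction j in sample s is the summed relative
abundance of the species whose models carry j:

    RA(s, j) = sum_i P(i, j) * a(i, s)

with P the binary species x reaction presence matrix and a the species
relative abundance.  Presence is binary — per-model reaction copy number is
not multiplied in.  Downstream, reactions are tested case vs control per
disease (Wilcoxon + BH), intersected across diseases, filtered for a
consistent enrichment direction, mapped to KEGG orthologs (KOs), and filtered
by the presence-gap rule on enriched vs depleted species models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats
from .gem import GEM

__all__ = [
    "compute_reaction_abundance",
    "differential_reactions",
    "intersect_significant",
    "consistent_direction",
    "ko_map_from_gems",
    "map_to_kos",
    "ko_abundance",
    "presence_gap_filter",
]

log = logging.getLogger(__name__)


def compute_reaction_abundance(presence: pd.DataFrame, abundance: pd.DataFrame) -> pd.DataFrame:
    """Samples x reactions abundance matrix: ``abundance @ presence``.

    ``presence`` is species x reactions (binary), ``abundance`` samples x
    species.  Species in the abundance table without a model contribute
    nothing and are logged; species in ``presence`` absent from the table are
    dropped the same way.
    """
    shared = [s for s in abundance.columns if s in set(presence.index)]
    if not shared:
        raise ValueError("no species shared between abundance table and presence matrix")
    missing_models = sorted(set(abundance.columns) - set(shared))
    if missing_models:
        log.warning("%d species lack a model and are ignored: %s", len(missing_models), missing_models[:10])
    ra = abundance[shared].to_numpy(dtype=float) @ presence.loc[shared].to_numpy(dtype=float)
    return pd.DataFrame(ra, index=abundance.index, columns=presence.columns)


def differential_reactions(
    matrix: pd.DataFrame, meta: pd.DataFrame, fdr: float = 0.01
) -> pd.DataFrame:
    """Per-reaction case/control differential table (all reactions, with FDR).

    Significance at the given threshold is a filter applied downstream; the
    full table is returned so intersection and direction checks can reuse it.
    """
    diff = stats.differential_table(matrix, meta)
    diff.attrs["fdr_threshold"] = fdr
    return diff


def significant_set(diff: pd.DataFrame, fdr: float = 0.01) -> set[str]:
    """Reaction ids with BH FDR below threshold."""
    return set(diff.loc[diff["fdr"] < fdr, "feature_id"])


def intersect_significant(per_disease: dict[str, pd.DataFrame], fdr: float = 0.01) -> set[str]:
    """Reactions significant (FDR < threshold) in every disease."""
    if len(per_disease) < 2:
        raise ValueError("need at least two diseases to intersect")
    sets = [significant_set(d, fdr) for d in per_disease.values()]
    return set.intersection(*sets)


def consistent_direction(
    per_disease: dict[str, pd.DataFrame],
    reactions: set[str],
    direction: str = stats.DISEASE_ENRICHED,
) -> set[str]:
    """Subset of ``reactions`` with the same enrichment direction in every disease."""
    keep = set(reactions)
    for diff in per_disease.values():
        directed = set(diff.loc[diff["direction"] == direction, "feature_id"])
        keep &= directed
    return keep


def ko_map_from_gems(gems: list[GEM]) -> dict[str, set[str]]:
    """reaction id -> union of KO annotations over all models carrying it."""
    komap: dict[str, set[str]] = {}
    for g in gems:
        for r in g.reactions:
            if r.ko_ids:
                komap.setdefault(r.id, set()).update(r.ko_ids)
    return komap


def map_to_kos(reactions: set[str], komap: dict[str, set[str]]) -> tuple[set[str], set[str]]:
    """Deduplicated KO union over a reaction set, plus the unannotated reactions."""
    kos: set[str] = set()
    unmapped: set[str] = set()
    for rid in reactions:
        annotations = komap.get(rid)
        if annotations:
            kos |= set(annotations)
        else:
            unmapped.add(rid)
    return kos, unmapped


def ko_abundance(matrix: pd.DataFrame, komap: dict[str, set[str]]) -> pd.DataFrame:
    """Samples x KO abundance: sum of member-reaction abundances per KO.

    Supports KO-level re-testing (differential_reactions on the result) as an
    alternative to taking the plain KO union over significant reactions.
    """
    cols: dict[str, np.ndarray] = {}
    for rid, kos in komap.items():
        if rid not in matrix.columns:
            continue
        for ko in kos:
            if ko in cols:
                cols[ko] = cols[ko] + matrix[rid].to_numpy(dtype=float)
            else:
                cols[ko] = matrix[rid].to_numpy(dtype=float).copy()
    return pd.DataFrame(cols, index=matrix.index).sort_index(axis=1)


def presence_gap_filter(
    presence: pd.DataFrame,
    model_groups: dict[str, str],
    min_gap: float = 0.2,
    reactions: set[str] | None = None,
) -> set[str]:
    """Reactions whose presence fraction differs by more than ``min_gap``
    between disease-enriched and control-enriched species models.
    """
    enriched = [m for m, g in model_groups.items() if g == stats.DISEASE_ENRICHED and m in presence.index]
    depleted = [m for m, g in model_groups.items() if g == stats.CONTROL_ENRICHED and m in presence.index]
    if not enriched or not depleted:
        raise ValueError("both model groups must be non-empty")
    cols = sorted(reactions) if reactions is not None else list(presence.columns)
    frac_enriched = presence.loc[enriched, cols].mean(axis=0)
    frac_depleted = presence.loc[depleted, cols].mean(axis=0)
    gap = (frac_enriched - frac_depleted).abs()
    return set(gap.index[gap > min_gap])
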