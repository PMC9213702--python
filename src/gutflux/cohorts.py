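"""Published cohort summaries of the targeted metabolic-disease studies.

These are the printed per-cohort and per-disease sample counts of the public
gut-metagenome studies (EBI/SRA accessions) whose analysis this package
re-implements.  They are inputs for bookkeeping and consistency arithmetic
only — the raw metagenomes themselves are out of scope and all computation
runs on synthetic data.

Known discrepancy, reproduced as printed and deliberately not reconciled:
the per-cohort T2D case counts (71 + 93) do not sum to the per-disease T2D
case total (271).
"""

from __future__ import annotations

__all__ = [
    "COHORTS",
    "DISEASE_TOTALS",
    "total_subjects",
    "cases_from_cohorts",
    "controls_from_cohorts",
    "selection_worked_example",
]

#: per-cohort rows: disease, label, region, case/control counts, accessions
COHORTS = [
    {"disease": "T2D", "cohort": "T2D cohort 1", "region": "China", "n_case": 71, "n_control": 192,
     "accessions": ("SRA045646", "SRA050230")},
    {"disease": "T2D", "cohort": "T2D cohort 2", "region": "Sweden", "n_case": 93, "n_control": 39,
     "accessions": ("ERP002469",)},
    {"disease": "obesity", "cohort": "Obesity cohort 1", "region": "Denmark", "n_case": 71, "n_control": 89,
     "accessions": ("ERA000116",)},
    {"disease": "obesity", "cohort": "Obesity cohort 2", "region": "Denmark", "n_case": 207, "n_control": 174,
     "accessions": ("ERP003612",)},
    {"disease": "ACVD", "cohort": "ACVD cohort 1", "region": "China", "n_case": 214, "n_control": 171,
     "accessions": ("ERP023788",)},
    {"disease": "ACVD", "cohort": "ACVD cohort 2", "region": "Sweden", "n_case": 5, "n_control": 10,
     "accessions": ("SRA059451",)},
]

#: per-disease totals (cases, controls) from the study-level summary
DISEASE_TOTALS = {"obesity": (278, 263), "T2D": (271, 231), "ACVD": (219, 181)}


def total_subjects() -> int:
    """Overall subject count across the three diseases (cases + controls)."""
    return sum(c + n for c, n in DISEASE_TOTALS.values())


def cases_from_cohorts(disease: str) -> int:
    """Case count for a disease obtained by summing its cohort rows."""
    return sum(row["n_case"] for row in COHORTS if row["disease"] == disease)


def controls_from_cohorts(disease: str) -> int:
    return sum(row["n_control"] for row in COHORTS if row["disease"] == disease)


def selection_worked_example() -> dict[str, set[str]]:
    """Synthetic per-disease selected-MSP sets for the union bookkeeping check.

    A synthetic stand-in (the real per-disease selections live in an external
    supplement): three sets of sizes 17 (obesity), 6 (T2D), and 25 (ACVD)
    in which the six T2D species are exactly the overlap with ACVD, matching
    the published overlap structure, so the deduplicated union has 42
    members.
    """
    obesity = {f"mspO_{i:02d}" for i in range(1, 18)}
    shared = {f"mspS_{i:02d}" for i in range(1, 7)}
    t2d = set(shared)
    acvd = shared | {f"mspA_{i:02d}" for i in range(1, 20)}
    return {"obesity": obesity, "T2D": t2d, "ACVD": acvd}
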