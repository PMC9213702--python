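"""Shared fixtures: hand-built toy networks and seeded synthetic studies."""

from __future__ import annotations

import logging

import pytest

from gutflux.fba import Diet
from gutflux.gem import GEM, Metabolite, Reaction
from gutflux.pipeline import PipelineConfig, run_pipeline
from gutflux.synthetic import SyntheticConfig, generate_study

logging.getLogger("gutflux").setLevel(logging.ERROR)


def build_gem(gem_id, metabolites, reactions, biomass, exchanges, taxonomy=None):
    return GEM(
        id=gem_id,
        taxonomy=taxonomy or {"phylum": "Firmicutes"},
        metabolites=[Metabolite(id=m, compartment=("e" if m.endswith("_e") else "c")) for m in metabolites],
        reactions=reactions,
        biomass_reaction_id=biomass,
        exchange_reaction_ids=set(exchanges),
    )


@pytest.fixture
def chain_gem():
    """A uptake -> conversion -> biomass; growth is uptake-limited at 10/h."""
    return build_gem(
        "chain",
        ["A_e", "A_c", "B_c"],
        [
            Reaction("EX_A_e", {"A_e": -1.0}, -10.0, 1000.0),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, -1000.0, 1000.0),
            Reaction("CONV", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B_c": -1.0}, 0.0, 1000.0),
        ],
        "BIOMASS",
        ["EX_A_e"],
    )


@pytest.fixture
def branched_gem():
    """Six-reaction branched network with a hand-checkable optimum of 12."""
    return build_gem(
        "branched",
        ["A_e", "A_c", "B_c", "C_c", "D_c"],
        [
            Reaction("EX_A_e", {"A_e": -1.0}, -10.0, 1000.0),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
            Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 6.0),
            Reaction("R2", {"A_c": -1.0, "C_c": 2.0}, 0.0, 1000.0),
            Reaction("R3", {"B_c": -1.0, "C_c": -1.0, "D_c": 2.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"D_c": -1.0}, 0.0, 1000.0),
        ],
        "BIOMASS",
        ["EX_A_e"],
    )


@pytest.fixture
def simple_diet():
    return Diet(uptake_limits={"A_e": 10.0}, anaerobic=True)


SMALL = SyntheticConfig(
    seed=11,
    n_species=14,
    n_samples_case=30,
    n_samples_control=30,
    n_planted_differential=4,
    n_metabolites=60,
    n_planted_associations=4,
    n_accessory_reactions=30,
)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study reused across module tests."""
    return generate_study(SMALL)


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """One full pipeline run at the default study conditions."""
    out = tmp_path_factory.mktemp("pipeline")
    manifest = run_pipeline(PipelineConfig(out_dir=out, seed=17))
    return out, manifest
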