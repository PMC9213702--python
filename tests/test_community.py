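"""Community construction and community FBA: equivalences, mass balance,
coupling, and determinism."""

import numpy as np
import pytest

from gutflux.community import (
    community_fba,
    load_community,
    make_community,
    net_exchange_profile,
    save_community,
    select_top_n,
)
from gutflux.fba import Diet, fba
from gutflux.gem import Reaction
from gutflux.synthetic import default_diet
from conftest import build_gem


def _single_substrate_species(gem_id):
    """Uptake S, biomass with yield 1 per unit substrate."""
    return build_gem(
        gem_id,
        ["S_e", "S_c"],
        [
            Reaction("EX_S_e", {"S_e": -1.0}, -1000.0, 1000.0),
            Reaction("T_S", {"S_e": -1.0, "S_c": 1.0}, -1000.0, 1000.0),
            Reaction("BIOMASS", {"S_c": -1.0}, 0.0, 1000.0),
        ],
        "BIOMASS",
        ["EX_S_e"],
    )


def test_select_top_n_renormalizes_and_breaks_ties():
    top = select_top_n({"A": 0.5, "B": 0.3, "C": 0.2}, n=2)
    assert top == [("A", pytest.approx(0.625)), ("B", pytest.approx(0.375))]
    # n larger than the species count keeps everything
    assert len(select_top_n({"A": 0.5, "B": 0.3}, n=10)) == 2
    # lexicographic tie-break at the cutoff
    top = select_top_n({"mspB": 0.2, "mspA": 0.2, "mspC": 0.6}, n=2)
    assert [m for m, _ in top] == ["mspC", "mspA"]
    # zero-abundance and model-less species are ineligible
    top = select_top_n({"A": 0.5, "B": 0.0, "C": 0.5}, n=3, gems_available={"A", "B"})
    assert [m for m, _ in top] == [("A")]
    with pytest.raises(ValueError):
        select_top_n({"A": 0.0}, n=2)


def test_construction_counts_and_weights_validation():
    sp = _single_substrate_species("spA")
    cm = make_community([sp], {"spA": 1.0})
    # all species reactions kept + 2 per lumen metabolite + community biomass
    assert len(cm.model.reactions) == len(sp.reactions) + 2 * len(cm.lumen_metabolites) + 1
    assert cm.lumen_metabolites == ["S_e"]
    with pytest.raises(ValueError):
        make_community([sp, sp], {"spA": 1.0})
    with pytest.raises(ValueError):
        make_community([sp], {"spA": 0.9})


def test_shared_lumen_metabolite_is_deduplicated():
    a, b = _single_substrate_species("spA"), _single_substrate_species("spB")
    cm = make_community([a, b], {"spA": 0.5, "spB": 0.5})
    duts = [r for r in cm.model.reactions if r.id.startswith("DUt_")]
    outs = [r for r in cm.model.reactions if r.id.startswith("UFEx_")]
    assert len(duts) == 1 and len(outs) == 1


def test_two_identical_species_split_a_shared_substrate():
    """Hand-derived optimum: substrate capped at 10, yield 1, equal weights
    -> community growth 10, each species carrying half."""
    a, b = _single_substrate_species("spA"), _single_substrate_species("spB")
    cm = make_community([a, b], {"spA": 0.5, "spB": 0.5})
    res = community_fba(cm, Diet(uptake_limits={"S_e": 10.0}, anaerobic=True))
    assert res.optimal
    assert res.community_growth == pytest.approx(10.0, abs=1e-6)
    assert res.species_growth["spA"] == pytest.approx(5.0, abs=1e-6)
    assert res.species_growth["spB"] == pytest.approx(5.0, abs=1e-6)
    assert res.net_exchange["S_e"] == pytest.approx(-10.0, abs=1e-6)


def test_species_growth_follows_abundance_coupling():
    a, b = _single_substrate_species("spA"), _single_substrate_species("spB")
    cm = make_community([a, b], {"spA": 0.8, "spB": 0.2})
    res = community_fba(cm, Diet(uptake_limits={"S_e": 10.0}, anaerobic=True))
    for sp, w in cm.weights.items():
        assert res.species_growth[sp] == pytest.approx(w * res.community_growth, abs=1e-6)


def test_single_species_community_equals_individual_fba(small_study):
    diet = default_diet()
    for gem in small_study["gems"]:
        single = fba(gem, diet)
        cm = make_community([gem], {gem.id: 1.0})
        res = community_fba(cm, diet)
        assert res.optimal
        assert res.community_growth == pytest.approx(single.growth_rate, abs=1e-6)


def test_lumen_mass_balance(small_study):
    """Steady state holds in every compartment including the lumen: for each
    lumen metabolite, diet inflow + production = outflow + consumption."""
    gems = small_study["gems"][:4]
    w = 1.0 / len(gems)
    cm = make_community(gems, {g.id: w for g in gems})
    res = community_fba(cm, default_diet())
    assert res.optimal
    S = cm.model.stoichiometric_matrix()
    v = np.array([res.fluxes[r] for r in S.columns])
    imbalance = S.to_numpy() @ v
    assert np.abs(imbalance).max() <= 1e-6
    lumen_rows = [i for i, m in enumerate(S.index) if m.endswith("_u")]
    assert np.abs(imbalance[lumen_rows]).max() <= 1e-6


def test_block_assembly_structure():
    """The merged stoichiometry equals the explicit block construction for a
    two-species pair: per-species blocks, exchange-to-transport rewiring,
    and weight-coefficient community biomass."""
    a, b = _single_substrate_species("spA"), _single_substrate_species("spB")
    cm = make_community([a, b], {"spA": 0.6, "spB": 0.4})
    S = cm.model.stoichiometric_matrix()
    # species block: internal reaction touches only that species' metabolites
    assert S.loc["S_c_c_1", "T_S__spA"] == 1.0
    assert S.loc["S_e_c_1", "T_S__spA"] == -1.0
    assert (S.loc[[m for m in S.index if m.endswith("_c_2")], "T_S__spA"] == 0).all()
    # exchange rewired into a species<->lumen transport
    assert S.loc["S_e_c_1", "EX_S_e__spA"] == -1.0
    assert S.loc["S_e_u", "EX_S_e__spA"] == 1.0
    # biomass coupling: community biomass consumes species biomass at weights
    assert S.loc["biomass__spA", "community_biomass"] == pytest.approx(-0.6)
    assert S.loc["biomass__spB", "community_biomass"] == pytest.approx(-0.4)
    assert S.loc["biomass__spA", "BIOMASS__spA"] == pytest.approx(1.0)
    # diet and output reactions move only the lumen metabolite
    assert S.loc["S_e_u", "DUt_S_e"] == 1.0
    assert S.loc["S_e_u", "UFEx_S_e"] == -1.0


def test_equality_coupling_never_beats_proportional_bound():
    """Relaxing the equality coupling to proportional caps can only increase
    the attainable community biomass."""
    a, b = _single_substrate_species("spA"), _single_substrate_species("spB")
    diet = Diet(uptake_limits={"S_e": 10.0}, anaerobic=True)
    for wa in (0.5, 0.7, 0.9):
        weights = {"spA": wa, "spB": 1.0 - wa}
        eq = community_fba(make_community([a, b], weights), diet)
        bound = community_fba(make_community([a, b], weights, coupling="bound"), diet)
        assert bound.community_growth >= eq.community_growth - 1e-9


def test_diet_relaxation_monotone_for_communities(small_study):
    gems = small_study["gems"][:3]
    cm = make_community(gems, {g.id: 1 / 3 for g in gems})
    diet = default_diet()
    base = community_fba(cm, diet).community_growth
    rng = np.random.default_rng(5)
    for _ in range(10):
        met = rng.choice(sorted(diet.uptake_limits))
        relaxed = Diet(
            uptake_limits={**diet.uptake_limits, met: diet.uptake_limits[met] * (1 + rng.uniform(0, 2))},
            anaerobic=True,
        )
        assert community_fba(cm, relaxed).community_growth >= base - 1e-7


def test_determinism_and_roundtrip(tmp_path, small_study):
    gems = small_study["gems"][:3]
    weights = {g.id: 1 / 3 for g in gems}
    diet = default_diet()
    g1 = community_fba(make_community(gems, weights), diet).community_growth
    g2 = community_fba(make_community(gems, weights), diet).community_growth
    assert g1 == g2  # bit-identical for identical inputs and solver settings
    cm = make_community(gems, weights)
    path = tmp_path / "community.json"
    save_community(cm, path)
    back = load_community(path)
    assert back.species == cm.species
    assert back.weights == pytest.approx(cm.weights)
    assert community_fba(back, diet).community_growth == pytest.approx(g1, abs=1e-9)


def test_net_exchange_profile_classification(small_study):
    gems = small_study["gems"][:3]
    cm = make_community(gems, {g.id: 1 / 3 for g in gems})
    res = community_fba(cm, default_diet())
    prof = net_exchange_profile(res)
    assert not (prof.produced & prof.consumed)
    # growth requires dietary sugar and glutamate (a biomass precursor)
    assert prof.consumed & {"glc_e", "fru_e", "sucr_e", "starch_e"}
    assert "glu_e" in prof.consumed
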