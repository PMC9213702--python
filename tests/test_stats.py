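"""Rank-sum testing, BH adjustment, the two-step selection rule, and
phylum aggregation — each checked against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutflux.stats import (
    CONTROL_ENRICHED,
    DISEASE_ENRICHED,
    aggregate_by_phylum,
    benjamini_hochberg,
    differential_table,
    enrichment_direction,
    select_significant_msps,
    unique_union,
    wilcoxon_two_sided,
)


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration of group labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    n2 = len(y)
    lo = min(u_obs, n1 * n2 - u_obs)
    hi = n1 * n2 - lo
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[pooled[i]] for i in combo) - n1 * (n1 + 1) / 2
        if u <= lo + 1e-9 or u >= hi - 1e-9:
            count += 1
        total += 1
    return count / total


@pytest.mark.parametrize("n1,n2", [(3, 3), (4, 3), (4, 4), (5, 5), (6, 6), (2, 8)])
def test_exact_wilcoxon_matches_full_enumeration(n1, n2):
    rng = np.random.default_rng(100 + n1 * 10 + n2)
    for _ in range(5):
        pooled = rng.permutation(rng.uniform(0, 10, n1 + n2))
        x, y = pooled[:n1], pooled[n1:]
        assert wilcoxon_two_sided(x, y) == pytest.approx(
            wilcoxon_enumeration_oracle(x, y), abs=1e-12
        )


def test_extreme_separation_small_sample():
    # complete separation of 3 vs 3: 2 of the 20 labelings are as extreme
    assert wilcoxon_two_sided([1.2, 3.4, 5.6], [7.8, 9.1, 10.2]) == pytest.approx(0.1)


def test_identical_samples_give_p_one():
    assert wilcoxon_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)


def test_wilcoxon_rejects_empty():
    with pytest.raises(ValueError):
        wilcoxon_two_sided([], [1.0])


@settings(max_examples=100, derandomize=True)
@given(
    data=st.lists(st.integers(-100, 100), min_size=6, max_size=16, unique=True),
    split=st.integers(2, 4),
)
def test_wilcoxon_invariant_under_monotone_transform(data, split):
    x, y = np.array(data[:split], dtype=float), np.array(data[split:], dtype=float)
    p = wilcoxon_two_sided(x, y)
    assert wilcoxon_two_sided(np.exp(x / 50), np.exp(y / 50)) == pytest.approx(p, rel=1e-9)
    assert wilcoxon_two_sided(3 * x + 2, 3 * y + 2) == pytest.approx(p, rel=1e-9)


def test_type_one_error_is_calibrated():
    """Empirical size at alpha=0.05 over 500 independent null features stays
    inside the 99% binomial interval."""
    rng = np.random.default_rng(2024)
    alpha, n_feat = 0.05, 500
    rejections = sum(
        wilcoxon_two_sided(rng.normal(size=30), rng.normal(size=30)) < alpha
        for _ in range(n_feat)
    )
    half_width = 2.576 * np.sqrt(alpha * (1 - alpha) / n_feat)
    assert abs(rejections / n_feat - alpha) <= half_width


def test_bh_hand_stepped_vectors():
    assert benjamini_hochberg([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])
    assert benjamini_hochberg([1.0, 1.0]) == pytest.approx([1.0, 1.0])
    assert benjamini_hochberg([0.37]) == pytest.approx([0.37])
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.5])


@settings(max_examples=100, derandomize=True)
@given(p=st.lists(st.floats(0, 1), min_size=1, max_size=25), seed=st.integers(0, 10**6))
def test_bh_properties(p, seed):
    adj = benjamini_hochberg(p)
    assert (adj >= np.asarray(p) - 1e-15).all()
    assert (adj <= 1.0).all()
    # order-equivariance: adjusting a permutation permutes the adjustment
    perm = np.random.default_rng(seed).permutation(len(p))
    assert benjamini_hochberg(np.asarray(p)[perm]) == pytest.approx(adj[perm])


def _toy_cohort():
    rng = np.random.default_rng(7)
    n = 40
    sample_ids = [f"s{i}" for i in range(n)]
    case = np.array([True] * 20 + [False] * 20)
    table = pd.DataFrame(
        {
            # selected: zero in controls, positive in cases
            "planted": np.where(case, rng.uniform(0.1, 0.2, n), 0.0),
            # shifted but both medians positive -> excluded by the median rule
            "shifted": np.where(case, rng.uniform(0.3, 0.4, n), rng.uniform(0.05, 0.1, n)),
            # null
            "flat": rng.uniform(0.1, 0.2, n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta = pd.DataFrame({"sample_id": sample_ids, "group": np.where(case, "case", "control")})
    return table, meta


def test_two_step_selection_rule():
    table, meta = _toy_cohort()
    sel = select_significant_msps(table, meta, fdr_threshold=0.01)
    assert list(sel["feature_id"]) == ["planted"]
    row = sel.iloc[0]
    assert row["fdr"] < 0.01 and row["median_control"] == 0 and row["median_case"] > 0
    assert row["direction"] == DISEASE_ENRICHED
    # the shifted feature is significant but fails the median rule
    diff = differential_table(table, meta)
    assert diff.set_index("feature_id").loc["shifted", "fdr"] < 0.01


def test_selection_requires_minimum_group_size():
    table, meta = _toy_cohort()
    with pytest.raises(ValueError):
        select_significant_msps(table.iloc[:21], meta.iloc[:21])


def test_enrichment_direction_and_tie_break():
    assert enrichment_direction(0.4, 0.1) == DISEASE_ENRICHED
    assert enrichment_direction(0.2, 0.2) == CONTROL_ENRICHED  # strict inequality
    table, meta = _toy_cohort()
    diff = differential_table(table, meta)
    fc = diff.set_index("feature_id")["fold_change"]
    assert fc["planted"] > 0 and fc["shifted"] > 0


def test_fold_change_sign_with_zero_case_mean():
    rng = np.random.default_rng(3)
    n = 20
    table = pd.DataFrame(
        {"f": np.concatenate([np.zeros(10), rng.uniform(0.1, 0.3, 10)])},
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    meta = pd.DataFrame(
        {"sample_id": table.index, "group": ["case"] * 10 + ["control"] * 10}
    )
    diff = differential_table(table, meta)
    assert diff["fold_change"].iloc[0] < 0
    assert diff["direction"].iloc[0] == CONTROL_ENRICHED


def test_aggregate_by_phylum_matches_groupby_oracle():
    rng = np.random.default_rng(12)
    features = [f"msp{i}" for i in range(50)]
    phyla = {f: f"P{rng.integers(0, 5)}" for f in features}
    table = pd.DataFrame(
        rng.uniform(0, 0.02, (8, 50)), columns=features,
        index=pd.Index([f"s{i}" for i in range(8)], name="sample_id"),
    )
    agg = aggregate_by_phylum(table, phyla)
    for s in table.index:
        for ph in set(phyla.values()):
            expected = sum(table.loc[s, f] for f in features if phyla[f] == ph)
            assert agg.loc[s, ph] == pytest.approx(expected)
    # simple additivity
    two = aggregate_by_phylum(
        pd.DataFrame({"a": [0.1], "b": [0.2]}, index=["s"]), {"a": "Firmicutes", "b": "Firmicutes"}
    )
    assert two.loc["s", "Firmicutes"] == pytest.approx(0.3)


def test_unique_union_bookkeeping():
    assert unique_union({"a": {"x"}, "b": {"y"}, "c": {"z"}}) == {"x", "y", "z"}
    assert unique_union({"a": {"x", "y"}, "b": {"x", "y"}}) == {"x", "y"}
    with pytest.raises(ValueError):
        unique_union({})


def test_null_table_fdr_discoveries_are_rare():
    """On a structure-free table the fraction of FDR<0.01 calls stays at the
    nominal level (plus Monte-Carlo slack)."""
    rng = np.random.default_rng(55)
    n, m = 60, 300
    table = pd.DataFrame(
        rng.lognormal(0, 1, (n, m)),
        columns=[f"f{i}" for i in range(m)],
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    meta = pd.DataFrame({"sample_id": table.index, "group": ["case"] * 30 + ["control"] * 30})
    diff = differential_table(table, meta)
    assert (diff["fdr"] < 0.01).mean() <= 0.01 + 0.01
    assert len(select_significant_msps(table, meta)) == 0
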