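"""Carriage, sharing proportions, rank-sum test and BH adjustment."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from mitolineage import (
    SharingConfig,
    bh_adjust,
    cluster_variant_carriage,
    compute_sharing,
    one_vs_rest_test,
    wilcoxon_rank_sum,
)
from mitolineage.experiments import trace_once
from mitolineage.sharing import SharingResult, carriage_sets


def make_carriage(entries):
    """entries: (donor, tissue, cluster, lineage, variant, n_cells)."""
    return pd.DataFrame(
        entries,
        columns=["donor_id", "tissue", "cluster", "lineage", "variant_id", "n_cells"],
    )


def test_carriage_threshold(default_run):
    """A cluster carries a variant iff >= min_cells_per_side cells detect it."""
    ivs, annotations = default_run["ivs"], default_run["annotations"]
    for m in (2, 3):
        carriage = cluster_variant_carriage(ivs, annotations, SharingConfig(min_cells_per_side=m))
        assert (carriage["n_cells"] >= m).all()
    c2 = cluster_variant_carriage(ivs, annotations, SharingConfig(min_cells_per_side=2))
    c3 = cluster_variant_carriage(ivs, annotations, SharingConfig(min_cells_per_side=3))
    assert len(c3) < len(c2)  # some variants detected in exactly 2 cells


def test_precursor_cluster_carries_its_clone_variants(tiny_clone_config):
    """In a noise-free, high-coverage simulation the skin precursor cluster
    carries exactly the informative variants of its clones."""
    cfg = replace(tiny_clone_config, fixed_heteroplasmy=0.6,
                  coverage_model=(100.0, 20.0))
    run = trace_once(cfg, clusters=[])
    gt, annotations = run["ground_truth"], run["annotations"]
    carriage = run["carriage"]
    sets = carriage_sets(carriage)
    carried = sets[("donor1", "skin", "pre")]
    skin_pre_cells = annotations[
        (annotations["tissue"] == "skin") & (annotations["cluster"] == "pre")
    ]
    truth = set()
    for clone in set(skin_pre_cells["clone"]):
        truth |= set(gt.variants_of_clone[clone])
    informative_truth = truth & set(run["ivs"].variants["donor1"])
    assert carried == informative_truth


def test_sharing_set_arithmetic():
    carriage = make_carriage(
        [
            ("d1", "synovium", "syn", "myeloid", v, 3)
            for v in ("v1", "v2", "v3")
        ]
        + [("d1", "skin", "sk", "myeloid", v, 3) for v in ("v2", "v3", "v9")]
    )
    res = compute_sharing(carriage, SharingConfig())
    row = res.table.iloc[0]
    assert row["shared_variants"] == frozenset({"v2", "v3"})
    assert row["proportion"] == pytest.approx(2 / 3)
    # disjoint sets -> zero
    carriage2 = make_carriage(
        [("d1", "synovium", "syn", "myeloid", "a", 3),
         ("d1", "skin", "sk", "myeloid", "b", 3)]
    )
    row2 = compute_sharing(carriage2, SharingConfig()).table.iloc[0]
    assert row2["shared_count"] == 0 and row2["proportion"] == 0.0


def test_lineage_matching_restricts_skin_union():
    carriage = make_carriage(
        [
            ("d1", "synovium", "syn", "myeloid", "v1", 3),
            ("d1", "skin", "skT", "T", "v1", 3),
        ]
    )
    matched = compute_sharing(carriage, SharingConfig(lineage_matched=True)).table
    pooled = compute_sharing(carriage, SharingConfig(lineage_matched=False)).table
    assert matched.iloc[0]["shared_count"] == 0
    assert pooled.iloc[0]["shared_count"] == 1


def test_donor_without_skin_flagged():
    carriage = make_carriage([("d1", "synovium", "syn", "myeloid", "v1", 3)])
    with pytest.warns(UserWarning, match="lacks skin"):
        res = compute_sharing(carriage, SharingConfig())
    assert not res.table.iloc[0]["computable"]


def test_forced_migration_proportions(tiny_clone_config):
    """migration_fraction=1 in a noise-free limit: the landing cluster's
    proportion is 1, non-migratory controls stay at 0."""
    cfg = replace(
        tiny_clone_config,
        migration_fraction=1.0,
        fixed_heteroplasmy=0.6,
        differentiation_retention=1.0,
        coverage_model=(100.0, 20.0),
    )
    run = trace_once(cfg, clusters=[])
    tab = run["sharing"].table.set_index("cluster")
    assert tab.loc["pre", "proportion"] == 1.0
    assert tab.loc["syn T", "proportion"] == 0.0


def test_sharing_subset_invariant(default_run):
    tab = default_run["sharing"].table
    carriage = default_run["carriage"]
    sets = carriage_sets(carriage)
    for _, row in tab.iterrows():
        carried = sets.get((row["donor_id"], "synovium", row["cluster"]), frozenset())
        assert row["shared_variants"] <= carried
        assert row["shared_count"] <= row["n_carried"]


# -- Wilcoxon rank sum ---------------------------------------------------------


def enumeration_p(x, y):
    """Independent oracle: full enumeration over subsets of midranks."""
    x, y = list(x), list(y)
    nx = len(x)
    ranks = scipy.stats.rankdata(x + y)
    obs = ranks[:nx].sum()
    mean = nx * (len(ranks) + 1) / 2
    hits = total = 0
    for subset in itertools.combinations(range(len(ranks)), nx):
        s = ranks[list(subset)].sum()
        total += 1
        hits += abs(s - mean) >= abs(obs - mean) - 1e-9
    return hits / total


def test_wilcoxon_worked_examples():
    u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1)
    _, p = wilcoxon_rank_sum([1, 2], [1, 2])
    assert p == 1.0
    _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5])
    assert p == 1.0


@pytest.mark.parametrize("seed", range(12))
def test_exact_matches_enumeration(seed):
    """Tie-aware exact p equals full enumeration for n_x + n_y <= 10."""
    rng = np.random.default_rng(seed)
    nx = int(rng.integers(1, 6))
    ny = int(rng.integers(1, 11 - nx))
    vals = rng.integers(0, 4, size=nx + ny).astype(float)  # heavy ties
    x, y = vals[:nx], vals[nx:]
    _, p = wilcoxon_rank_sum(x, y, mode="exact")
    assert p == pytest.approx(enumeration_p(x, y))
    xc = rng.normal(size=nx)
    yc = rng.normal(size=ny)
    _, p = wilcoxon_rank_sum(xc, yc, mode="exact")
    assert p == pytest.approx(enumeration_p(xc, yc))


def test_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        u, p = wilcoxon_rank_sum(x, y, mode="exact")
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# -- Benjamini-Hochberg --------------------------------------------------------


def test_bh_worked_examples():
    assert bh_adjust([0.03]).tolist() == [0.03]
    out = bh_adjust([0.005, 0.01, 0.03, 0.04])
    assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])
    assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
@settings(deadline=None, max_examples=100)
def test_bh_properties(pvals):
    """Adjusted >= raw, capped at 1, order-preserving, matches statsmodels."""
    adj = bh_adjust(pvals)
    p = np.asarray(pvals)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0).all()
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(adj[order]) >= -1e-12).all()
    from statsmodels.stats.multitest import multipletests

    _, ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(adj, ref)


# -- one-vs-rest ---------------------------------------------------------------


def ovr_result(values_by_group):
    rows = []
    for d_i in range(len(next(iter(values_by_group.values())))):
        for g, vals in values_by_group.items():
            rows.append((f"d{d_i}", g, "myeloid", 1, frozenset(), 0, vals[d_i], True))
    table = pd.DataFrame(
        rows,
        columns=["donor_id", "cluster", "lineage", "n_carried", "shared_variants",
                 "shared_count", "proportion", "computable"],
    )
    return SharingResult(table=table, donor_summary=pd.DataFrame(), config=SharingConfig())


def test_identical_groups_give_p_one():
    res = ovr_result({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]})
    out = one_vs_rest_test(res)
    assert (out["p"] == 1.0).all()
    assert len(out) == 2


def test_dominating_group_attains_minimal_p():
    res = ovr_result(
        {"a": [0.9, 0.8, 0.95], "b": [0.1, 0.2, 0.15], "c": [0.3, 0.25, 0.2]}
    )
    out = one_vs_rest_test(res).set_index("group")
    assert len(out) == 3  # family size equals number of groups
    assert out.loc["a", "p"] == out["p"].min()
    assert out.loc["a", "direction"] == "higher"
    assert (out["p_adj"] >= out["p"] - 1e-12).all()


def test_power_maximal_median_sharing(recovery_stats):
    """At migration >= 0.3 and coverage >= 20, the landing precursor shows the
    maximal median sharing proportion in >= 90% of replicates."""
    assert recovery_stats["max_median_sharing_fraction"] >= 0.90
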