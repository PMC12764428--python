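"""Preprocessing, neighbor graphs, permutation interaction tests, distances."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from mitolineage import (
    SpatialCellMap,
    SpatialSimConfig,
    analyze_sample,
    arcsinh_zscore,
    build_neighbor_graph,
    interacting_proportion,
    interaction_test,
    nn_distance,
    simulate_spatial_tissue,
    summarize_interactions,
)
from mitolineage.spatial import SampleInteractions


def cell_map(coords, labels, sample_id="s"):
    return SpatialCellMap(
        sample_id=sample_id,
        cells=pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(len(labels))],
                "x": [c[0] for c in coords],
                "y": [c[1] for c in coords],
                "label": labels,
            }
        ),
    )


# -- arcsinh + z-score ---------------------------------------------------------


def test_arcsinh_closed_forms():
    x = np.array([[0.0], [1.0]])
    t = np.arcsinh(x / 1.0)
    assert t[0, 0] == 0.0
    assert t[1, 0] == pytest.approx(math.log(1 + math.sqrt(2)))


def test_zscore_normalisation_identity():
    rng = np.random.default_rng(0)
    x = rng.gamma(2.0, 5.0, size=(200, 4))
    z = arcsinh_zscore(x, cofactor=1.0)
    assert np.abs(z.mean(axis=0)).max() < 1e-9
    assert np.allclose(z.std(axis=0), 1.0)


def test_constant_marker_warns_and_zeroes():
    x = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.warns(UserWarning, match="constant"):
        z = arcsinh_zscore(x)
    assert (z[:, 0] == 0).all()
    df = pd.DataFrame(x, columns=["m1", "m2"])
    with pytest.warns(UserWarning):
        zf = arcsinh_zscore(df)
    assert isinstance(zf, pd.DataFrame) and list(zf.columns) == ["m1", "m2"]
    with pytest.raises(ValueError):
        arcsinh_zscore(x, cofactor=0)


# -- neighbor graph ------------------------------------------------------------


def test_radius_rule_inclusive_at_boundary():
    m = cell_map([(0, 0), (30, 0), (0, 40), (50, 0)], list("AAAA"))
    g = build_neighbor_graph(m, radius=40.0)
    adj = g.adjacency.toarray()
    assert adj[0, 1] == 1  # 30 µm apart
    assert adj[0, 2] == 1  # exactly 40 µm: inclusive
    assert adj[0, 3] == 0  # 50 µm apart
    assert (adj == adj.T).all()
    assert np.trace(adj) == 0  # no self-edges


def test_graph_invariant_under_relabeling():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 200, size=(40, 2))
    m1 = cell_map(coords, ["A"] * 20 + ["B"] * 20)
    m2 = cell_map(coords, ["B"] * 20 + ["A"] * 20)
    g1 = build_neighbor_graph(m1, 40.0)
    g2 = build_neighbor_graph(m2, 40.0)
    assert (g1.adjacency != g2.adjacency).nnz == 0


# -- interaction test ----------------------------------------------------------


def exact_interaction_p(adj, labels, a, b):
    """Oracle: enumerate all distinct labelings of the sample."""
    labels = list(labels)
    n = len(labels)
    n_a = labels.count(a)
    deg_total = adj.sum()
    if a == b:
        expected = deg_total * (n_a - 1) / (n * (n - 1))
    else:
        expected = deg_total * labels.count(b) / (n * (n - 1))

    def stat(lab):
        ia = np.array([l == a for l in lab], float)
        ib = np.array([l == b for l in lab], float)
        return float(ia @ adj @ ib) / ia.sum()

    obs_dev = abs(stat(labels) - expected)
    seen = set(permutations(labels))
    hits = sum(abs(stat(lab) - expected) >= obs_dev - 1e-9 for lab in seen)
    return hits / len(seen), expected


def test_single_label_pair_invariant_p_one():
    m = cell_map([(0, 0), (10, 0), (20, 0)], list("AAA"))
    g = build_neighbor_graph(m, 15.0)
    (res,) = interaction_test(g, m.cells["label"], pairs=[("A", "A")],
                              n_permutations=50, seed=0)
    assert res.p == 1.0
    assert res.classification == "ns"


def test_path_graph_matches_enumeration_oracle():
    """Path A-B-B-A: permutation p converges to the exact enumerated p."""
    m = cell_map([(0, 0), (10, 0), (20, 0), (30, 0)], list("ABBA"))
    g = build_neighbor_graph(m, 15.0)
    labels = m.cells["label"].to_numpy()
    adj = g.adjacency.toarray().astype(float)
    for pair in [("A", "B"), ("B", "A"), ("A", "A")]:
        exact, expected = exact_interaction_p(adj, labels, *pair)
        (res,) = interaction_test(g, labels, pairs=[pair], n_permutations=20000, seed=1)
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / 20000)
        assert res.null_mean == pytest.approx(expected)
        assert abs(res.p - exact) <= 3 * se + 2 / 20001


def test_random_eight_cell_fixtures_match_enumeration():
    rng = np.random.default_rng(5)
    for trial in range(3):
        coords = rng.uniform(0, 100, size=(8, 2))
        labels = np.array(list("AABBBABA"))
        m = cell_map(coords, labels)
        g = build_neighbor_graph(m, 45.0)
        adj = g.adjacency.toarray().astype(float)
        exact, _ = exact_interaction_p(adj, labels, "A", "B")
        (res,) = interaction_test(g, labels, pairs=[("A", "B")],
                                  n_permutations=100_000, seed=trial)
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / 100_000)
        assert abs(res.p - exact) <= 3 * se + 2 / 100_001


def test_p_lower_bound_and_single_permutation():
    m = cell_map([(0, 0), (5, 0), (100, 100), (200, 200)], list("ABAB"))
    g = build_neighbor_graph(m, 40.0)
    for n_perm in (1, 7, 99):
        (res,) = interaction_test(g, m.cells["label"], pairs=[("A", "B")],
                                  n_permutations=n_perm, seed=0)
        assert res.p >= 1.0 / (n_perm + 1)
        assert res.p <= 1.0


def test_absent_type_skipped_with_warning():
    m = cell_map([(0, 0), (10, 0)], list("AA"))
    g = build_neighbor_graph(m, 40.0)
    with pytest.warns(UserWarning, match="absent"):
        out = interaction_test(g, m.cells["label"], pairs=[("A", "Z")], n_permutations=9)
    assert out == []


def test_attraction_detected_in_paired_layouts():
    """Fully paired layouts at 20 µm are classified as attraction in >= 95%
    of replicate simulations."""
    hits = 0
    n = 100
    for r in range(n):
        cfg = SpatialSimConfig(
            types=(("A", 40), ("B", 40), ("C", 60)),
            attraction_pairs=(("A", "B", 1.0, 20.0),),
            seed=1000 + r,
        )
        (m,) = simulate_spatial_tissue(cfg)
        g = build_neighbor_graph(m, 40.0)
        (res,) = interaction_test(g, m.cells["label"], pairs=[("A", "B")],
                                  n_permutations=199, seed=r)
        hits += res.classification == "attraction"
    assert hits / n >= 0.95


def test_fully_paired_interacting_proportion_is_one():
    cfg = SpatialSimConfig(
        types=(("A", 30), ("B", 30)),
        attraction_pairs=(("A", "B", 1.0, 20.0),),
        seed=3,
    )
    (m,) = simulate_spatial_tissue(cfg)
    g = build_neighbor_graph(m, 40.0)
    assert interacting_proportion(g, m.cells["label"], "A", "B") == 1.0


def test_interacting_proportion_counts():
    # 3 A cells, 2 with a B neighbor within 40 µm
    m = cell_map(
        [(0, 0), (100, 0), (300, 300), (10, 0), (110, 0)],
        ["A", "A", "A", "B", "B"],
    )
    g = build_neighbor_graph(m, 40.0)
    labels = m.cells["label"]
    assert interacting_proportion(g, labels, "A", "B") == pytest.approx(2 / 3)
    assert interacting_proportion(g, labels, "A", "Z") == 0.0
    assert math.isnan(interacting_proportion(g, labels, "Z", "A"))


# -- nearest-neighbor distances -------------------------------------------------


def test_nn_distance_examples():
    m = cell_map([(0, 0), (3, 4)], ["A", "B"])
    d, med = nn_distance(m, "A", "B")
    assert d.tolist() == [5.0] and med == 5.0
    m2 = cell_map([(1, 1), (1, 1)], ["A", "B"])
    _, med2 = nn_distance(m2, "A", "B")
    assert med2 == 0.0
    _, med3 = nn_distance(m2, "A", "Z")
    assert math.isnan(med3)


def test_nn_distance_matches_brute_force():
    rng = np.random.default_rng(8)
    coords = rng.uniform(0, 500, size=(25, 2))
    labels = np.array(["A"] * 10 + ["B"] * 15)
    m = cell_map(coords, labels)
    d, _ = nn_distance(m, "A", "B")
    a = coords[:10]
    b = coords[10:]
    brute = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min(axis=1)
    assert np.allclose(np.sort(d), np.sort(brute))


# -- cross-sample summary --------------------------------------------------------


def test_summary_counts_significant_fraction():
    def sample(sid, cls):
        from mitolineage import InteractionResult

        return SampleInteractions(
            sample_id=sid,
            results=[
                InteractionResult("A", "B", 1.0, 0.5, 0.01 if cls != "ns" else 0.8,
                                  cls, 99, 0)
            ],
            proportions={("A", "B"): 0.4},
        )

    samples = [sample(f"s{i}", "attraction") for i in range(3)] + [
        sample("s3", "ns"),
        sample("s4", "avoidance"),
    ]
    out = summarize_interactions(samples).iloc[0]
    assert out["n_samples"] == 5
    assert out["significant_fraction"] == pytest.approx(0.8)
    assert out["attraction_fraction"] == pytest.approx(0.6)
    assert out["avoidance_fraction"] == pytest.approx(0.2)
    assert "s3:ns" in out["per_sample_classification"]
    assert out["median_interacting_proportion"] == pytest.approx(0.4)
    single = summarize_interactions(samples[:1]).iloc[0]
    assert single["significant_fraction"] == 1.0
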