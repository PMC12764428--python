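"""Graph-based precursor ranking of synovial clusters from shared variants.

Synovial clusters are the nodes of an undirected graph whose edge weights
count the informative variants carried by both endpoints.  In
``exclude_skin`` mode only variants carried by *no* skin cluster enter the
edge weights and scores, isolating purely within-joint sharing.  Each
cluster's precursor score is the number of its (mode-filtered) variants
shared with at least one other synovial cluster plus, in ``include_skin``
mode, its skin-shared count; the cluster containing most of the joint's
between-cluster sharing, first in every donor's ranking, is the candidate
earliest precursor.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

MODES = ("include_skin", "exclude_skin")


@dataclass
class LineageGraph:
    """Per-donor cluster-sharing graphs plus a donor-median consensus."""

    per_donor: dict[str, nx.Graph]
    consensus: nx.Graph
    mode: str


def _donor_graph(
    syn_sets: dict[str, frozenset[str]],
    skin_union_all: frozenset[str],
    skin_union_by_lineage: dict[str, frozenset[str]],
    lineage_of: dict[str, str],
    support: dict[str, int],
    mode: str,
    lineage_matched: bool,
) -> nx.Graph:
    g = nx.Graph(mode=mode)
    for c, carried in syn_sets.items():
        scoring = carried - skin_union_all if mode == "exclude_skin" else carried
        skin_ref = (
            skin_union_by_lineage.get(lineage_of.get(c, ""), frozenset())
            if lineage_matched
            else skin_union_all
        )
        g.add_node(
            c,
            carried=carried,
            scoring=scoring,
            skin_shared_count=len(carried & skin_ref),
            support=support.get(c, 0),
            lineage=lineage_of.get(c, ""),
        )
    nodes = sorted(g.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            w = len(g.nodes[a]["scoring"] & g.nodes[b]["scoring"])
            g.add_edge(a, b, weight=w)
    return g


def build_lineage_graph(
    carriage: pd.DataFrame,
    mode: str = "include_skin",
    lineage_matched: bool = True,
    synovial_tissue: str = "synovium",
    skin_tissue: str = "skin",
    clusters: list[str] | None = None,
) -> LineageGraph:
    """Build per-donor sharing graphs from a carriage table.

    ``clusters`` restricts the node set (e.g. to the myeloid compartment);
    by default every synovial cluster present in ``carriage`` is a node.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    graphs: dict[str, nx.Graph] = {}
    for donor, sub in carriage.groupby("donor_id"):
        syn = sub[sub["tissue"] == synovial_tissue]
        if clusters is not None:
            syn = syn[syn["cluster"].isin(clusters)]
        skin = sub[sub["tissue"] == skin_tissue]
        syn_sets = {
            c: frozenset(rows["variant_id"]) for c, rows in syn.groupby("cluster")
        }
        if clusters is not None:
            for c in clusters:
                syn_sets.setdefault(c, frozenset())
        support = syn.groupby("cluster")["n_cells"].sum().astype(int).to_dict()
        lineage_of = dict(zip(syn["cluster"], syn["lineage"]))
        skin_union_all = frozenset(skin["variant_id"])
        skin_by_lin = {
            lin: frozenset(rows["variant_id"])
            for lin, rows in skin.groupby("lineage")
        }
        graphs[donor] = _donor_graph(
            syn_sets, skin_union_all, skin_by_lin, lineage_of, support, mode,
            lineage_matched,
        )

    consensus = nx.Graph(mode=mode)
    all_nodes = sorted({c for g in graphs.values() for c in g.nodes})
    for c in all_nodes:
        skin_counts = [
            g.nodes[c]["skin_shared_count"] for g in graphs.values() if c in g
        ]
        consensus.add_node(c, skin_shared_count=float(np.median(skin_counts)))
    for i, a in enumerate(all_nodes):
        for b in all_nodes[i + 1 :]:
            ws = [
                g.edges[a, b]["weight"]
                for g in graphs.values()
                if g.has_edge(a, b)
            ]
            consensus.add_edge(a, b, weight=float(np.median(ws)) if ws else 0.0)
    return LineageGraph(per_donor=graphs, consensus=consensus, mode=mode)


@dataclass
class PrecursorRanking:
    """Ordered precursor candidates, per donor and as a median-rank consensus."""

    per_donor: dict[str, pd.DataFrame]
    consensus: pd.DataFrame  # cluster, median_rank, median_score, rank
    mode: str

    def top(self) -> str | None:
        if not len(self.consensus):
            return None
        return str(self.consensus.iloc[0]["cluster"])

    def rank1_tied(self) -> tuple[str, ...]:
        """Clusters tied for rank 1 on (score, containment, support) in consensus.

        Ties are decided before the final lexicographic tie-break, so equally
        scored clusters are all reported.
        """
        if not len(self.consensus):
            return ()
        key = ["median_rank", "median_score"]
        best = self.consensus.iloc[0][key]
        tied = self.consensus[(self.consensus[key] == best).all(axis=1)]
        return tuple(sorted(tied["cluster"]))


def _rank_one_donor(g: nx.Graph, mode: str) -> pd.DataFrame:
    nodes = sorted(g.nodes)
    shared_pool: set[str] = set()
    scoring = {c: g.nodes[c]["scoring"] for c in nodes}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            shared_pool |= scoring[a] & scoring[b]
    rows = []
    for c in nodes:
        others = frozenset().union(*(scoring[b] for b in nodes if b != c)) if len(nodes) > 1 else frozenset()
        within = len(scoring[c] & others)
        skin_shared = int(g.nodes[c]["skin_shared_count"])
        score = within + (skin_shared if mode == "include_skin" else 0)
        containment = (
            len(scoring[c] & shared_pool) / len(shared_pool) if shared_pool else np.nan
        )
        rows.append(
            (c, score, within, skin_shared, containment, int(g.nodes[c]["support"]))
        )
    df = pd.DataFrame(
        rows,
        columns=["cluster", "precursor_score", "within_joint_shared",
                 "skin_shared_count", "containment_fraction", "support"],
    )
    df = df.sort_values(
        by=["precursor_score", "containment_fraction", "support", "cluster"],
        ascending=[False, False, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    # ties on the substantive keys share the best (minimum) rank so that
    # downstream tallies can count them fractionally; the lexicographic
    # ordering above stays purely presentational
    keys = list(
        zip(df["precursor_score"], df["containment_fraction"].fillna(-1.0), df["support"])
    )
    df["rank"] = [1 + sum(other > k for other in keys) for k in keys]
    return df


def rank_precursors(graph: LineageGraph) -> PrecursorRanking:
    """Rank clusters by precursor score; consensus orders by median rank.

    Ties are broken by containment fraction, then total detecting-cell
    support, then cluster name; the tie-break order is recorded in the
    per-donor tables.
    """
    per_donor = {d: _rank_one_donor(g, graph.mode) for d, g in graph.per_donor.items()}
    if not per_donor:
        consensus = pd.DataFrame(columns=["cluster", "median_rank", "median_score", "rank"])
        return PrecursorRanking(per_donor, consensus, graph.mode)
    stacked = pd.concat(
        [df.assign(donor_id=d) for d, df in per_donor.items()], ignore_index=True
    )
    consensus = (
        stacked.groupby("cluster")
        .agg(median_rank=("rank", "median"), median_score=("precursor_score", "median"))
        .reset_index()
        .sort_values(
            by=["median_rank", "median_score", "cluster"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )
    consensus["rank"] = np.arange(1, len(consensus) + 1)
    return PrecursorRanking(per_donor, consensus, graph.mode)


def containment_check(
    carriage: pd.DataFrame,
    precursor: str,
    synovial_tissue: str = "synovium",
    clusters: list[str] | None = None,
) -> dict[str, float]:
    """Fraction of between-cluster shared variants explainable via the precursor.

    For each donor, collect the variants carried by at least two synovial
    clusters and report the fraction of them also carried by the precursor
    cluster.  1.0 means all joint sharing could derive from the precursor,
    ruling out other migratory sources; NaN flags donors with no
    between-cluster sharing (not computable).
    """
    out: dict[str, float] = {}
    for donor, sub in carriage.groupby("donor_id"):
        syn = sub[sub["tissue"] == synovial_tissue]
        if clusters is not None:
            syn = syn[syn["cluster"].isin(clusters)]
        sets = {c: frozenset(r["variant_id"]) for c, r in syn.groupby("cluster")}
        pre = sets.get(precursor, frozenset())
        names = sorted(sets)
        shared: set[str] = set()
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                shared |= sets[a] & sets[b]
        out[donor] = len(shared & pre) / len(shared) if shared else np.nan
    return out


def export_edge_list(graph: LineageGraph, path) -> None:
    rows = []
    for donor, g in graph.per_donor.items():
        for a, b, data in g.edges(data=True):
            rows.append((donor, a, b, data["weight"]))
    pd.DataFrame(rows, columns=["donor_id", "cluster_a", "cluster_b", "weight"]).to_csv(
        path, index=False
    )


def export_graphml(graph: LineageGraph, path) -> None:
    g = nx.Graph()
    for c, data in graph.consensus.nodes(data=True):
        g.add_node(c, skin_shared_count=float(data["skin_shared_count"]))
    for a, b, data in graph.consensus.edges(data=True):
        g.add_edge(a, b, weight=float(data["weight"]))
    nx.write_graphml(g, path)
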