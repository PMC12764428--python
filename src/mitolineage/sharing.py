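"""Cross-tissue shared-variant statistics and cluster enrichment tests.

A cluster *carries* a variant when at least ``min_cells_per_side`` of its
cells detect it.  For each synovial cluster the shared set is the
intersection of its carried variants with the union of carried variants of
the (lineage-matched) skin clusters of the same donor, and the sharing
proportion divides the shared count by the cluster's carried-variant count
(or, optionally, by the donor's total informative count).  Cluster-wise
enrichment is tested with a one-versus-rest two-sided Wilcoxon rank-sum
test followed by Benjamini-Hochberg correction across the family of
clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .variants import InformativeVariantSet


@dataclass(frozen=True)
class SharingConfig:
    """Carriage rule and comparison scope for sharing statistics."""

    min_cells_per_side: int = 2
    lineage_matched: bool = True
    #: "carried" divides shared counts by the synovial cluster's carried
    #: variants; "donor_informative" divides by the donor's informative total.
    denominator: str = "carried"

    def __post_init__(self) -> None:
        if self.min_cells_per_side < 1:
            raise ValueError("min_cells_per_side must be >= 1")
        if self.denominator not in ("carried", "donor_informative"):
            raise ValueError("denominator must be 'carried' or 'donor_informative'")


def cluster_variant_carriage(
    ivs: InformativeVariantSet,
    annotations: pd.DataFrame,
    config: SharingConfig,
) -> pd.DataFrame:
    """Tidy carriage table: one row per carried (donor, tissue, cluster, variant).

    ``n_cells`` is the number of cells of the cluster detecting the variant;
    rows with ``n_cells < min_cells_per_side`` are dropped.  Clusters without
    any carried variant simply contribute no rows (their carried set is
    empty).
    """
    cols = ["donor_id", "tissue", "cluster", "lineage", "variant_id", "n_cells"]
    if not len(ivs.detection):
        return pd.DataFrame(columns=cols)
    det = ivs.detection
    det = det.assign(
        donor_id=det["donor_id"].astype(str),
        variant_id=det["variant_id"].astype(str),
        cell_id=det["cell_id"].astype(str),
    )
    det = det.merge(
        annotations[["cell_id", "donor_id", "tissue", "cluster", "lineage"]],
        on=["cell_id", "donor_id"],
        how="left",
    )
    if det["cluster"].isna().any():
        missing = det.loc[det["cluster"].isna(), "cell_id"].unique()
        warnings.warn(
            f"{len(missing)} detected cells missing from annotations were dropped",
            stacklevel=2,
        )
        det = det.dropna(subset=["cluster"])
    carriage = (
        det.groupby(["donor_id", "tissue", "cluster", "lineage", "variant_id"])
        .size()
        .rename("n_cells")
        .reset_index()
    )
    return carriage[carriage["n_cells"] >= config.min_cells_per_side].reset_index(drop=True)


def carriage_sets(carriage: pd.DataFrame) -> dict[tuple[str, str, str], frozenset[str]]:
    """Map (donor, tissue, cluster) -> carried variant set."""
    out: dict[tuple[str, str, str], frozenset[str]] = {}
    for (d, t, c), sub in carriage.groupby(["donor_id", "tissue", "cluster"]):
        out[(d, t, c)] = frozenset(sub["variant_id"])
    return out


@dataclass
class SharingResult:
    """Per-(donor, synovial cluster) sharing table plus per-donor summaries."""

    table: pd.DataFrame  # donor_id, cluster, lineage, n_carried, shared_variants,
    #                      shared_count, proportion, computable
    donor_summary: pd.DataFrame  # donor_id, median_shared, iqr_shared
    config: SharingConfig


def compute_sharing(
    carriage: pd.DataFrame,
    config: SharingConfig,
    annotations: pd.DataFrame | None = None,
    ivs: InformativeVariantSet | None = None,
    synovial_tissue: str = "synovium",
    skin_tissue: str = "skin",
) -> SharingResult:
    """Shared-variant counts and proportions per synovial cluster.

    When ``annotations`` is given, synovial clusters that carry no variant
    still appear with zero counts; otherwise the cluster universe is the set
    of clusters present in ``carriage``.
    """
    sets = carriage_sets(carriage)
    skin_by_donor: dict[str, set[str]] = {}
    skin_by_donor_lineage: dict[tuple[str, str], set[str]] = {}
    lineage_of: dict[tuple[str, str], str] = {}
    for (d, t, c), sub in carriage.groupby(["donor_id", "tissue", "cluster"]):
        lineage_of[(d, c)] = sub["lineage"].iloc[0]
        if t == skin_tissue:
            vs = set(sub["variant_id"])
            skin_by_donor.setdefault(d, set()).update(vs)
            lin = sub["lineage"].iloc[0]
            skin_by_donor_lineage.setdefault((d, lin), set()).update(vs)

    # cluster universe and donors-with-skin bookkeeping
    if annotations is not None:
        uni = (
            annotations[annotations["tissue"] == synovial_tissue][
                ["donor_id", "cluster", "lineage"]
            ]
            .drop_duplicates()
            .itertuples(index=False)
        )
        universe = [(r.donor_id, r.cluster, r.lineage) for r in uni]
        donors_with_skin = set(
            annotations.loc[annotations["tissue"] == skin_tissue, "donor_id"]
        )
    else:
        universe = [
            (d, c, lineage_of[(d, c)])
            for (d, t, c) in sets
            if t == synovial_tissue
        ]
        donors_with_skin = set(skin_by_donor)

    informative_totals = (
        {d: len(v) for d, v in ivs.variants.items()} if ivs is not None else {}
    )

    rows = []
    for d, cluster, lineage in sorted(universe):
        carried = sets.get((d, synovial_tissue, cluster), frozenset())
        computable = d in donors_with_skin
        if not computable:
            warnings.warn(f"donor {d!r} lacks skin cells; sharing not computable", stacklevel=2)
            shared, prop = frozenset(), np.nan
        else:
            skin = (
                skin_by_donor_lineage.get((d, lineage), set())
                if config.lineage_matched
                else skin_by_donor.get(d, set())
            )
            shared = frozenset(carried & skin)
            if config.denominator == "carried":
                denom = len(carried)
            else:
                denom = informative_totals.get(d, 0)
            prop = len(shared) / denom if denom else 0.0
        rows.append(
            (d, cluster, lineage, len(carried), shared, len(shared), prop, computable)
        )
    table = pd.DataFrame(
        rows,
        columns=["donor_id", "cluster", "lineage", "n_carried", "shared_variants",
                 "shared_count", "proportion", "computable"],
    )
    summ = []
    for d, sub in table[table["computable"]].groupby("donor_id"):
        counts = sub["shared_count"].to_numpy(dtype=float)
        q75, q25 = np.percentile(counts, [75, 25]) if len(counts) else (np.nan, np.nan)
        summ.append((d, float(np.median(counts)), float(q75 - q25)))
    donor_summary = pd.DataFrame(summ, columns=["donor_id", "median_shared", "iqr_shared"])
    return SharingResult(table=table, donor_summary=donor_summary, config=config)


# -- rank-sum machinery ------------------------------------------------------


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` where ``U`` is the Mann-Whitney statistic of ``x``.
    ``mode='exact'`` enumerates the tie-aware permutation distribution of
    the rank sum (midranks; the two-sided p counts rank sums at least as
    far from the null mean as observed).  ``mode='normal'`` uses the normal
    approximation with tie and continuity corrections.  ``mode='auto'``
    picks the exact branch for n_x + n_y <= 12.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    nx, ny = len(x), len(y)
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    rx = float(ranks[:nx].sum())
    u = rx - nx * (nx + 1) / 2.0
    if np.all(combined == combined[0]):
        return u, 1.0
    exact = mode == "exact" or (mode == "auto" and n <= 12)
    if exact:
        if n > 30:
            raise ValueError("exact mode limited to n_x + n_y <= 30")
        d = np.rint(2 * ranks).astype(np.int64)  # doubled midranks are integers
        total = int(d.sum())
        dp = np.zeros((nx + 1, total + 1))
        dp[0, 0] = 1.0
        for val in d:
            for k in range(nx, 0, -1):
                dp[k, val:] += dp[k - 1, : total + 1 - val]
        obs = int(np.rint(2 * rx))
        mean2 = nx * (n + 1)  # doubled null mean of the rank sum
        dev = abs(obs - mean2)
        s = np.arange(total + 1)
        tail = dp[nx, np.abs(s - mean2) >= dev - 1e-9].sum()
        return u, float(tail / comb(n, nx))
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(list(pvals), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, None, 1.0)
    return out


def one_vs_rest_test(
    result: SharingResult, level: str = "cluster", alpha: float = 0.05
) -> pd.DataFrame:
    """One-versus-rest two-sided rank-sum tests with BH correction.

    The statistical unit is the per-donor per-cluster sharing proportion;
    at ``level='lineage'`` the cluster values are pooled within lineages.
    Returns one row per group: ``group, n, n_rest, statistic, p, p_adj,
    direction, significant``.
    """
    if level not in ("cluster", "lineage"):
        raise ValueError("level must be 'cluster' or 'lineage'")
    df = result.table[result.table["computable"]]
    values = df["proportion"].to_numpy(dtype=float)
    groups = df[level].to_numpy()
    names = sorted(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("one-vs-rest requires at least two groups")
    rows = []
    for g in names:
        xs = values[groups == g]
        ys = values[groups != g]
        if len(xs) < 1:
            warnings.warn(f"group {g!r} has no values; skipped", stacklevel=2)
            continue
        # the exact tie-aware enumeration stays cheap at family sizes typical
        # for per-donor cluster values and avoids the normal approximation's
        # anti-conservatism at small n
        mode = "exact" if len(xs) + len(ys) <= 24 else "normal"
        u, p = wilcoxon_rank_sum(xs, ys, mode=mode)
        direction = (
            "higher"
            if np.median(xs) > np.median(ys)
            else "lower" if np.median(xs) < np.median(ys) else "equal"
        )
        rows.append((g, len(xs), len(ys), u, p, direction))
    out = pd.DataFrame(rows, columns=["group", "n", "n_rest", "statistic", "p", "direction"])
    out["p_adj"] = bh_adjust(out["p"])
    out["significant"] = out["p_adj"] < alpha
    return out.loc[:, ["group", "n", "n_rest", "statistic", "p", "p_adj", "direction",
                       "significant"]]


def export_sharing_csv(result: SharingResult, tests: pd.DataFrame | None, path) -> None:
    """Tidy CSV export (shared sets serialised as ';'-joined variant ids)."""
    tab = result.table.copy()
    tab["shared_variants"] = tab["shared_variants"].map(lambda s: ";".join(sorted(s)))
    if tests is not None:
        tab = tab.merge(
            tests[["group", "p", "p_adj"]].rename(columns={"group": "cluster"}),
            on="cluster",
            how="left",
        )
    tab.to_csv(path, index=False)
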