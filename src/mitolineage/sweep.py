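"""Threshold-robustness sweep: re-run filtering -> sharing -> ranking on a grid.

Each iteration re-applies a :class:`FilterConfig` drawn from the grid to a
fixed variant table, recomputes cluster carriage, skin-sharing and the
precursor ranking, and the summary reports how stable the qualitative
conclusions are: the fraction of iterations in which each lineage shows the
maximal skin-sharing, the fraction in which each cluster ranks first
(ties counted fractionally, 1/k to each of k tied clusters), and per-field
marginal sensitivities (how often the rank-1 cluster flips when one
threshold varies with the others held fixed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph import build_lineage_graph, rank_precursors
from .sharing import SharingConfig, cluster_variant_carriage, compute_sharing
from .variants import FilterConfig, VariantTable, call_informative_variants

#: Default candidate values per selection criterion.
DEFAULT_GRID_VALUES: dict[str, list] = {
    "min_coverage": [3, 5, 10],
    "min_vaf": [0.03, 0.05, 0.10],
    "min_cells_detected": [2, 3, 5],
    "max_detected_fraction": [0.3, 0.5, 0.7],
}


@dataclass(frozen=True)
class SweepGrid:
    """Candidate threshold values per :class:`FilterConfig` field."""

    values: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID_VALUES))
    cartesian: bool = True
    n_samples: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.values or any(len(v) == 0 for v in self.values.values()):
            raise ValueError("grid must list at least one value per swept field")
        unknown = set(self.values) - set(FilterConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown FilterConfig fields in grid: {sorted(unknown)}")
        if not self.cartesian and not self.n_samples:
            raise ValueError("sampled mode requires n_samples")

    def configs(self, base: FilterConfig) -> list[FilterConfig]:
        """All grid configurations, in deterministic order.

        Every configuration is validated through ``FilterConfig`` so listed
        values must satisfy the field invariants.
        """
        fields = list(self.values)
        combos = list(itertools.product(*(self.values[f] for f in fields)))
        if not self.cartesian:
            rng = np.random.default_rng(self.seed)
            idx = rng.choice(len(combos), size=min(self.n_samples, len(combos)),
                             replace=False)
            combos = [combos[i] for i in sorted(idx)]
        return [replace(base, **dict(zip(fields, c))) for c in combos]


@dataclass
class SweepIteration:
    config: FilterConfig
    degenerate: bool
    lineage_skin_counts: dict[str, float]
    max_sharing_lineages: tuple[str, ...]
    rank1_clusters: tuple[str, ...]
    ranking: pd.DataFrame  # consensus ranking table


@dataclass
class SweepResult:
    iterations: list[SweepIteration]
    grid: SweepGrid
    swept_fields: list[str]


def run_iteration(
    table: VariantTable,
    annotations: pd.DataFrame,
    filter_config: FilterConfig,
    sharing_config: SharingConfig,
    mode: str = "include_skin",
    clusters: list[str] | None = None,
) -> SweepIteration:
    """One filtering -> sharing -> ranking pass; replayable bit-identically."""
    ivs = call_informative_variants(table, annotations, filter_config)
    degenerate = all(len(v) == 0 for v in ivs.variants.values())
    if degenerate:
        return SweepIteration(filter_config, True, {}, (), (), pd.DataFrame())
    carriage = cluster_variant_carriage(ivs, annotations, sharing_config)
    sharing = compute_sharing(carriage, sharing_config, annotations=annotations, ivs=ivs)

    # per-lineage skin-shared counts: median across donors of the number of
    # distinct variants shared with skin by the lineage's synovial clusters
    tab = sharing.table[sharing.table["computable"]]
    lineage_counts: dict[str, float] = {}
    for lin, sub in tab.groupby("lineage"):
        per_donor = [
            len(frozenset().union(*rows["shared_variants"]))
            for _, rows in sub.groupby("donor_id")
        ]
        lineage_counts[lin] = float(np.median(per_donor)) if per_donor else 0.0
    if lineage_counts:
        mx = max(lineage_counts.values())
        max_lineages = tuple(sorted(l for l, v in lineage_counts.items() if v == mx))
    else:
        max_lineages = ()

    graph = build_lineage_graph(carriage, mode=mode, clusters=clusters,
                                lineage_matched=sharing_config.lineage_matched)
    ranking = rank_precursors(graph)
    return SweepIteration(
        config=filter_config,
        degenerate=False,
        lineage_skin_counts=lineage_counts,
        max_sharing_lineages=max_lineages,
        rank1_clusters=ranking.rank1_tied(),
        ranking=ranking.consensus,
    )


def run_sweep(
    table: VariantTable,
    annotations: pd.DataFrame,
    grid: SweepGrid,
    base_filter: FilterConfig | None = None,
    sharing_config: SharingConfig | None = None,
    mode: str = "include_skin",
    clusters: list[str] | None = None,
) -> SweepResult:
    """Run every grid configuration; iterations are independent and stored."""
    base = base_filter or FilterConfig()
    sharing_config = sharing_config or SharingConfig()
    iterations = [
        run_iteration(table, annotations, cfg, sharing_config, mode=mode,
                      clusters=clusters)
        for cfg in grid.configs(base)
    ]
    return SweepResult(iterations=iterations, grid=grid, swept_fields=list(grid.values))


def _fractional_tally(winners: list[tuple[str, ...]]) -> dict[str, float]:
    tally: dict[str, float] = {}
    for ws in winners:
        if not ws:
            continue
        for w in ws:
            tally[w] = tally.get(w, 0.0) + 1.0 / len(ws)
    n = len(winners)
    return {k: v / n for k, v in tally.items()} if n else {}


def summarize_sweep(result: SweepResult) -> dict:
    """Stability summary over the non-degenerate iterations.

    Returns a dict with ``rank1`` and ``lineage`` tidy tables, a
    ``sensitivity`` table of per-field rank-flip fractions, plus iteration
    counts.  Raises when every iteration is degenerate.
    """
    ok = [it for it in result.iterations if not it.degenerate]
    n_degenerate = len(result.iterations) - len(ok)
    if not ok:
        raise ValueError("all sweep iterations were degenerate (no informative variants)")

    rank1 = _fractional_tally([it.rank1_clusters for it in ok])
    lineage = _fractional_tally([it.max_sharing_lineages for it in ok])
    rank1_df = (
        pd.DataFrame(sorted(rank1.items()), columns=["cluster", "rank1_fraction"])
        .sort_values("rank1_fraction", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    lineage_df = (
        pd.DataFrame(sorted(lineage.items()), columns=["lineage", "max_sharing_fraction"])
        .sort_values("max_sharing_fraction", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )

    # marginal sensitivity: group iterations by the values of the other swept
    # fields; a group "flips" when its rank-1 winners are not all identical
    sens_rows = []
    fields = result.swept_fields
    for f in fields:
        groups: dict[tuple, list[tuple[str, ...]]] = {}
        for it in ok:
            key = tuple(getattr(it.config, g) for g in fields if g != f)
            groups.setdefault(key, []).append(it.rank1_clusters)
        multi = {k: v for k, v in groups.items() if len(v) > 1}
        if multi:
            flips = sum(1 for v in multi.values() if len(set(v)) > 1)
            sens_rows.append((f, flips / len(multi)))
        else:
            sens_rows.append((f, np.nan))
    sensitivity = pd.DataFrame(sens_rows, columns=["field", "rank_flip_fraction"])

    return {
        "rank1": rank1_df,
        "lineage": lineage_df,
        "sensitivity": sensitivity,
        "n_iterations": len(result.iterations),
        "n_degenerate": n_degenerate,
    }
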