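"""Synthetic clonal mitochondrial populations and spatial point patterns.

The clonal generator emulates the structure of a cross-tissue single-cell
mitochondrial genotyping study: each donor carries near-homoplasmic germline
haplogroup variants in every cell, donor-private heteroplasmic somatic clone
variants organised on a rooted clone tree, and a skin-resident precursor
population whose clones migrate into the synovium and seed downstream
myeloid clusters through a clonal bottleneck.  Observed counts pass through
a negative-binomial coverage model, binomial allele sampling and a uniform
base-error channel, so downstream filters face realistic noise.

The spatial generator produces labelled point patterns with controlled
pairwise attraction (a fraction of source cells receive a partner of the
target type within a fixed distance) and avoidance (exclusion radii), used
as ground-truthed fixtures for the neighborhood interaction tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tensor import BASES, MT_GENOME_LENGTH, AlleleCountTensor

#: True heteroplasmy assigned to germline haplogroup variants.  Deliberately
#: below 1 so that specificity filters, not an exact-1 shortcut, must remove
#: them.
GERMLINE_HETEROPLASMY = 0.98

ClusterSpec = Sequence[tuple[str, str, int]]

PRECURSOR = "CD2+MHC-II+CCR2+ precursors"

DEFAULT_CLUSTERS: dict[str, tuple[tuple[str, str, int], ...]] = {
    "skin": (
        (PRECURSOR, "myeloid", 80),
        ("skin T cells", "T", 60),
    ),
    "synovium": (
        (PRECURSOR, "myeloid", 60),
        ("MHC-II- lining macrophages", "myeloid", 60),
        ("HMOX1+ macrophages", "myeloid", 60),
        ("S100A12+ monocytes", "myeloid", 60),
        ("synovial T cells", "T", 60),
    ),
}

DEFAULT_DOWNSTREAM = (
    PRECURSOR,
    "MHC-II- lining macrophages",
    "HMOX1+ macrophages",
)


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class CloneSimConfig:
    """Generative parameters for a clonal cross-tissue population.

    ``clusters_per_tissue`` maps tissue -> sequence of
    ``(cluster_name, lineage, n_cells)``.  ``precursor_cluster`` names the
    skin cluster whose clones migrate; ``downstream_clusters`` are the
    synovial clusters seeded from it, the first of which is treated as the
    landing population (recent migrants) unless ``landing_cluster`` says
    otherwise.  ``coverage_model`` is ``(mean, dispersion)`` of a negative
    binomial with variance ``mean + mean**2 / dispersion``.
    """

    n_donors: int = 3
    mito_genome_length: int = MT_GENOME_LENGTH
    n_germline_variants_per_donor: int = 10
    n_clones: int = 8
    clone_tree_depth: int = 3
    somatic_variants_per_clone: int = 3
    heteroplasmy_distribution: tuple[float, float] = (2.0, 8.0)
    clusters_per_tissue: Mapping[str, ClusterSpec] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTERS)
    )
    precursor_cluster: str = PRECURSOR
    downstream_clusters: tuple[str, ...] = DEFAULT_DOWNSTREAM
    landing_cluster: str | None = None
    migration_fraction: float = 0.5
    bottleneck_fraction: float = 0.5
    nested_downstream: bool = True
    #: Resident (non-migrating) clone pools hold ``n_clones *
    #: resident_polyclonality`` clones: tissue-resident compartments are
    #: polyclonal relative to the expanded migrating precursor clones.
    resident_polyclonality: int = 2
    #: Heteroplasmy retention in migrant-derived cells of differentiated
    #: (non-landing) downstream clusters.  Proliferation during
    #: differentiation lets heteroplasmy drift downward (vegetative
    #: segregation), so recent migrants in the landing cluster show the
    #: strongest variant signal.
    differentiation_retention: float = 0.6
    #: Synovial clusters of independent (e.g. blood) origin: their cells draw
    #: from a cluster-private clone pool and share no clones with either the
    #: migrating precursor or the synovium-resident pool.
    independent_clusters: tuple[str, ...] = ("S100A12+ monocytes",)
    coverage_model: tuple[float, float] = (20.0, 2.0)
    base_error_rate: float = 0.002
    fixed_heteroplasmy: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.heteroplasmy_distribution
        if a <= 0 or b <= 0:
            raise ConfigurationError("heteroplasmy_distribution parameters must be > 0")
        for name in (
            "n_donors",
            "n_germline_variants_per_donor",
            "n_clones",
            "clone_tree_depth",
            "somatic_variants_per_clone",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.migration_fraction <= 1.0:
            raise ConfigurationError("migration_fraction must be in [0, 1]")
        if not 0.0 <= self.base_error_rate < 0.25:
            raise ConfigurationError("base_error_rate must be in [0, 0.25)")
        if not 0.0 < self.bottleneck_fraction <= 1.0:
            raise ConfigurationError("bottleneck_fraction must be in (0, 1]")
        if self.resident_polyclonality < 1:
            raise ConfigurationError("resident_polyclonality must be >= 1")
        if not 0.0 < self.differentiation_retention <= 1.0:
            raise ConfigurationError("differentiation_retention must be in (0, 1]")
        skin = {c for c, _, _ in self.clusters_per_tissue.get("skin", ())}
        syn = {c for c, _, _ in self.clusters_per_tissue.get("synovium", ())}
        if self.precursor_cluster not in skin:
            raise ConfigurationError(
                f"precursor_cluster {self.precursor_cluster!r} is not a skin cluster"
            )
        for c in self.downstream_clusters:
            if c not in syn:
                raise ConfigurationError(f"downstream cluster {c!r} is not a synovial cluster")
        landing = self.landing_cluster or (
            self.downstream_clusters[0] if self.downstream_clusters else None
        )
        if self.downstream_clusters and landing not in self.downstream_clusters:
            raise ConfigurationError("landing_cluster must be one of downstream_clusters")
        for c in self.independent_clusters:
            if c in skin:
                raise ConfigurationError(
                    f"independent cluster {c!r} must be synovial, not a skin cluster"
                )
            if c in self.downstream_clusters:
                raise ConfigurationError(
                    f"independent cluster {c!r} cannot also be downstream"
                )
        pools = {
            (tissue, lineage)
            for tissue, specs in self.clusters_per_tissue.items()
            for _, lineage, _ in specs
        }
        n_indep = len([c for c in self.independent_clusters if c in syn])
        total = self.n_germline_variants_per_donor + sum(
            self.pool_size(p) * self.somatic_variants_per_clone for p in pools
        ) + n_indep * self.n_clones * self.resident_polyclonality * self.somatic_variants_per_clone
        if total > self.mito_genome_length:
            raise ConfigurationError(
                f"{total} requested variant positions exceed genome length "
                f"{self.mito_genome_length}"
            )

    @property
    def precursor_lineage(self) -> str:
        for c, lineage, _ in self.clusters_per_tissue.get("skin", ()):
            if c == self.precursor_cluster:
                return lineage
        return ""

    def pool_size(self, pool: tuple[str, str]) -> int:
        """Clone count of a (tissue, lineage) pool.

        The migrating source pool (skin, precursor lineage) holds
        ``n_clones`` expanded clones; resident pools are more polyclonal.
        """
        if pool == ("skin", self.precursor_lineage):
            return self.n_clones
        return self.n_clones * self.resident_polyclonality

    @property
    def landing(self) -> str | None:
        if not self.downstream_clusters:
            return None
        return self.landing_cluster or self.downstream_clusters[0]


@dataclass
class GroundTruth:
    """True clonal structure behind a simulated dataset."""

    clone_of_cell: dict[str, str]
    variants_of_clone: dict[str, dict[str, float]]
    germline_variants: dict[str, dict[str, float]]
    migration_origin: dict[str, str | None]
    precursor_cluster: str
    landing_cluster: str | None
    variant_meta: pd.DataFrame  # variant_id, donor_id, position, ref, alt, origin, pool, clone

    def germline_ids(self, donor: str) -> frozenset[str]:
        return frozenset(self.germline_variants.get(donor, {}))

    def ref_base_map(self) -> dict[int, str]:
        """position -> reference base for every simulated position."""
        return dict(
            zip(self.variant_meta["position"].astype(int), self.variant_meta["ref"])
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "clone_of_cell": self.clone_of_cell,
            "variants_of_clone": self.variants_of_clone,
            "germline_variants": self.germline_variants,
            "migration_origin": self.migration_origin,
            "precursor_cluster": self.precursor_cluster,
            "landing_cluster": self.landing_cluster,
            "variant_meta": self.variant_meta.to_dict(orient="list"),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["variant_meta"] = pd.DataFrame(payload["variant_meta"])
        return cls(**payload)


def _clone_tree(n: int, max_depth: int, rng: np.random.Generator) -> list[int | None]:
    """Random rooted forest over ``n`` clones with node depth < ``max_depth``."""
    parents: list[int | None] = []
    depth: list[int] = []
    for i in range(n):
        candidates = [j for j in range(i) if depth[j] < max_depth - 1]
        if i == 0 or not candidates:
            parents.append(None)
            depth.append(0)
        else:
            p = int(rng.choice(candidates))
            parents.append(p)
            depth.append(depth[p] + 1)
    return parents


def _sample_heteroplasmy(config: CloneSimConfig, size: int, rng: np.random.Generator):
    if config.fixed_heteroplasmy is not None:
        return np.full(size, float(config.fixed_heteroplasmy))
    a, b = config.heteroplasmy_distribution
    return rng.beta(a, b, size=size)


def _simulate_donor(
    donor: str, config: CloneSimConfig, ref_idx_of_pos, rng: np.random.Generator
):
    """Simulate one donor; returns (annotation rows, dense counts, truth pieces)."""
    pools = sorted(
        {
            (tissue, lineage)
            for tissue, specs in config.clusters_per_tissue.items()
            for _, lineage, _ in specs
        }
    )
    syn_clusters = {c for c, _, _ in config.clusters_per_tissue.get("synovium", ())}
    independent = sorted(c for c in config.independent_clusters if c in syn_clusters)
    indep_pool_size = config.n_clones * config.resident_polyclonality
    n_som = (
        sum(config.pool_size(p) * config.somatic_variants_per_clone for p in pools)
        + len(independent) * indep_pool_size * config.somatic_variants_per_clone
    )
    total = config.n_germline_variants_per_donor + n_som
    positions = rng.choice(config.mito_genome_length, size=total, replace=False) + 1

    ref_idx = ref_idx_of_pos(positions)
    alt_shift = rng.integers(1, 4, size=total)
    alt_idx = (ref_idx + alt_shift) % 4
    base_arr = np.array(BASES)
    vids = np.array(
        [f"{p}{base_arr[r]}>{base_arr[a]}" for p, r, a in zip(positions, ref_idx, alt_idx)]
    )

    meta_rows = []
    germ = {}
    k = 0
    for i in range(config.n_germline_variants_per_donor):
        germ[vids[k]] = GERMLINE_HETEROPLASMY
        meta_rows.append((vids[k], donor, int(positions[k]), base_arr[ref_idx[k]],
                          base_arr[alt_idx[k]], "germline", "", ""))
        k += 1

    variants_of_clone: dict[str, dict[str, float]] = {}
    pool_clones: dict[tuple[str, str], list[str]] = {}

    def build_pool(key: tuple[str, str], size: int, label: str) -> None:
        nonlocal k
        parents = _clone_tree(size, config.clone_tree_depth, rng)
        names = [f"{donor}:{label}:c{i}" for i in range(size)]
        pool_clones[key] = names
        for ci, name in enumerate(names):
            own: dict[str, float] = {}
            hs = _sample_heteroplasmy(config, config.somatic_variants_per_clone, rng)
            for h in hs:
                own[vids[k]] = float(h)
                meta_rows.append((vids[k], donor, int(positions[k]), base_arr[ref_idx[k]],
                                  base_arr[alt_idx[k]], "somatic", label, name))
                k += 1
            inherited = dict(variants_of_clone[names[parents[ci]]]) if parents[ci] is not None else {}
            inherited.update(own)
            variants_of_clone[name] = inherited

    for tissue, lineage in pools:
        build_pool((tissue, lineage), config.pool_size((tissue, lineage)),
                   f"{tissue}:{lineage}")
    for cluster in independent:
        build_pool(("independent", cluster), indep_pool_size, f"independent:{cluster}")

    # --- cell assignment --------------------------------------------------
    ann_rows = []  # cell_id, donor, tissue, lineage, cluster, clone, migration_origin
    counter = 0

    def new_cell() -> str:
        nonlocal counter
        cid = f"{donor}_{counter:04d}"
        counter += 1
        return cid

    # skin and non-downstream synovial clusters first: native pool clones
    cluster_cells: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for tissue in config.clusters_per_tissue:
        for cluster, lineage, n in config.clusters_per_tissue[tissue]:
            is_downstream = tissue == "synovium" and cluster in config.downstream_clusters
            if is_downstream:
                cluster_cells[(tissue, cluster)] = []
                continue
            if tissue == "synovium" and cluster in independent:
                clones = pool_clones[("independent", cluster)]
            else:
                clones = pool_clones[(tissue, lineage)]
            picks = rng.integers(0, len(clones), size=n)
            rows = [(new_cell(), clones[p]) for p in picks]
            cluster_cells[(tissue, cluster)] = rows
            ann_rows += [
                (cid, donor, tissue, lineage, cluster, cl, None) for cid, cl in rows
            ]

    skin_precursor = ("skin", config.precursor_cluster)
    precursor_clones = sorted({cl for _, cl in cluster_cells.get(skin_precursor, [])})
    if config.downstream_clusters and config.migration_fraction > 0 and not precursor_clones:
        raise ConfigurationError(
            "precursor cluster has no cells but migration_fraction > 0"
        )

    migration_origin: dict[str, str | None] = {}
    landing = config.landing
    landing_migrant_clones: list[str] = []
    diluted_cells: list[str] = []
    ordered_downstream = [landing] + [c for c in config.downstream_clusters if c != landing]
    syn_specs = {c: (lin, n) for c, lin, n in config.clusters_per_tissue.get("synovium", ())}
    for cluster in ordered_downstream:
        if cluster is None:
            continue
        lineage, n = syn_specs[cluster]
        native = pool_clones[("synovium", lineage)]
        n_mig = int(round(config.migration_fraction * n))
        if cluster == landing or not config.nested_downstream:
            source = precursor_clones
        else:
            source = landing_migrant_clones or precursor_clones
        if config.bottleneck_fraction < 1.0 and cluster != landing:
            size = max(1, int(round(config.bottleneck_fraction * len(source))))
            source = sorted(rng.choice(source, size=size, replace=False))
        mig_flags = np.zeros(n, dtype=bool)
        if n_mig:
            mig_flags[rng.choice(n, size=n_mig, replace=False)] = True
        rows = []
        for i in range(n):
            cid = new_cell()
            if mig_flags[i]:
                cl = source[int(rng.integers(0, len(source)))]
                migration_origin[cid] = cl
                if cluster == landing:
                    landing_migrant_clones.append(cl)
                else:
                    diluted_cells.append(cid)
            else:
                cl = native[int(rng.integers(0, len(native)))]
            rows.append((cid, cl))
        landing_migrant_clones = sorted(set(landing_migrant_clones))
        cluster_cells[("synovium", cluster)] = rows
        ann_rows += [
            (cid, donor, "synovium", lineage, cluster, cl, migration_origin.get(cid))
            for cid, cl in rows
        ]

    # --- observed counts --------------------------------------------------
    ann = pd.DataFrame(
        ann_rows,
        columns=["cell_id", "donor_id", "tissue", "lineage", "cluster", "clone",
                 "migration_origin"],
    )
    C = len(ann)
    order = np.argsort(positions, kind="stable")
    pos_sorted = positions[order]
    ref_sorted, alt_sorted = ref_idx[order], alt_idx[order]
    P = len(pos_sorted)

    clone_names = sorted(variants_of_clone)
    clone_pos = {c: i for i, c in enumerate(clone_names)}
    pos_col = {int(p): j for j, p in enumerate(pos_sorted)}
    vid_pos = {v: int(p) for v, p in zip(vids, positions)}

    clone_h = np.zeros((len(clone_names), P))
    for cname, vs in variants_of_clone.items():
        for v, h in vs.items():
            clone_h[clone_pos[cname], pos_col[vid_pos[v]]] = h
    H = clone_h[[clone_pos[c] for c in ann["clone"]]]
    if diluted_cells and config.differentiation_retention < 1.0:
        row_of = {cid: i for i, cid in enumerate(ann["cell_id"])}
        rows_dil = [row_of[c] for c in diluted_cells]
        H[rows_dil] *= config.differentiation_retention
    for v, h in germ.items():
        H[:, pos_col[vid_pos[v]]] = h

    mean, disp = config.coverage_model
    p_nb = disp / (disp + mean)
    depth = rng.negative_binomial(disp, p_nb, size=(C, P))

    e = config.base_error_rate
    p_alt = H * (1 - e) + (1 - H) * (e / 3)
    alt = rng.binomial(depth, p_alt)
    rem = depth - alt
    p_ref = (1 - H) * (1 - e) + H * (e / 3)
    denom = np.clip(1.0 - p_alt, 1e-12, None)
    refc = rng.binomial(rem, np.clip(p_ref / denom, 0.0, 1.0))
    rem2 = rem - refc
    o1 = rng.binomial(rem2, 0.5)
    o2 = rem2 - o1

    arr = np.zeros((C, P, 4), dtype=np.int64)
    cols = np.arange(P)
    arr[:, cols, ref_sorted] += refc
    arr[:, cols, alt_sorted] += alt
    others = np.array(
        [sorted(set(range(4)) - {r, a}) for r, a in zip(ref_sorted, alt_sorted)]
    )
    arr[:, cols, others[:, 0]] += o1
    arr[:, cols, others[:, 1]] += o2

    meta = pd.DataFrame(
        meta_rows,
        columns=["variant_id", "donor_id", "position", "ref", "alt", "origin", "pool", "clone"],
    )
    truth = {
        "clone_of_cell": dict(zip(ann["cell_id"], ann["clone"])),
        "germline": germ,
        "variants_of_clone": variants_of_clone,
        "migration_origin": migration_origin,
        "meta": meta,
    }
    return ann, (ann["cell_id"].to_numpy(), pos_sorted, arr), truth


def simulate_clonal_population(
    config: CloneSimConfig,
) -> tuple[pd.DataFrame, AlleleCountTensor, GroundTruth]:
    """Generate annotations, an allele-count tensor and ground truth.

    Deterministic given ``config.seed``.  Returns the annotation table
    (``cell_id, donor_id, tissue, lineage, cluster, clone, migration_origin``),
    the observed :class:`AlleleCountTensor` and the :class:`GroundTruth`.
    """
    ref_rng = np.random.default_rng([config.seed, 7919])
    ref_genome = ref_rng.integers(0, 4, size=config.mito_genome_length)

    def ref_idx_of_pos(positions: np.ndarray) -> np.ndarray:
        return ref_genome[np.asarray(positions) - 1]

    anns, blocks = [], []
    clone_of_cell: dict[str, str] = {}
    variants_of_clone: dict[str, dict[str, float]] = {}
    germline: dict[str, dict[str, float]] = {}
    migration_origin: dict[str, str | None] = {}
    metas = []
    for d in range(config.n_donors):
        donor = f"donor{d + 1}"
        rng = np.random.default_rng([config.seed, d + 1])
        ann, block, truth = _simulate_donor(donor, config, ref_idx_of_pos, rng)
        anns.append(ann)
        blocks.append(block)
        clone_of_cell.update(truth["clone_of_cell"])
        variants_of_clone.update(truth["variants_of_clone"])
        germline[donor] = truth["germline"]
        migration_origin.update(truth["migration_origin"])
        metas.append(truth["meta"])

    annotations = pd.concat(anns, ignore_index=True)
    all_cells = np.concatenate([c for c, _, _ in blocks])
    all_positions = np.unique(np.concatenate([p for _, p, _ in blocks]))
    arr = np.zeros((len(all_cells), len(all_positions), 4), dtype=np.int64)
    row = 0
    for cells, positions, block in blocks:
        cols = np.searchsorted(all_positions, positions)
        arr[row : row + len(cells)][:, cols, :] = block
        row += len(cells)
    tensor = AlleleCountTensor.from_dense(
        all_cells, all_positions, arr, genome_length=config.mito_genome_length
    )
    gt = GroundTruth(
        clone_of_cell=clone_of_cell,
        variants_of_clone=variants_of_clone,
        germline_variants=germline,
        migration_origin={c: migration_origin.get(c) for c in annotations["cell_id"]},
        precursor_cluster=config.precursor_cluster,
        landing_cluster=config.landing,
        variant_meta=pd.concat(metas, ignore_index=True),
    )
    return annotations, tensor, gt


# -- spatial -----------------------------------------------------------------


@dataclass
class SpatialCellMap:
    """Point pattern of one imaged sample: centroids in µm plus type labels."""

    sample_id: str
    cells: pd.DataFrame  # cell_id, x, y, label [+ marker columns]

    def __post_init__(self) -> None:
        missing = {"cell_id", "x", "y", "label"} - set(self.cells.columns)
        if missing:
            raise ConfigurationError(f"spatial map lacks columns: {sorted(missing)}")
        if len(self.cells) < 1:
            raise ConfigurationError("spatial map must contain at least one cell")
        xy = self.cells[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ConfigurationError("non-finite coordinates in spatial map")


@dataclass(frozen=True)
class SpatialSimConfig:
    """Parameters for labelled point patterns with pairwise structure."""

    n_samples: int = 1
    field_size: tuple[float, float] = (500.0, 500.0)
    types: tuple[tuple[str, int], ...] = (("A", 50), ("B", 50))
    attraction_pairs: tuple[tuple[str, str, float, float], ...] = ()
    avoidance_pairs: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_size
        for a, b, frac, dist in self.attraction_pairs:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fraction_paired must be in [0, 1]")
            if dist >= min(w, h):
                raise ConfigurationError("pair_distance must be below the field dimensions")
        for _, n in self.types:
            if n < 0:
                raise ConfigurationError("n_cells must be >= 0")


def simulate_spatial_tissue(config: SpatialSimConfig) -> list[SpatialCellMap]:
    """Place cells uniformly, then apply attraction pairing and avoidance."""
    w, h = config.field_size
    type_counts = dict(config.types)
    maps = []
    for s in range(config.n_samples):
        rng = np.random.default_rng([config.seed, 104729 + s])
        placed: dict[str, np.ndarray] = {
            t: np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
            for t, n in config.types
        }
        for a, b, frac, dist in config.attraction_pairs:
            n_pair = int(round(frac * type_counts.get(a, 0)))
            if n_pair > type_counts.get(b, 0):
                raise ConfigurationError(
                    f"attraction pair ({a},{b}): {n_pair} partners requested but only "
                    f"{type_counts.get(b, 0)} {b} cells available"
                )
            if n_pair == 0:
                continue
            a_idx = rng.choice(len(placed[a]), size=n_pair, replace=False)
            theta = rng.uniform(0, 2 * np.pi, n_pair)
            r = dist * np.sqrt(rng.uniform(0, 1, n_pair))
            partner = placed[a][a_idx] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            # clipping to the field is a projection onto a convex set containing
            # the anchor, so the pair distance never grows
            partner[:, 0] = np.clip(partner[:, 0], 0, w)
            partner[:, 1] = np.clip(partner[:, 1], 0, h)
            placed[b][:n_pair] = partner
        for a, b, radius in config.avoidance_pairs:
            anchors = placed.get(a)
            if anchors is None or not len(anchors):
                continue
            pts = placed[b]
            for i in range(len(pts)):
                for _ in range(1000):
                    d2 = np.min(np.sum((anchors - pts[i]) ** 2, axis=1))
                    if d2 >= radius**2:
                        break
                    pts[i] = [rng.uniform(0, w), rng.uniform(0, h)]
                else:
                    raise ConfigurationError(
                        f"avoidance pair ({a},{b}): no admissible position found"
                    )
        rows = []
        i = 0
        for t, _ in config.types:
            for x, y in placed[t]:
                rows.append((f"s{s}_{i:04d}", float(x), float(y), t))
                i += 1
        maps.append(
            SpatialCellMap(
                sample_id=f"sample{s + 1}",
                cells=pd.DataFrame(rows, columns=["cell_id", "x", "y", "label"]),
            )
        )
    return maps
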