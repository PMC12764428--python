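"""Reproducible pipeline orchestration: config loading, stages, manifests.

A pipeline config is a YAML mapping with optional sections ``clone_sim``,
``spatial_sim``, ``filters``, ``sharing``, ``sweep``, ``spatial``, plus a
global ``seed`` and ``outdir``.  Every stage writes a ``manifest.json``
embedding the SHA-1 of the canonicalised config and the seed, so two runs
with equal hashes produce identical artefacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .graph import build_lineage_graph, containment_check, rank_precursors
from .sharing import (
    SharingConfig,
    cluster_variant_carriage,
    compute_sharing,
    export_sharing_csv,
    one_vs_rest_test,
)
from .simulate import (
    CloneSimConfig,
    SpatialSimConfig,
    simulate_clonal_population,
    simulate_spatial_tissue,
    SpatialCellMap,
)
from .spatial import analyze_sample, nn_distance, summarize_interactions
from .sweep import SweepGrid, run_sweep, summarize_sweep
from .tensor import read_annotations, read_long_csv, write_annotations, write_long_csv
from .variants import (
    FilterConfig,
    call_informative_variants,
    compute_variant_table,
    export_vcf,
)


class DegenerateRunError(RuntimeError):
    """Filtering produced no informative variants; the run is reportable but empty."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _write_manifest(outdir: Path, config: dict, seed: int) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "config_hash": config_hash(config),
                "seed": seed,
                "version": __version__,
            },
            indent=2,
        )
    )


def _clone_config(config: dict, seed: int) -> CloneSimConfig:
    kw = dict(config.get("clone_sim", {}))
    if "clusters_per_tissue" in kw:
        kw["clusters_per_tissue"] = {
            t: tuple(tuple(c) for c in specs)
            for t, specs in kw["clusters_per_tissue"].items()
        }
    if "downstream_clusters" in kw:
        kw["downstream_clusters"] = tuple(kw["downstream_clusters"])
    kw.setdefault("seed", seed)
    return CloneSimConfig(**kw)


def run_simulate(config: dict, outdir: str | Path, seed: int) -> Path:
    """Write annotations, allele counts, reference bases, ground truth and
    spatial maps for the configured synthetic scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ccfg = _clone_config(config, seed)
    annotations, tensor, gt = simulate_clonal_population(ccfg)
    write_annotations(annotations, outdir / "annotations.csv")
    write_long_csv(tensor, outdir / "allele_counts.csv")
    gt.to_json(outdir / "ground_truth.json")
    pd.DataFrame(
        sorted(gt.ref_base_map().items()), columns=["position", "ref"]
    ).to_csv(outdir / "ref_bases.csv", index=False)

    skw = dict(config.get("spatial_sim", {}))
    if skw:
        for key in ("types", "attraction_pairs", "avoidance_pairs"):
            if key in skw:
                skw[key] = tuple(tuple(x) for x in skw[key])
        if "field_size" in skw:
            skw["field_size"] = tuple(skw["field_size"])
        skw.setdefault("seed", seed)
        maps = simulate_spatial_tissue(SpatialSimConfig(**skw))
        pd.concat(
            [m.cells.assign(sample_id=m.sample_id) for m in maps], ignore_index=True
        ).to_csv(outdir / "spatial_maps.csv", index=False)
    _write_manifest(outdir, config, seed)
    return outdir


def _read_ref_map(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path)
    return dict(zip(df["position"].astype(int), df["ref"]))


def consensus_ref_map(tensor) -> dict[int, str]:
    """Fallback reference: the base with the highest total count per position."""
    totals = (
        tensor.counts.groupby(["position", "base"])["count"].sum().unstack(fill_value=0)
    )
    return {int(p): str(totals.loc[p].idxmax()) for p in totals.index}


def run_trace(
    counts_path: str | Path,
    annotations_path: str | Path,
    config: dict,
    outdir: str | Path,
    seed: int,
    ref_path: str | Path | None = None,
) -> Path:
    """Filtering -> VCF export -> sharing -> tests -> ranking -> sweep."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tensor = read_long_csv(counts_path)
    annotations = read_annotations(annotations_path)
    orphans = set(tensor.counts["cell_id"]) - set(annotations["cell_id"])
    if orphans:
        raise ValueError(
            f"{len(orphans)} cells in counts lack annotations: {sorted(orphans)[:5]} ..."
        )
    ref_map = _read_ref_map(ref_path) if ref_path else consensus_ref_map(tensor)
    fcfg = FilterConfig(**config.get("filters", {}))
    scfg = SharingConfig(**config.get("sharing", {}))

    table = compute_variant_table(tensor, ref_map, min_coverage=fcfg.min_coverage)
    ivs = call_informative_variants(table, annotations, fcfg)
    if all(len(v) == 0 for v in ivs.variants.values()):
        (outdir / "degenerate.json").write_text(
            json.dumps({"reason": "no informative variants", "filters": fcfg.to_dict()})
        )
        _write_manifest(outdir, config, seed)
        raise DegenerateRunError("filtering yielded no informative variants")
    export_vcf(ivs, ref_map, outdir / "vcf")
    carriage = cluster_variant_carriage(ivs, annotations, scfg)
    carriage.to_csv(outdir / "carriage.csv", index=False)
    sharing = compute_sharing(carriage, scfg, annotations=annotations, ivs=ivs)
    tests = one_vs_rest_test(sharing, level="cluster")
    export_sharing_csv(sharing, tests, outdir / "sharing.csv")
    tests.to_csv(outdir / "tests.csv", index=False)
    sharing.donor_summary.to_csv(outdir / "donor_summary.csv", index=False)

    clusters = config.get("rank_clusters")
    rank1 = {}
    for mode in ("include_skin", "exclude_skin"):
        g = build_lineage_graph(carriage, mode=mode, clusters=clusters,
                                lineage_matched=scfg.lineage_matched)
        ranking = rank_precursors(g)
        ranking.consensus.to_csv(outdir / f"ranking_{mode}.csv", index=False)
        rank1[mode] = ranking.top()
    if rank1["include_skin"] is not None:
        cont = containment_check(carriage, rank1["include_skin"], clusters=clusters)
        (outdir / "containment.json").write_text(
            json.dumps({"precursor": rank1["include_skin"], "per_donor": cont})
        )

    if "sweep" in config:
        grid = SweepGrid(**config["sweep"])
        result = run_sweep(table, annotations, grid, base_filter=fcfg,
                           sharing_config=scfg, clusters=clusters)
        summary = summarize_sweep(result)
        summary["rank1"].to_csv(outdir / "sweep_rank1.csv", index=False)
        summary["lineage"].to_csv(outdir / "sweep_lineage.csv", index=False)
        summary["sensitivity"].to_csv(outdir / "sweep_sensitivity.csv", index=False)
    _write_manifest(outdir, config, seed)
    return outdir


def run_spatial(
    spatial_path: str | Path, config: dict, outdir: str | Path, seed: int
) -> Path:
    """Interaction tests, interacting proportions, distances, summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(spatial_path)
    sp = config.get("spatial", {})
    radius = float(sp.get("radius", 40.0))
    n_permutations = int(sp.get("n_permutations", 1000))
    alpha = float(sp.get("alpha", 0.05))
    pairs = [tuple(p) for p in sp["pairs"]] if "pairs" in sp else None
    known = set(df["label"])
    if pairs:
        unknown = {t for p in pairs for t in p} - known
        if unknown:
            raise ValueError(f"unknown labels in pairs list: {sorted(unknown)}")

    samples = []
    rows = []
    for sid, sub in df.groupby("sample_id"):
        cell_map = SpatialCellMap(sample_id=str(sid), cells=sub.reset_index(drop=True))
        sample = analyze_sample(
            cell_map, radius=radius, pairs=pairs, n_permutations=n_permutations,
            alpha=alpha, seed=seed,
        )
        samples.append(sample)
        for r in sample.results:
            rows.append(
                (sid, r.from_type, r.to_type, r.observed, r.null_mean, r.p,
                 r.classification, sample.proportions[(r.from_type, r.to_type)])
            )
        for a, b in sp.get("distance_pairs", []):
            if a in set(sub["label"]) and b in set(sub["label"]):
                _, med = nn_distance(cell_map, a, b)
                rows_d = pd.DataFrame(
                    [(sid, a, b, med)],
                    columns=["sample_id", "from_type", "to_type", "median_nn_um"],
                )
                mode = "a" if (outdir / "distances.csv").exists() else "w"
                rows_d.to_csv(outdir / "distances.csv", index=False, mode=mode,
                              header=mode == "w")
    pd.DataFrame(
        rows,
        columns=["sample_id", "from_type", "to_type", "observed", "null_mean", "p",
                 "classification", "interacting_proportion"],
    ).to_csv(outdir / "interactions.csv", index=False)
    summarize_interactions(samples).to_csv(outdir / "summary.csv", index=False)
    _write_manifest(outdir, config, seed)
    return outdir
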