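"""Variant table construction, informative-variant filters, VCF export."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mitolineage import (
    AlleleCountTensor,
    FilterConfig,
    call_informative_variants,
    compute_variant_table,
    export_vcf,
)
from mitolineage.experiments import TIGHTENINGS, _random_small_tensor


def annotations_for(cells, donor="d1"):
    return pd.DataFrame(
        {
            "cell_id": list(cells),
            "donor_id": donor,
            "tissue": "skin",
            "lineage": "myeloid",
            "cluster": "c",
        }
    )


def tensor_from_rows(rows, genome_length=16569):
    return AlleleCountTensor(
        pd.DataFrame(rows, columns=["cell_id", "position", "base", "count"]),
        genome_length=genome_length,
    )


def test_variant_table_basic_arithmetic():
    t = tensor_from_rows([("c1", 100, "A", 5), ("c1", 100, "T", 5)])
    table = compute_variant_table(t, {100: "A"}, min_coverage=5)
    rec = table.records
    assert list(rec["variant_id"].astype(str)) == ["100A>T"]
    assert rec["vaf"].iloc[0] == 0.5
    assert bool(rec["evaluable"].iloc[0])


def test_low_coverage_cell_not_evaluable():
    t = tensor_from_rows(
        [("c1", 100, "A", 2), ("c1", 100, "T", 2), ("c2", 100, "A", 5), ("c2", 100, "T", 5)]
    )
    table = compute_variant_table(t, {100: "A"}, min_coverage=5)
    summ = table.summaries().set_index("variant_id")
    assert summ.loc["100A>T", "n_evaluable_cells"] == 1  # c1 has coverage 4
    rec = table.records.set_index("cell_id")
    assert not bool(rec.loc["c1", "evaluable"])
    assert np.isnan(rec.loc["c1", "vaf"])


def test_mean_vaf_over_ten_cells():
    rows = []
    for i in range(10):
        rows += [(f"c{i}", 100, "A", 9), (f"c{i}", 100, "T", 1)]
    table = compute_variant_table(tensor_from_rows(rows), {100: "A"}, min_coverage=5)
    summ = table.summaries().set_index("variant_id")
    assert summ.loc["100A>T", "n_evaluable_cells"] == 10
    assert summ.loc["100A>T", "mean_vaf"] == pytest.approx(0.1)


def test_missing_reference_base_errors():
    t = tensor_from_rows([("c1", 100, "A", 5)])
    with pytest.raises(ValueError, match="position 100"):
        compute_variant_table(t, {}, min_coverage=1)


def test_germline_like_variant_excluded():
    """A near-homoplasmic variant present in all cells fails the specificity
    caps regardless of its per-cell quality."""
    rows = []
    for i in range(50):
        rows += [(f"c{i}", 200, "G", 1), (f"c{i}", 200, "C", 49)]
    t = tensor_from_rows(rows)
    table = compute_variant_table(t, {200: "G"}, min_coverage=5)
    ivs = call_informative_variants(table, annotations_for(f"c{i}" for i in range(50)),
                                    FilterConfig())
    assert ivs.variants["d1"] == frozenset()


def test_clone_like_variant_retained_and_recurrence_edge():
    """10 of 200 cells at VAF 0.3 passes all default filters; detection in
    only 2 cells fails min_cells_detected=3."""
    rows = []
    for i in range(200):
        alt = 6 if i < 10 else 0  # VAF 0.3 at coverage 20 in 10 cells
        rows.append((f"c{i}", 300, "A", 20 - alt))
        if alt:
            rows.append((f"c{i}", 300, "G", alt))
        alt2 = 6 if i < 2 else 0
        rows.append((f"c{i}", 400, "T", 20 - alt2))
        if alt2:
            rows.append((f"c{i}", 400, "C", alt2))
    t = tensor_from_rows(rows)
    table = compute_variant_table(t, {300: "A", 400: "T"}, min_coverage=5)
    ivs = call_informative_variants(
        table, annotations_for(f"c{i}" for i in range(200)), FilterConfig()
    )
    assert "300A>G" in ivs.variants["d1"]
    assert "400T>C" not in ivs.variants["d1"]  # detected in 2 < 3 cells
    # detection masks recorded per cell
    det = ivs.detection
    assert set(det.loc[det["variant_id"] == "300A>G", "cell_id"].astype(str)) == {
        f"c{i}" for i in range(10)
    }


def test_blacklisted_position_excluded():
    rows = []
    for i in range(10):
        rows += [(f"c{i}", 3107, "A", 10), (f"c{i}", 3107, "G", 10)]
    t = tensor_from_rows(rows)
    table = compute_variant_table(t, {3107: "A"}, min_coverage=5)
    ivs = call_informative_variants(table, annotations_for(f"c{i}" for i in range(10)),
                                    FilterConfig(max_detected_fraction=1.0, max_mean_vaf=1.0))
    assert ivs.variants["d1"] == frozenset()


def brute_force_informative(tensor, ref_map, annotations, config):
    """Independent nested-loop reference implementation of the filters."""
    donor_of = dict(zip(annotations["cell_id"], annotations["donor_id"]))
    cells, positions, arr = tensor.to_dense()
    out = {d: set() for d in set(donor_of.values())}
    for pi, pos in enumerate(positions):
        ref = ref_map[int(pos)]
        for b in "ACGT":
            if b == ref:
                continue
            vid = f"{pos}{ref}>{b}"
            if arr[:, pi, "ACGT".index(b)].sum() == 0:
                continue
            for donor in out:
                n_det = n_cov = n_spec = 0
                vaf_sum = 0.0
                for ci, cell in enumerate(cells):
                    if donor_of[cell] != donor:
                        continue
                    cov = int(arr[ci, pi].sum())
                    alt = int(arr[ci, pi, "ACGT".index(b)])
                    if cov < 1:
                        continue
                    n_cov += 1
                    vaf_sum += alt / cov
                    if alt >= 1:
                        n_spec += 1
                    if (
                        cov >= config.min_coverage
                        and alt >= config.min_alt_reads
                        and alt / cov >= config.min_vaf
                    ):
                        n_det += 1
                if n_cov == 0:
                    continue
                if (
                    n_det >= config.min_cells_detected
                    and n_spec / n_cov <= config.max_detected_fraction
                    and vaf_sum / n_cov <= config.max_mean_vaf
                    and int(pos) not in config.blacklist_positions
                ):
                    out[donor].add(vid)
    return out


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    tensor, ref_map, annotations = _random_small_tensor(rng, n_cells=30, n_pos=15)
    # split cells over two donors to exercise per-donor filtering
    annotations = annotations.copy()
    annotations.loc[15:, "donor_id"] = "d2"
    config = FilterConfig(min_cells_detected=2)
    table = compute_variant_table(tensor, ref_map, min_coverage=config.min_coverage)
    ivs = call_informative_variants(table, annotations, config)
    expected = brute_force_informative(tensor, ref_map, annotations, config)
    assert {d: set(v) for d, v in ivs.variants.items()} == expected


def test_donor_privacy(default_run):
    """Per-donor sets are invariant to the presence of other donors."""
    table = default_run["table"]
    annotations = default_run["annotations"]
    config = FilterConfig()
    full = call_informative_variants(table, annotations, config)
    one = annotations[annotations["donor_id"] == "donor1"]
    rec = table.records
    sub_rec = rec[rec["cell_id"].astype(str).isin(set(one["cell_id"]))]
    sub_table = replace(default_run["table"], records=sub_rec)
    solo = call_informative_variants(sub_table, one, config)
    assert solo.variants["donor1"] == full.variants["donor1"]


def test_refilter_reproduces_set(default_run):
    """Re-applying the stored config to the source tensor reproduces the set."""
    run = default_run
    ivs = run["ivs"]
    table2 = compute_variant_table(
        run["tensor"], run["ground_truth"].ref_base_map(), min_coverage=1
    )
    again = call_informative_variants(table2, run["annotations"], ivs.config)
    assert again.variants == ivs.variants


def test_monotone_under_tightening_small():
    rng = np.random.default_rng(42)
    tensor, ref_map, annotations = _random_small_tensor(rng)
    table = compute_variant_table(tensor, ref_map, min_coverage=1)
    base = FilterConfig()
    n_base = sum(
        len(v) for v in call_informative_variants(table, annotations, base).variants.values()
    )
    for f, v in TIGHTENINGS:
        tightened = replace(base, **{f: v})
        n = sum(
            len(v)
            for v in call_informative_variants(table, annotations, tightened).variants.values()
        )
        assert n <= n_base, f"tightening {f} increased the set"


# -- VCF export ---------------------------------------------------------------


def test_vcf_export_and_round_trip(tmp_path, default_run):
    pysam = pytest.importorskip("pysam")
    run = default_run
    ref_map = run["ground_truth"].ref_base_map()
    paths = export_vcf(run["ivs"], ref_map, tmp_path)
    assert set(paths) == set(run["ivs"].variants)
    for donor, path in paths.items():
        with pysam.VariantFile(str(path)) as vf:
            assert vf.header.contigs["chrM"].length == 16569
            seen = set()
            for rec in vf:
                assert rec.chrom == "chrM"
                assert rec.ref == ref_map[rec.pos]
                seen.add(f"{rec.pos}{rec.ref}>{rec.alts[0]}")
                assert rec.info["NDET"] >= 1
            assert seen == set(run["ivs"].variants[donor])


def test_vcf_empty_set_header_only(tmp_path):
    t = tensor_from_rows([("c1", 100, "A", 5), ("c1", 100, "T", 5)])
    table = compute_variant_table(t, {100: "A"}, min_coverage=5)
    ivs = call_informative_variants(
        table, annotations_for(["c1"]), FilterConfig(min_cells_detected=5)
    )
    paths = export_vcf(ivs, {100: "A"}, tmp_path)
    lines = paths["d1"].read_text().strip().splitlines()
    assert all(line.startswith("#") for line in lines)
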