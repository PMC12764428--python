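"""Informative somatic variant detection from per-cell allele counts.

Variants are called per donor.  A variant is retained when it passes four
groups of filters: per-cell detection (coverage, alt-read and VAF floors),
recurrence (minimum number of detecting cells), specificity (upper bounds
on the fraction of detecting cells and on mean heteroplasmy, which remove
near-homoplasmic germline/haplogroup variants), and a position blacklist.

The per-cell detection and recurrence filters use the thresholds of the
:class:`FilterConfig` under evaluation.  The specificity statistics
(detected fraction and mean VAF) are computed over all covered cells at a
fixed coverage >= 1 floor, so they are properties of the data rather than
of the threshold configuration; this keeps the informative-set size
monotone under coordinate-wise threshold tightening, which the robustness
sweep relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tensor import BASES, MT_GENOME_LENGTH, AlleleCountTensor

#: Default position blacklist: 3107 is the spacer "N" of the revised
#: Cambridge reference sequence and is a standard exclusion.
DEFAULT_BLACKLIST = frozenset({3107})


@dataclass(frozen=True)
class FilterConfig:
    """Quality and specificity thresholds for informative variant calling.

    All comparisons are inclusive (``>=`` for floors, ``<=`` for caps).
    """

    min_coverage: int = 5
    min_alt_reads: int = 2
    min_vaf: float = 0.05
    min_cells_detected: int = 3
    max_detected_fraction: float = 0.5
    max_mean_vaf: float = 0.35
    blacklist_positions: frozenset[int] = DEFAULT_BLACKLIST

    def __post_init__(self) -> None:
        if min(self.min_coverage, self.min_alt_reads, self.min_cells_detected) < 0:
            raise ValueError("count thresholds must be >= 0")
        for name in ("min_vaf", "max_detected_fraction", "max_mean_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        object.__setattr__(self, "blacklist_positions", frozenset(self.blacklist_positions))

    def to_dict(self) -> dict:
        return {
            "min_coverage": self.min_coverage,
            "min_alt_reads": self.min_alt_reads,
            "min_vaf": self.min_vaf,
            "min_cells_detected": self.min_cells_detected,
            "max_detected_fraction": self.max_detected_fraction,
            "max_mean_vaf": self.max_mean_vaf,
            "blacklist_positions": sorted(self.blacklist_positions),
        }


@dataclass
class VariantTable:
    """Per-(variant, cell) observations plus the evaluable-coverage floor.

    ``records`` has one row per (variant, cell) pair with coverage >= 1 at
    the variant position: columns ``variant_id, cell_id, position, ref, alt,
    coverage, alt_count, vaf, evaluable``.  ``vaf`` is ``alt/coverage`` when
    ``coverage >= min_coverage`` and NaN otherwise.
    """

    records: pd.DataFrame
    min_coverage: int
    genome_length: int = MT_GENOME_LENGTH

    def summaries(self) -> pd.DataFrame:
        """Per-variant summary over evaluable cells.

        ``n_detected_cells`` counts evaluable cells with at least one alt
        read; ``mean_vaf`` averages VAF over all evaluable cells.
        """
        df = self.records
        ev = df[df["evaluable"]]
        g = ev.groupby("variant_id", observed=True)
        out = pd.DataFrame(
            {
                "n_evaluable_cells": g.size(),
                "n_detected_cells": g["alt_count"].apply(lambda a: int((a >= 1).sum())),
                "mean_vaf": g["vaf"].mean(),
            }
        )
        out["detected_fraction"] = out["n_detected_cells"] / out["n_evaluable_cells"]
        return out.reset_index()


def compute_variant_table(
    tensor: AlleleCountTensor,
    ref_base_per_position: Mapping[int, str],
    min_coverage: int = 5,
) -> VariantTable:
    """Enumerate observed non-reference alleles and their per-cell support."""
    cells, positions, arr = tensor.to_dense()
    refs = []
    for p in positions:
        r = ref_base_per_position.get(int(p))
        if r is None:
            raise ValueError(f"no reference base for position {int(p)}")
        refs.append(r)
    ref_idx = np.array([BASES.index(r) for r in refs])

    cov = arr.sum(axis=2)  # cells x positions
    observed = arr.sum(axis=0) > 0  # positions x 4
    observed[np.arange(len(positions)), ref_idx] = False
    pairs = np.argwhere(observed)  # (position index, base index)
    if not len(pairs):
        records = pd.DataFrame(
            columns=["variant_id", "cell_id", "position", "ref", "alt", "coverage",
                     "alt_count", "vaf", "evaluable"]
        )
        return VariantTable(records, min_coverage, tensor.genome_length)

    base_arr = np.array(BASES)
    vid = [
        f"{positions[pi]}{base_arr[ref_idx[pi]]}>{base_arr[b]}" for pi, b in pairs
    ]
    covV = cov[:, pairs[:, 0]]
    altV = arr[:, pairs[:, 0], pairs[:, 1]]
    ci, vi = np.nonzero(covV >= 1)
    coverage = covV[ci, vi].astype(np.int64)
    alt_count = altV[ci, vi].astype(np.int64)
    evaluable = coverage >= min_coverage
    vaf = np.where(evaluable, alt_count / np.maximum(coverage, 1), np.nan)
    records = pd.DataFrame(
        {
            "variant_id": pd.Categorical.from_codes(vi, categories=vid),
            "cell_id": pd.Categorical.from_codes(ci, categories=list(cells)),
            "position": positions[pairs[vi, 0]],
            "ref": pd.Categorical.from_codes(ref_idx[pairs[vi, 0]], categories=list(BASES)),
            "alt": pd.Categorical.from_codes(pairs[vi, 1], categories=list(BASES)),
            "coverage": coverage,
            "alt_count": alt_count,
            "vaf": vaf,
            "evaluable": evaluable,
        }
    )
    return VariantTable(records, min_coverage, tensor.genome_length)


@dataclass
class InformativeVariantSet:
    """Somatic variants surviving the filters, per donor, with provenance.

    ``detection`` holds one row per (donor, variant, cell) where the
    per-cell detection rule fired; ``per_variant`` the per-donor filter
    statistics; ``config`` the exact :class:`FilterConfig` used.
    """

    variants: dict[str, frozenset[str]]
    detection: pd.DataFrame  # donor_id, variant_id, cell_id
    per_variant: pd.DataFrame  # donor_id, variant_id, position, n_detected, ...
    config: FilterConfig

    def all_variants(self) -> frozenset[str]:
        return frozenset().union(*self.variants.values()) if self.variants else frozenset()


def call_informative_variants(
    table: VariantTable,
    annotations: pd.DataFrame,
    config: FilterConfig,
) -> InformativeVariantSet:
    """Apply quality/specificity filters per donor.

    The result is independent of the ``min_coverage`` the table was built
    with: per-cell detection is recomputed from the raw coverage/alt-read
    columns with the thresholds in ``config``.
    """
    donor_of = dict(zip(annotations["cell_id"], annotations["donor_id"]))
    df = table.records
    if len(df) == 0:
        donors = sorted(annotations["donor_id"].unique())
        return InformativeVariantSet(
            variants={d: frozenset() for d in donors},
            detection=pd.DataFrame(columns=["donor_id", "variant_id", "cell_id"]),
            per_variant=pd.DataFrame(
                columns=["donor_id", "variant_id", "position", "n_detected", "n_covered",
                         "n_spec_detected", "mean_vaf", "detected_fraction", "informative"]
            ),
            config=config,
        )

    cell_cats = list(df["cell_id"].cat.categories)
    cell_codes = df["cell_id"].cat.codes.to_numpy()
    donors = sorted(annotations["donor_id"].unique())
    donor_idx_of = {d: i for i, d in enumerate(donors)}
    cell_donor_idx = np.array(
        [donor_idx_of.get(donor_of.get(c), -1) for c in cell_cats]
    )
    used = np.unique(cell_codes)
    orphans = [cell_cats[i] for i in used if cell_donor_idx[i] < 0]
    if orphans:
        raise ValueError(
            f"{len(orphans)} cells in the count tensor lack annotations, e.g. "
            f"{orphans[:5]}"
        )
    var_codes = df["variant_id"].cat.codes.to_numpy()
    var_cats = list(df["variant_id"].cat.categories)
    n_var, n_donor = len(var_cats), len(donors)

    cov = df["coverage"].to_numpy()
    alt = df["alt_count"].to_numpy()
    raw_vaf = alt / np.maximum(cov, 1)
    detected = (
        (cov >= config.min_coverage)
        & (alt >= config.min_alt_reads)
        & (raw_vaf >= config.min_vaf)
    )

    key = cell_donor_idx[cell_codes] * n_var + var_codes
    n_keys = n_donor * n_var
    n_covered = np.bincount(key, minlength=n_keys)
    n_detected = np.bincount(key[detected], minlength=n_keys)
    n_spec = np.bincount(key[alt >= 1], minlength=n_keys)
    sum_vaf = np.bincount(key, weights=raw_vaf, minlength=n_keys)

    present = n_covered > 0
    keys = np.flatnonzero(present)
    d_idx, v_idx = keys // n_var, keys % n_var
    var_pos = np.array([int("".join(ch for ch in v if ch.isdigit())) for v in var_cats])
    mean_vaf = sum_vaf[keys] / n_covered[keys]
    detected_fraction = n_spec[keys] / n_covered[keys]
    keep = (
        (n_detected[keys] >= config.min_cells_detected)
        & (detected_fraction <= config.max_detected_fraction)
        & (mean_vaf <= config.max_mean_vaf)
        & ~np.isin(var_pos[v_idx], list(config.blacklist_positions))
    )
    stats = pd.DataFrame(
        {
            "donor_id": pd.Categorical.from_codes(d_idx, categories=donors),
            "variant_id": pd.Categorical.from_codes(v_idx, categories=var_cats),
            "position": var_pos[v_idx],
            "n_detected": n_detected[keys],
            "n_covered": n_covered[keys],
            "n_spec_detected": n_spec[keys],
            "mean_vaf": mean_vaf,
            "detected_fraction": detected_fraction,
            "informative": keep,
        }
    )

    kept_key = np.zeros(n_keys, dtype=bool)
    kept_key[keys[keep]] = True
    variants: dict[str, frozenset[str]] = {}
    donors_with_records = set(np.unique(cell_donor_idx[cell_codes]))
    for d, donor in enumerate(donors):
        vs = np.flatnonzero(kept_key[d * n_var : (d + 1) * n_var])
        variants[donor] = frozenset(var_cats[v] for v in vs)
        if d not in donors_with_records:
            warnings.warn(f"donor {donor!r} has no allele-count records", stacklevel=2)

    det_rows = detected & kept_key[key]
    detection = pd.DataFrame(
        {
            "donor_id": pd.Categorical.from_codes(
                cell_donor_idx[cell_codes[det_rows]], categories=donors
            ),
            "variant_id": pd.Categorical.from_codes(
                var_codes[det_rows], categories=var_cats
            ),
            "cell_id": pd.Categorical.from_codes(
                cell_codes[det_rows], categories=cell_cats
            ),
        }
    )
    return InformativeVariantSet(
        variants=variants,
        detection=detection,
        per_variant=stats,
        config=config,
    )


def export_vcf(
    ivs: InformativeVariantSet,
    ref_base_per_position: Mapping[int, str],
    directory: str | Path,
    genome_length: int = MT_GENOME_LENGTH,
) -> dict[str, Path]:
    """Write one VCF 4.2 file per donor (contig chrM, 1-based positions)."""
    if not ref_base_per_position:
        raise ValueError("empty reference map")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stats = ivs.per_variant.set_index(["donor_id", "variant_id"])
    out: dict[str, Path] = {}
    for donor, vs in ivs.variants.items():
        path = directory / f"{donor}.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID=chrM,length={genome_length}>",
            '##INFO=<ID=NDET,Number=1,Type=Integer,Description="Cells detecting the variant">',
            '##INFO=<ID=DETFRAC,Number=1,Type=Float,Description="Detected fraction over covered cells">',
            '##INFO=<ID=MEANVAF,Number=1,Type=Float,Description="Mean VAF over covered cells">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        def sort_key(v: str) -> tuple[int, str]:
            pos = int("".join(ch for ch in v if ch.isdigit()))
            return pos, v

        for v in sorted(vs, key=sort_key):
            row = stats.loc[(donor, v)]
            pos = int(row["position"])
            ref = ref_base_per_position[pos]
            alt = v.split(">")[-1]
            if ref == alt:
                raise ValueError(f"identical ref and alt for {v}")
            info = (
                f"NDET={int(row['n_detected'])};"
                f"DETFRAC={row['detected_fraction']:.6g};"
                f"MEANVAF={row['mean_vaf']:.6g}"
            )
            lines.append(f"chrM\t{pos}\t{v}\t{ref}\t{alt}\t.\tPASS\t{info}")
        path.write_text("\n".join(lines) + "\n")
        out[donor] = path
    return out
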