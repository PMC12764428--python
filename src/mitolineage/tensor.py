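"""Sparse per-cell mitochondrial allele counts and cell annotation tables.

The central container is :class:`AlleleCountTensor`, a long-format sparse map
``(cell_id, position, base) -> count`` over the 16,569 bp circular
mitochondrial reference (1-based positions, VCF convention).  Annotation
tables are plain :class:`pandas.DataFrame` objects with a fixed column
contract, validated by :func:`validate_annotations`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Length of the revised Cambridge reference mitochondrial genome.
MT_GENOME_LENGTH = 16_569

TISSUES = ("skin", "synovium", "blood")

ANNOTATION_COLUMNS = ("cell_id", "donor_id", "tissue", "lineage", "cluster")

COUNT_COLUMNS = ("cell_id", "position", "base", "count")


class ParseError(ValueError):
    """An on-disk table violates the format contract."""


class AlleleCountTensor:
    """Per-cell, per-position base counts.

    Construct either from a long-format DataFrame with columns
    ``cell_id, position, base, count`` (duplicate ``(cell, position, base)``
    rows are aggregated) or, via :meth:`from_dense`, from a dense
    ``cells x positions x 4`` array.  The long view is materialised lazily;
    positions must lie in ``[1, genome_length]``.
    """

    def __init__(self, counts: pd.DataFrame | None = None,
                 genome_length: int = MT_GENOME_LENGTH, *, _dense=None) -> None:
        self.genome_length = int(genome_length)
        self._long: pd.DataFrame | None = None
        self._dense = _dense
        if counts is None and _dense is None:
            raise ParseError("AlleleCountTensor needs a count table")
        if counts is not None:
            missing = set(COUNT_COLUMNS) - set(counts.columns)
            if missing:
                raise ParseError(f"count table lacks columns: {sorted(missing)}")
            df = counts.loc[:, list(COUNT_COLUMNS)].copy()
            self._check_rows(df, self.genome_length)
            df["position"] = df["position"].astype(np.int64)
            df["count"] = df["count"].astype(np.int64)
            if df.duplicated(["cell_id", "position", "base"]).any():
                df = (
                    df.groupby(["cell_id", "position", "base"], as_index=False,
                               sort=False, observed=True)["count"].sum()
                )
            self._long = df.reset_index(drop=True)

    @property
    def counts(self) -> pd.DataFrame:
        """Long-format view (``cell_id, position, base, count``)."""
        if self._long is None:
            cells, positions, arr = self._dense
            ci, pi, bi = np.nonzero(arr)
            self._long = pd.DataFrame(
                {
                    "cell_id": pd.Categorical.from_codes(ci, categories=list(cells)),
                    "position": np.asarray(positions)[pi],
                    "base": pd.Categorical.from_codes(bi, categories=list(BASES)),
                    "count": arr[ci, pi, bi],
                }
            )
        return self._long

    @staticmethod
    def _check_rows(df: pd.DataFrame, genome_length: int) -> None:
        bad = ~df["base"].isin(BASES)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"row {i}: unknown base {df['base'].iloc[i]!r}")
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = counts.isna() | (counts < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"row {i}: negative or non-numeric count {df['count'].iloc[i]!r}")
        pos = pd.to_numeric(df["position"], errors="coerce")
        bad = pos.isna() | (pos < 1) | (pos > genome_length)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"row {i}: position {df['position'].iloc[i]!r} outside [1, {genome_length}]"
            )

    # -- views -------------------------------------------------------------

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.to_dense()[0])

    @property
    def positions(self) -> np.ndarray:
        return np.asarray(self.to_dense()[1])

    def coverage(self) -> pd.DataFrame:
        """Total read depth per (cell, position): the sum of the four base counts."""
        cells, positions, arr = self.to_dense()
        cov = arr.sum(axis=2)
        ci, pi = np.nonzero(cov)
        return pd.DataFrame(
            {
                "cell_id": np.asarray(cells)[ci],
                "position": np.asarray(positions)[pi],
                "coverage": cov[ci, pi],
            }
        )

    def to_dense(self) -> tuple[pd.Index, np.ndarray, np.ndarray]:
        """Densify into a ``cells x positions x 4`` array of base counts.

        Cells are ordered as first seen (sorted when built from a long
        table); the dense view is cached.
        """
        if self._dense is None:
            df = self._long
            cell_index = pd.Index(sorted(df["cell_id"].unique()), name="cell_id")
            pos_index = np.sort(df["position"].unique())
            arr = np.zeros((len(cell_index), len(pos_index), 4), dtype=np.int64)
            ci = cell_index.get_indexer(df["cell_id"])
            pi = np.searchsorted(pos_index, df["position"].to_numpy())
            bi = df["base"].map(BASE_INDEX).to_numpy()
            np.add.at(arr, (ci, pi, bi), df["count"].to_numpy())
            self._dense = (cell_index, pos_index, arr)
        return self._dense

    @classmethod
    def from_dense(
        cls,
        cell_ids,
        positions,
        arr: np.ndarray,
        genome_length: int = MT_GENOME_LENGTH,
    ) -> "AlleleCountTensor":
        arr = np.asarray(arr)
        if (arr < 0).any():
            raise ParseError("negative counts in dense array")
        dense = (pd.Index(np.asarray(cell_ids), name="cell_id"),
                 np.asarray(positions), arr.astype(np.int64))
        return cls(genome_length=genome_length, _dense=dense)


# -- long CSV ----------------------------------------------------------------


def write_long_csv(tensor: AlleleCountTensor, path: str | Path) -> Path:
    path = Path(path)
    tensor.counts.to_csv(path, index=False)
    return path


def read_long_csv(path: str | Path, genome_length: int = MT_GENOME_LENGTH) -> AlleleCountTensor:
    df = pd.read_csv(path, dtype={"cell_id": str, "base": str})
    return AlleleCountTensor(df, genome_length=genome_length)


# -- matrix-triplet (MTX-style, one matrix per base) -------------------------


def write_mtx(tensor: AlleleCountTensor, directory: str | Path) -> Path:
    """Write one MatrixMarket triplet file per base plus barcode/position lists."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cells, positions, arr = tensor.to_dense()
    pd.Series(cells).to_csv(directory / "barcodes.tsv", index=False, header=False)
    pd.Series(positions).to_csv(directory / "positions.tsv", index=False, header=False)
    for bi, base in enumerate(BASES):
        m = scipy.sparse.coo_matrix(arr[:, :, bi])
        scipy.io.mmwrite(directory / f"matrix_{base}.mtx", m)
    return directory


def read_mtx(directory: str | Path, genome_length: int = MT_GENOME_LENGTH) -> AlleleCountTensor:
    directory = Path(directory)
    cells = pd.read_csv(directory / "barcodes.tsv", header=None)[0].astype(str).to_numpy()
    positions = pd.read_csv(directory / "positions.tsv", header=None)[0].astype(int).to_numpy()
    arr = np.zeros((len(cells), len(positions), 4), dtype=np.int64)
    for bi, base in enumerate(BASES):
        m = scipy.io.mmread(directory / f"matrix_{base}.mtx")
        arr[:, :, bi] = np.asarray(m.todense() if scipy.sparse.issparse(m) else m)
    return AlleleCountTensor.from_dense(cells, positions, arr, genome_length=genome_length)


# -- annotations -------------------------------------------------------------


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation table contract and return the validated frame.

    Required columns are ``cell_id, donor_id, tissue, lineage, cluster``;
    ``(donor_id, cell_id)`` must be unique, tissues must come from the
    declared vocabulary, and every cluster must map to exactly one lineage.
    """
    missing = set(ANNOTATION_COLUMNS) - set(annotations.columns)
    if missing:
        raise ParseError(f"annotation table lacks columns: {sorted(missing)}")
    if annotations.duplicated(["donor_id", "cell_id"]).any():
        dup = annotations[annotations.duplicated(["donor_id", "cell_id"])].iloc[0]
        raise ParseError(f"duplicate (donor_id, cell_id): {dup['donor_id']}/{dup['cell_id']}")
    bad = ~annotations["tissue"].isin(TISSUES)
    if bad.any():
        raise ParseError(f"unknown tissue {annotations.loc[bad, 'tissue'].iloc[0]!r}")
    lineages = annotations.groupby("cluster")["lineage"].nunique()
    multi = lineages[lineages > 1]
    if len(multi):
        raise ParseError(f"cluster mapped to multiple lineages: {multi.index[0]!r}")
    return annotations


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_annotations(annotations).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> pd.DataFrame:
    return validate_annotations(pd.read_csv(path, dtype=str))
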