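"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a light wrapper around a
sparse cells x features matrix that tracks what the features are (isoforms,
genes, TSS groups, equivalence classes, or a targeted gene panel) and what
normalization state the values are in.  Annotation tables (transcripts and
cells) are plain pandas DataFrames validated by the helpers below, in the
style of scanpy's ``.var``/``.obs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

FEATURE_LEVELS = ("isoform", "gene", "tss_group", "equivalence_class", "panel_gene")
STATES = ("raw_counts", "length_normalized", "tpm", "log1p", "scaled")

#: transcript annotation columns, in canonical order
ANNOTATION_COLUMNS = (
    "transcript_id",
    "gene_id",
    "length",
    "strand",
    "tss_coord",
    "tss_group",
    "end_group",
    "unique3p",
)

#: cell annotation columns (total_counts / mito_fraction filled by QC)
CELL_COLUMNS = (
    "cell_id",
    "class_label",
    "subclass_label",
    "cluster_label",
    "sex",
    "batch_date",
    "platform",
)


@dataclass
class ExpressionMatrix:
    """Cells x features matrix with identifier vectors and state tracking.

    Parameters
    ----------
    values
        Sparse (CSR) or dense array, cells in rows, features in columns.
    cell_ids, feature_ids
        Unique identifier sequences matching the matrix dimensions.
    feature_level
        One of ``isoform``, ``gene``, ``tss_group``, ``equivalence_class``,
        ``panel_gene``.
    state
        One of ``raw_counts``, ``length_normalized``, ``tpm``, ``log1p``,
        ``scaled``.
    """

    values: sp.csr_matrix
    cell_ids: pd.Index
    feature_ids: pd.Index
    feature_level: str = "isoform"
    state: str = "raw_counts"

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsr()
        self.cell_ids = pd.Index(self.cell_ids)
        self.feature_ids = pd.Index(self.feature_ids)
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        if not self.feature_ids.is_unique:
            dup = self.feature_ids[self.feature_ids.duplicated()].tolist()[:5]
            raise ValueError(f"feature_ids not unique, e.g. {dup}")
        if self.feature_level not in FEATURE_LEVELS:
            raise ValueError(f"unknown feature_level {self.feature_level!r}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "raw_counts" and self.values.nnz and self.values.data.min() < 0:
            raise ValueError("raw_counts state requires nonnegative values")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=float)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    # -- subsetting --------------------------------------------------------
    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        idx = self._resolve(mask_or_ids, self.cell_ids)
        return replace(self, values=self.values[idx], cell_ids=self.cell_ids[idx])

    def subset_features(self, mask_or_ids) -> "ExpressionMatrix":
        idx = self._resolve(mask_or_ids, self.feature_ids)
        return replace(
            self, values=self.values[:, idx].tocsr(), feature_ids=self.feature_ids[idx]
        )

    @staticmethod
    def _resolve(sel, index: pd.Index) -> np.ndarray:
        sel = np.asarray(sel)
        if sel.dtype == bool:
            if sel.shape[0] != len(index):
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(sel)
        if sel.dtype.kind in "iu":
            return sel
        locs = index.get_indexer(sel)
        if (locs < 0).any():
            missing = np.asarray(sel)[locs < 0][:5].tolist()
            raise KeyError(f"ids not found: {missing}")
        return locs

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy())


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a transcript annotation table and return it indexed by transcript.

    Checks lengths >= 1, TSS groups consistent with (gene, tss_coord, strand)
    sharing, and that no TSS group spans two genes.
    """
    ann = ann.copy()
    if ann.index.name != "transcript_id":
        if "transcript_id" not in ann.columns:
            raise ValueError("annotation needs a transcript_id column or index")
        ann = ann.set_index("transcript_id")
    missing = [c for c in ANNOTATION_COLUMNS[1:] if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if (ann["length"] < 1).any():
        bad = ann.index[ann["length"] < 1].tolist()[:5]
        raise ValueError(f"transcript lengths < 1: {bad}")
    spans = ann.groupby("tss_group")["gene_id"].nunique()
    if (spans > 1).any():
        raise ValueError(f"tss_group spans genes: {spans[spans > 1].index.tolist()[:5]}")
    per_site = ann.groupby(["gene_id", "tss_coord", "strand"])["tss_group"].nunique()
    if (per_site > 1).any():
        raise ValueError("transcripts sharing (gene, tss_coord, strand) differ in tss_group")
    return ann


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell annotation table (hierarchy and mito bounds) and index it."""
    cells = cells.copy()
    if cells.index.name != "cell_id":
        if "cell_id" not in cells.columns:
            raise ValueError("cell table needs a cell_id column or index")
        cells = cells.set_index("cell_id")
    # cluster within subclass within class: each finer label maps to one coarser
    for fine, coarse in (("cluster_label", "subclass_label"), ("subclass_label", "class_label")):
        if fine in cells.columns and coarse in cells.columns:
            n = cells.groupby(fine)[coarse].nunique()
            if (n > 1).any():
                raise ValueError(f"{fine} values map to multiple {coarse} values")
    if "mito_fraction" in cells.columns:
        mf = cells["mito_fraction"].dropna()
        if ((mf < 0) | (mf > 1)).any():
            raise ValueError("mito_fraction outside [0, 1]")
    return cells


def strip_version(feature_ids: Iterable[str]) -> pd.Index:
    """Version-stripped aliases (``ENSMUST...​.3`` -> ``ENSMUST...``) for
    joining features across annotation releases."""
    return pd.Index([fid.rsplit(".", 1)[0] if "." in fid else fid for fid in feature_ids])
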