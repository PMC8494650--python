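"""Cluster-vs-complement differential testing and isoform-shift detection.

The central statistic is a two-sided t-test per feature between a cell
group and its complement on log1p-normalized values, Bonferroni-corrected
within each group comparison at alpha = 0.01.  On top of it sit:

* **gene-constant shift detection** — isoforms upregulated in a group whose
  parent gene is *not* differential: isoform expression shifts invisible to
  gene-level analysis;
* **marker detection** — upregulated isoforms regardless of gene behaviour;
* **sex-differential analysis** — male-vs-female tests within subclasses;
* **TSS-group regulation classification** — TSS-differential with constant
  members (transcriptional / promoter usage) versus member-differential with
  constant TSS totals (post-transcriptional / splicing).

All result tables share the MarkerTable schema (one row per feature x
group) and are ordinary pandas DataFrames.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .preprocess import aggregate_genes
from .stats import bonferroni, ttest_matrix

logger = logging.getLogger(__name__)

MARKER_COLUMNS = [
    "feature_id",
    "feature_level",
    "ontology_level",
    "group",
    "mean_in",
    "mean_out",
    "t_statistic",
    "p_raw",
    "p_adj",
    "expressed_fraction_in",
    "category",
]

LEVEL_COLUMN = {
    "class": "class_label",
    "subclass": "subclass_label",
    "cluster": "cluster_label",
}


def _labels_at(labels, level: str) -> pd.Series:
    if isinstance(labels, pd.DataFrame):
        col = LEVEL_COLUMN.get(level)
        if col not in labels.columns:
            raise ValueError(f"cell table has no {col!r} column for level {level!r}")
        return labels[col]
    return pd.Series(labels)


def cluster_vs_rest_test(
    m: ExpressionMatrix,
    labels,
    level: str = "cluster",
    min_cells: int = 6,
    equal_var: bool = True,
) -> pd.DataFrame:
    """t-test every feature between each group and its complement.

    ``m`` should hold log1p-normalized values.  ``labels`` is either a
    per-cell label Series (aligned to ``m.cell_ids``) or a cell annotation
    DataFrame from which the ``level`` column is taken.  Groups with fewer
    than ``min_cells`` cells are skipped with a warning, mirroring the
    more-than-5-cells rule.  The Bonferroni family is the number of features
    tested within one group comparison.
    """
    lab = _labels_at(labels, level).reindex(m.cell_ids)
    if lab.isna().any():
        raise ValueError(f"{int(lab.isna().sum())} cells missing a {level} label")
    dense = m.dense()
    rows = []
    for group in pd.unique(lab):
        in_mask = (lab == group).to_numpy()
        n_in = int(in_mask.sum())
        if n_in < min_cells:
            logger.warning("group %r has %d < %d cells; skipped", group, n_in, min_cells)
            continue
        if n_in == len(lab):
            logger.warning("group %r has an empty complement; skipped", group)
            continue
        x, y = dense[in_mask], dense[~in_mask]
        t, p = ttest_matrix(x, y, equal_var=equal_var)
        rows.append(pd.DataFrame({
            "feature_id": m.feature_ids,
            "feature_level": m.feature_level,
            "ontology_level": level,
            "group": group,
            "mean_in": x.mean(axis=0),
            "mean_out": y.mean(axis=0),
            "t_statistic": t,
            "p_raw": p,
            "p_adj": bonferroni(p),
            "expressed_fraction_in": (x > 0).mean(axis=0),
            "category": "test",
        }))
    if not rows:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    return pd.concat(rows, ignore_index=True)[MARKER_COLUMNS]


def detect_gene_constant_shifts(
    iso_tests: pd.DataFrame,
    gene_tests: pd.DataFrame,
    gene_map: pd.Series,
    expressed_fraction: float = 0.9,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Isoforms upregulated in a group whose parent gene is not differential.

    Reports isoform i for group g iff the isoform is Bonferroni-significant
    and upregulated (mean_in > mean_out), expressed in at least
    ``expressed_fraction`` of the group's cells, and the parent gene's
    adjusted p-value is >= alpha in the same comparison.
    """
    iso = iso_tests.copy()
    iso["gene_id"] = gene_map.reindex(iso["feature_id"]).to_numpy()
    if iso["gene_id"].isna().any():
        bad = iso.loc[iso["gene_id"].isna(), "feature_id"].unique().tolist()[:10]
        raise ValueError(f"isoforms without a gene mapping: {bad}")
    gene_p = gene_tests.set_index(["feature_id", "group"])["p_adj"]
    key = pd.MultiIndex.from_frame(iso[["gene_id", "group"]])
    parent_p = gene_p.reindex(key).to_numpy()
    if np.isnan(parent_p).any():
        bad = iso.loc[np.isnan(parent_p), "gene_id"].unique().tolist()[:10]
        raise ValueError(f"isoforms whose parent gene was not tested: {bad}")
    keep = (
        (iso["p_adj"] < alpha)
        & (iso["mean_in"] > iso["mean_out"])
        & (iso["expressed_fraction_in"] >= expressed_fraction)
        & (parent_p >= alpha)
    )
    out = iso.loc[keep, MARKER_COLUMNS].reset_index(drop=True)
    out["category"] = "gene_constant_shift"
    return out


def detect_markers(
    iso_tests: pd.DataFrame,
    expressed_fraction: float = 0.9,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Upregulated significant isoforms regardless of gene expression."""
    keep = (
        (iso_tests["p_adj"] < alpha)
        & (iso_tests["mean_in"] > iso_tests["mean_out"])
        & (iso_tests["expressed_fraction_in"] >= expressed_fraction)
    )
    out = iso_tests.loc[keep, MARKER_COLUMNS].reset_index(drop=True)
    out["category"] = "marker"
    return out


def sex_differential(
    m: ExpressionMatrix,
    cells: pd.DataFrame,
    level: str = "subclass",
    exclusions: set[str] = frozenset(),
    alpha: float = 0.01,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Male-vs-female t-tests within each (non-excluded) subclass.

    Bonferroni correction is applied within each subclass.  Subclasses in
    ``exclusions`` (e.g. one confounded with batch) are skipped, as are
    subclasses with fewer than ``min_cells`` cells of either sex.
    """
    lab = _labels_at(cells, level).reindex(m.cell_ids)
    sex = cells["sex"].reindex(m.cell_ids)
    dense = m.dense()
    rows = []
    for group in pd.unique(lab):
        if group in exclusions:
            continue
        in_group = (lab == group).to_numpy()
        male = in_group & (sex == "M").to_numpy()
        female = in_group & (sex == "F").to_numpy()
        if male.sum() < min_cells or female.sum() < min_cells:
            logger.warning("subclass %r lacks cells of one sex; skipped", group)
            continue
        x, y = dense[male], dense[female]
        t, p = ttest_matrix(x, y)
        rows.append(pd.DataFrame({
            "feature_id": m.feature_ids,
            "feature_level": m.feature_level,
            "ontology_level": level,
            "group": group,
            "mean_in": x.mean(axis=0),
            "mean_out": y.mean(axis=0),
            "t_statistic": t,
            "p_raw": p,
            "p_adj": bonferroni(p),
            "expressed_fraction_in": (dense[in_group] > 0).mean(axis=0),
            "category": "sex_differential",
        }))
    if not rows:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    tab = pd.concat(rows, ignore_index=True)[MARKER_COLUMNS]
    return tab[tab["p_adj"] < alpha].reset_index(drop=True)


def build_tss_matrix(m: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Sum raw isoform counts within each TSS group, per cell."""
    groups = annotation["tss_group"].reindex(m.feature_ids)
    if groups.isna().any():
        raise ValueError(
            f"isoforms without a tss_group: {m.feature_ids[groups.isna()].tolist()[:10]}"
        )
    out = aggregate_genes(m, groups)
    out.feature_level = "tss_group"
    return out


def classify_regulation(
    tss_tests: pd.DataFrame,
    iso_tests: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Classify TSS groups as transcriptional vs post-transcriptional.

    For each (TSS group, class group) pair:

    * ``tss_transcriptional`` — the TSS group is differential while *every*
      member isoform individually is not: the whole promoter's output moves
      together (differential promoter usage);
    * ``tss_post_transcriptional`` — one row per member isoform that is
      differential while the TSS group total is not: composition shifts
      within a promoter (differential splicing).

    The two categories are mutually exclusive for a given (TSS group, group)
    by construction.  Returns MarkerTable rows with a ``tss_group`` column.
    """
    members_of = annotation.groupby("tss_group").groups
    iso_idx = iso_tests.set_index(["feature_id", "group"])
    tss_idx = tss_tests.set_index(["feature_id", "group"])
    rows = []
    for (tss_id, group), tss_row in tss_idx.iterrows():
        if tss_id not in members_of:
            continue
        members = list(members_of[tss_id])
        try:
            member_rows = iso_idx.loc[[(t, group) for t in members]]
        except KeyError as err:
            raise ValueError(
                f"TSS group {tss_id!r} member missing from isoform tests: {err}"
            ) from None
        member_sig = member_rows["p_adj"].to_numpy() < alpha
        tss_sig = tss_row["p_adj"] < alpha
        if tss_sig and not member_sig.any():
            row = tss_row.copy()
            row["feature_id"] = tss_id
            row["group"] = group
            row["category"] = "tss_transcriptional"
            row["tss_group"] = tss_id
            rows.append(row)
        elif not tss_sig and member_sig.any():
            for (tid, _), mrow in member_rows[member_sig].iterrows():
                row = mrow.copy()
                row["feature_id"] = tid
                row["group"] = group
                row["category"] = "tss_post_transcriptional"
                row["tss_group"] = tss_id
                rows.append(row)
    if not rows:
        return pd.DataFrame(columns=MARKER_COLUMNS + ["tss_group"])
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out[MARKER_COLUMNS + ["tss_group"]]
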