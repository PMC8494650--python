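"""Cross-technology concordance and batch-effect diagnostics.

Different single-cell assays (full-length plate-based, 3'-end droplet,
imaging-based panels) should agree on the mean expression profile of a cell
type.  :func:`cluster_correlation` quantifies that agreement per ontology
group; the batch helpers check whether assay batches mix uniformly across
clusters and whether pseudo-bulk profiles correlate across batches.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .diffexp import _labels_at
from .preprocess import log1p, scale, to_tpm
from .stats import pearson

logger = logging.getLogger(__name__)


def cluster_correlation(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    level: str = "subclass",
    presence_fraction: float = 0.5,
) -> pd.DataFrame:
    """Pearson correlation of per-group mean cells across two platforms.

    Pipeline (executed in this order on raw counts): restrict both matrices
    to the common feature set; normalize each cell to one million; log1p;
    scale each feature to zero mean / unit variance per platform.  Within
    each group, restrict to features with raw count > 0 in at least
    ``presence_fraction`` of the group's cells on *both* platforms, average
    the scaled profiles into a mean cell per platform, and correlate.

    Groups absent from either platform are skipped with a warning; groups
    with fewer than 2 usable features get ``r = NaN``.
    """
    common = a.feature_ids.intersection(b.feature_ids)
    if len(common) == 0:
        raise ValueError("no common features between the two matrices")
    a_raw = a.subset_features(common.to_numpy(dtype=object))
    b_raw = b.subset_features(common.to_numpy(dtype=object))
    a_scaled = scale(log1p(to_tpm(a_raw))).dense()
    b_scaled = scale(log1p(to_tpm(b_raw))).dense()
    a_pres = (a_raw.dense() > 0)
    b_pres = (b_raw.dense() > 0)

    lab_a = _labels_at(cells_a, level).reindex(a.cell_ids)
    lab_b = _labels_at(cells_b, level).reindex(b.cell_ids)
    groups_a, groups_b = set(lab_a.dropna()), set(lab_b.dropna())
    rows = []
    for group in sorted(groups_a | groups_b, key=str):
        if group not in groups_a or group not in groups_b:
            logger.warning("group %r absent from one platform; skipped", group)
            continue
        ma = (lab_a == group).to_numpy()
        mb = (lab_b == group).to_numpy()
        ok = (
            (a_pres[ma].mean(axis=0) >= presence_fraction)
            & (b_pres[mb].mean(axis=0) >= presence_fraction)
        )
        n_feat = int(ok.sum())
        if n_feat < 2:
            logger.warning("group %r has < 2 features passing presence; r undefined", group)
            r = float("nan")
        else:
            r = pearson(a_scaled[ma][:, ok].mean(axis=0), b_scaled[mb][:, ok].mean(axis=0))
        rows.append({
            "group": group,
            "r": r,
            "n_features": n_feat,
            "n_cells_a": int(ma.sum()),
            "n_cells_b": int(mb.sum()),
        })
    return pd.DataFrame(rows, columns=["group", "r", "n_features", "n_cells_a", "n_cells_b"])


def batch_mixing_check(cells: pd.DataFrame, by: str = "batch_date") -> pd.DataFrame:
    """Observed vs expected batch fractions per cluster under uniform mixing.

    Expected fraction of a batch within every cluster is its global share of
    cells; deviation = observed - expected.  The per-cluster deviations sum
    to zero across batches.  ``attrs['max_abs_deviation']`` summarizes.
    """
    if by not in cells.columns or "cluster_label" not in cells.columns:
        raise ValueError(f"cell table needs {by!r} and cluster_label columns")
    global_share = cells[by].value_counts(normalize=True)
    rows = []
    for cluster, sub in cells.groupby("cluster_label"):
        obs = sub[by].value_counts(normalize=True)
        for batch, expected in global_share.items():
            observed = float(obs.get(batch, 0.0))
            rows.append({
                "cluster": cluster,
                "batch": batch,
                "observed_fraction": observed,
                "expected_fraction": float(expected),
                "deviation": observed - float(expected),
            })
    out = pd.DataFrame(rows)
    out.attrs["max_abs_deviation"] = float(out["deviation"].abs().max()) if len(out) else 0.0
    return out


def batch_pairwise_correlation(
    m: ExpressionMatrix,
    cells: pd.DataFrame,
    by: str = "batch_date",
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-batch pseudo-bulk gene profiles.

    Each batch's profile is the mean over its cells of log1p per-cell
    normalized (to 1e6) values.  Batches with no cells are excluded.
    ``attrs['mean_off_diagonal']`` holds the mean off-diagonal r.
    """
    batch = cells[by].reindex(m.cell_ids)
    norm = log1p(to_tpm(m)).dense()
    profiles = {}
    for b in pd.unique(batch.dropna()):
        mask = (batch == b).to_numpy()
        if mask.sum() == 0:
            continue
        profiles[b] = norm[mask].mean(axis=0)
    names = sorted(profiles, key=str)
    if len(names) < 2:
        raise ValueError("need at least 2 non-empty batches")
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, bi in enumerate(names):
        for bj in names[i + 1:]:
            rij = pearson(profiles[bi], profiles[bj])
            r.loc[bi, bj] = r.loc[bj, bi] = rij
    off = r.to_numpy()[~np.eye(len(names), dtype=bool)]
    r.attrs["mean_off_diagonal"] = float(np.nanmean(off))
    return r
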