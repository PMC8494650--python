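"""Spatial marker analysis, isoform extrapolation, and cortical depth models.

Imaging-based spatial assays (MERFISH) measure a targeted gene panel with
cell positions but no isoform resolution.  This module (1) finds subclass
marker genes in the spatial data, (2) joins them with full-length
(SMART-seq) isoform markers to extrapolate isoform identity onto the
spatial map, and (3) models cortical depth: a pial boundary line fitted to
the upper convex hull of a slice, per-subclass normalized perpendicular
centroid depths, and per-isoform weighted least-squares regression of
expression on depth with an F-test and a monotonicity check.

Coordinate convention: y increases downward from the pial surface, so the
"upper" boundary is the low-y side of the hull.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import ConvexHull, QhullError

from .containers import ExpressionMatrix
from .diffexp import cluster_vs_rest_test, detect_markers
from .stats import bonferroni

logger = logging.getLogger(__name__)


@dataclass
class DepthModel:
    """Fitted pial boundary line and per-subclass normalized depths.

    The line is stored in normalized general form a*x + b*y + c = 0 with
    a^2 + b^2 = 1, so it survives rigid motions (including rotations that
    make the line vertical); ``slope``/``intercept`` are derived views.
    """

    line: tuple[float, float, float]
    boundary_points: np.ndarray
    subclass_centroids: dict[str, tuple[float, float]] = field(default_factory=dict)
    depths: dict[str, float] = field(default_factory=dict)

    @property
    def slope(self) -> float:
        a, b, _ = self.line
        return float("inf") if b == 0 else -a / b

    @property
    def intercept(self) -> float:
        a, b, c = self.line
        return float("inf") if b == 0 else -c / b

    def distance(self, x, y) -> np.ndarray:
        a, b, c = self.line
        return np.abs(a * np.asarray(x) + b * np.asarray(y) + c)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "DepthModel":
        """The same physical boundary in rigidly moved coordinates.

        ``rotation`` is a 2x2 orthogonal matrix, ``translation`` a 2-vector;
        points transform as ``p' = R p + t``.
        """
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        a, b, c = self.line
        n_new = rotation @ np.array([a, b])
        c_new = c - float(n_new @ translation)
        pts = self.boundary_points @ rotation.T + translation
        centroids = {
            s: tuple(rotation @ np.array(p) + translation)
            for s, p in self.subclass_centroids.items()
        }
        return DepthModel(
            line=(float(n_new[0]), float(n_new[1]), c_new),
            boundary_points=pts,
            subclass_centroids=centroids,
            depths=dict(self.depths),
        )


def merfish_subclass_markers(
    panel: ExpressionMatrix,
    cells: pd.DataFrame,
    alpha: float = 0.01,
    min_cells: int = 6,
) -> pd.DataFrame:
    """Subclass-vs-complement marker genes in the spatial panel.

    ``panel`` must be normalized (per-cell to 1e6, log1p) — the same test
    machinery as the scRNA-seq marker analysis, upregulated results only.
    No expressed-fraction filter is applied: panel genes are targeted and
    near-ubiquitously detected.
    """
    tests = cluster_vs_rest_test(panel, cells, level="subclass", min_cells=min_cells)
    return detect_markers(tests, expressed_fraction=0.0, alpha=alpha)


def extrapolate_isoforms(
    merfish_markers: pd.DataFrame,
    smartseq_iso_markers: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Join spatial gene markers with full-length isoform markers.

    One row per (subclass, spatial marker gene, isoform marker of that gene
    in the same subclass); genes with no isoform marker in that subclass
    keep a row with an empty isoform field.  Gene ids must be resolvable
    through the annotation.
    """
    known_genes = set(annotation["gene_id"])
    iso = smartseq_iso_markers.copy()
    iso["gene_id"] = annotation["gene_id"].reindex(iso["feature_id"]).to_numpy()
    rows = []
    for _, mrow in merfish_markers.iterrows():
        gene, subclass = mrow["feature_id"], mrow["group"]
        if gene not in known_genes:
            raise ValueError(f"spatial marker gene {gene!r} absent from annotation")
        hits = iso[(iso["gene_id"] == gene) & (iso["group"] == subclass)]
        if hits.empty:
            rows.append((subclass, gene, "", mrow["p_adj"], np.nan))
        else:
            for _, irow in hits.iterrows():
                rows.append((subclass, gene, irow["feature_id"], mrow["p_adj"], irow["p_adj"]))
    return pd.DataFrame(
        rows, columns=["subclass", "gene_id", "isoform_id", "merfish_p_adj", "smartseq_p_adj"]
    )


def fit_boundary(spatial: pd.DataFrame) -> DepthModel:
    """Fit the pial boundary line to the upper convex hull of one slice.

    The convex hull of all cell positions is computed; hull edges whose
    outward normal points toward decreasing y (the pial side) contribute
    their vertices to the upper boundary; an ordinary least-squares line is
    fitted through those vertices.
    """
    pts = spatial[["x", "y"]].to_numpy(dtype=float)
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("need at least 3 distinct cell positions")
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise ValueError(f"degenerate (collinear?) cell positions: {err}") from None
    # hull.equations rows are [a, b, c] with outward normal (a, b)
    upper: set[int] = set()
    for simplex, eq in zip(hull.simplices, hull.equations):
        if eq[1] < 0:
            upper.update(simplex)
    boundary = pts[sorted(upper)]
    if len(boundary) < 2:
        raise ValueError("could not identify an upper boundary")
    X = sm.add_constant(boundary[:, 0])
    fit = sm.OLS(boundary[:, 1], X).fit()
    m, b = float(fit.params[1]), float(fit.params[0])
    norm = float(np.hypot(m, 1.0))
    return DepthModel(
        line=(m / norm, -1.0 / norm, b / norm),
        boundary_points=boundary,
    )


def subclass_depths(
    spatial: pd.DataFrame,
    cells: pd.DataFrame,
    model: DepthModel,
    subclasses: list[str] | None = None,
) -> DepthModel:
    """Normalized perpendicular centroid depths per subclass.

    Centroid = coordinate-wise mean of the subclass's cells; depth = its
    perpendicular distance to the boundary line, divided by the largest
    such distance (so the deepest subclass has depth exactly 1).
    """
    sub = cells["subclass_label"].reindex(pd.Index(spatial["cell_id"]))
    labels = subclasses if subclasses is not None else list(pd.unique(sub.dropna()))
    if len(labels) == 1:
        logger.warning("single subclass: its depth is 1 by normalization")
    centroids, dist = {}, {}
    for s in labels:
        pts = spatial.loc[(sub == s).to_numpy(), ["x", "y"]].to_numpy(dtype=float)
        if len(pts) == 0:
            raise ValueError(f"subclass {s!r} has no cells in this slice")
        cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
        centroids[s] = (float(cx), float(cy))
        dist[s] = float(model.distance(cx, cy))
    dmax = max(dist.values())
    if dmax == 0:
        raise ValueError("all subclass centroids lie on the boundary line")
    model.subclass_centroids = centroids
    model.depths = {s: d / dmax for s, d in dist.items()}
    return model


def representative_slice(spatial: pd.DataFrame) -> str:
    """Slice with the most cells (default representative-slice rule)."""
    return spatial["slice_id"].value_counts().idxmax()


def depth_regression(
    m: ExpressionMatrix,
    cells: pd.DataFrame,
    model: DepthModel,
    alpha: float = 0.01,
    slope_threshold: float = 1.5,
    expressed_fraction: float = 0.9,
    weights: str = "inverse_variance",
) -> pd.DataFrame:
    """Per-feature weighted least-squares of subclass mean expression on depth.

    Only features with nonzero expression in >= ``expressed_fraction`` of
    the cells of *every* subclass are tested.  The response is the
    per-subclass mean of the supplied values; the regressor is the subclass
    depth from ``model``.  ``weights`` is one of:

    * ``"inverse_variance"`` — 1 / per-subclass variance (standard WLS,
      the default);
    * ``"variance"`` — the per-subclass variance itself (the literal
      upweight-the-noisy choice; kept for comparability);
    * ``"equal"`` — unweighted (reduces to OLS).

    Zero-variance subclasses get the largest finite weight of that feature
    (equal weights when all variances vanish).  The slope F-test p-values
    are Bonferroni-corrected across tested features; monotonicity of the
    subclass means in depth order is evaluated only when |slope| >
    ``slope_threshold`` (strict monotonicity; ties break it).
    """
    if weights not in ("inverse_variance", "variance", "equal"):
        raise ValueError(f"unknown weights scheme {weights!r}")
    subs = list(model.depths)
    if len(subs) < 3:
        raise ValueError("need >= 3 subclasses with depths for the regression")
    depth = np.array([model.depths[s] for s in subs])
    order = np.argsort(depth)
    sub_label = cells["subclass_label"].reindex(m.cell_ids)
    dense = m.dense()
    masks = [(sub_label == s).to_numpy() for s in subs]
    if any(mask.sum() == 0 for mask in masks):
        raise ValueError("a subclass with a depth has no cells in the matrix")

    means = np.vstack([dense[mask].mean(axis=0) for mask in masks])
    variances = np.vstack([dense[mask].var(axis=0, ddof=1) for mask in masks])
    frac = np.vstack([(dense[mask] > 0).mean(axis=0) for mask in masks])
    testable = (frac >= expressed_fraction).all(axis=0)

    X = sm.add_constant(depth)
    rows = []
    for j in np.flatnonzero(testable):
        y = means[:, j]
        v = variances[:, j]
        if weights == "equal":
            w = np.ones_like(v)
        elif weights == "variance":
            w = v.copy()
            if (w == 0).any():
                w[w == 0] = w[w > 0].min() if (w > 0).any() else 1.0
        else:
            w = np.empty_like(v)
            pos = v > 0
            w[pos] = 1.0 / v[pos]
            w[~pos] = w[pos].max() if pos.any() else 1.0
        fit = sm.WLS(y, X, weights=w).fit()
        slope = float(fit.params[1])
        monotonic: bool | None = None
        if abs(slope) > slope_threshold:
            ordered = y[order]
            diffs = np.diff(ordered)
            monotonic = bool((diffs > 0).all() or (diffs < 0).all())
        rows.append({
            "isoform_id": m.feature_ids[j],
            "slope": slope,
            "slope_se": float(fit.bse[1]),
            "intercept": float(fit.params[0]),
            "F_p_raw": float(fit.f_pvalue),
            "monotonic": monotonic,
            "subclass_means": means[:, j].copy(),
            "subclass_variances": variances[:, j].copy(),
        })
    columns = ["isoform_id", "slope", "slope_se", "intercept", "F_p_raw", "F_p_adj",
               "monotonic", "subclass_means", "subclass_variances"]
    if not rows:
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows)
    out["F_p_adj"] = bonferroni(out["F_p_raw"].to_numpy())
    return out[columns]
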