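"""Normalization, filtering and aggregation of isoform count matrices.

Implements the full-length (SMART-seq-style) path — length normalization,
dispersion-based feature filtering, cell QC, TPM / log1p / scaling — and the
3'-end (10x-style) path — extraction of isoform counts from transcript
compatibility counts (TCCs) restricted to singleton equivalence classes —
plus highly-variable-feature selection and the naive-vs-length-normalized
gene quantification comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ExpressionMatrix


def length_normalize(m: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Divide each isoform's counts by its transcript length.

    Full-length protocols sample reads along the whole transcript, so raw
    counts over-represent long isoforms; dividing by length makes values
    proportional to molecule copy number.
    """
    missing = m.feature_ids.difference(annotation.index)
    if len(missing):
        raise ValueError(f"no length for transcripts: {missing.tolist()[:10]}")
    lengths = annotation.loc[m.feature_ids, "length"].to_numpy(dtype=float)
    values = m.values @ sp.diags(1.0 / lengths)
    return replace(m, values=values.tocsr(), state="length_normalized")


def filter_features(
    m: ExpressionMatrix,
    gene_map: pd.Series,
    min_count: float = 1.0,
    min_cells: int = 1,
    min_dispersion: float = 0.001,
) -> ExpressionMatrix:
    """Drop weakly expressed isoforms and low-dispersion genes.

    Isoforms with total count < ``min_count`` or expressed (value > 0) in
    fewer than ``min_cells`` cells are removed.  Gene-level dispersion
    (variance / mean of summed isoform values across cells) is then
    computed, and genes below ``min_dispersion`` are dropped together with
    all of their isoforms.
    """
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    n_expressed = np.asarray((m.values > 0).sum(axis=0)).ravel()
    keep = (totals >= min_count) & (n_expressed >= min_cells)
    out = m.subset_features(keep)

    genes = gene_map.reindex(out.feature_ids)
    if genes.isna().any():
        raise ValueError(f"isoforms without a gene: {out.feature_ids[genes.isna()].tolist()[:10]}")
    gsum = aggregate_genes(out, genes)
    dense = gsum.dense()
    mean = dense.mean(axis=0)
    var = dense.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    good_genes = set(gsum.feature_ids[dispersion >= min_dispersion])
    out = out.subset_features(genes.isin(good_genes).to_numpy())
    if out.n_features == 0:
        raise ValueError(
            "no features survive filtering; lower min_count/min_cells/min_dispersion"
        )
    return out


def filter_cells(
    m: ExpressionMatrix,
    min_counts: int = 250,
    max_mito: float = 0.10,
    mito_prefix: str = "mt-",
) -> tuple[ExpressionMatrix, pd.Index]:
    """Remove low-count and high-mitochondrial cells.

    Cells with total < ``min_counts`` or mitochondrial fraction >
    ``max_mito`` are removed; boundary values are kept.  Mitochondrial
    features are identified by ``mito_prefix`` on the feature id.
    """
    totals = m.cell_totals()
    is_mito = np.asarray(m.feature_ids.str.startswith(mito_prefix))
    mito_counts = np.asarray(m.values[:, is_mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
    keep = (totals >= min_counts) & (mito_frac <= max_mito)
    kept = m.subset_cells(keep)
    return kept, kept.cell_ids


def aggregate_genes(m: ExpressionMatrix, gene_map: pd.Series) -> ExpressionMatrix:
    """Sum isoform values per gene, per cell (totals conserved)."""
    genes = gene_map.reindex(m.feature_ids)
    if genes.isna().any():
        raise ValueError(f"unmapped isoforms: {m.feature_ids[genes.isna()].tolist()[:10]}")
    gene_ids = pd.Index(pd.unique(genes))
    pos = {g: j for j, g in enumerate(gene_ids)}
    cols = np.array([pos[g] for g in genes])
    routing = sp.csr_matrix(
        (np.ones(len(cols)), (np.arange(len(cols)), cols)),
        shape=(len(cols), len(gene_ids)),
    )
    return ExpressionMatrix(
        values=(m.values @ routing).tocsr(),
        cell_ids=m.cell_ids,
        feature_ids=gene_ids,
        feature_level="gene",
        state=m.state,
    )


def to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize each cell to one million (TPM / CPM depending on input)."""
    totals = m.cell_totals()
    if (totals == 0).any():
        zero = m.cell_ids[totals == 0].tolist()[:10]
        raise ValueError(f"cells with zero total (filter first): {zero}")
    values = sp.diags(1e6 / totals) @ m.values
    return replace(m, values=values.tocsr(), state="tpm")


def log1p(m: ExpressionMatrix) -> ExpressionMatrix:
    values = m.values.copy()
    values.data = np.log1p(values.data)
    return replace(m, values=values, state="log1p")


def scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each feature to zero mean, unit variance (dense output).

    Zero-variance features become all-zero columns.
    """
    dense = m.dense()
    mean = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    scaled = (dense - mean) / sd_safe
    scaled[:, sd == 0] = 0.0
    return replace(m, values=sp.csr_matrix(scaled), state="scaled")


def normalize_log_scale(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """The staged normalization: per-cell to 1e6, log1p, per-feature scaling.

    Returns all three stages ``(tpm, log1p, scaled)`` since downstream steps
    consume different stages (t-tests use log1p, projections use scaled).
    """
    t = to_tpm(m)
    l = log1p(t)
    return t, l, scale(l)


def select_hvg(m: ExpressionMatrix, n_top: int = 5000, n_bins: int = 20) -> pd.Index:
    """Rank features by dispersion z-scored within mean-expression bins.

    Dispersion = variance / mean of the supplied (log1p) values.  Features
    are placed into ``n_bins`` equal-frequency bins by mean expression; each
    feature's dispersion is z-scored against the dispersions in its bin
    (subtract the bin mean, divide by the bin standard deviation, as in the
    seurat-flavor selector); the top ``n_top`` by normalized dispersion are
    returned (all features, ranked, when fewer than ``n_top`` exist).
    Single-feature and zero-variance bins get normalized dispersion 0.
    """
    if m.n_features < n_bins:
        raise ValueError(f"need >= {n_bins} features, got {m.n_features}")
    dense = m.dense()
    mean = dense.mean(axis=0)
    var = dense.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)

    order = np.argsort(mean, kind="stable")
    bins = np.empty(m.n_features, dtype=int)
    bins[order] = (np.arange(m.n_features) * n_bins) // m.n_features
    z = np.zeros(m.n_features)
    for b in np.unique(bins):
        members = bins == b
        d = dispersion[members]
        if members.sum() < 2:
            continue
        s = d.std()
        if s == 0:
            continue
        z[members] = (d - d.mean()) / s
    ranked = np.argsort(-z, kind="stable")
    return m.feature_ids[ranked[: min(n_top, m.n_features)]]


def tcc_to_isoform(
    tcc: ExpressionMatrix, ec_map: dict[str, list[str]]
) -> ExpressionMatrix:
    """Extract isoform counts from a TCC matrix via singleton classes.

    Only equivalence classes containing exactly one transcript identify an
    isoform unambiguously in 3'-end data; those columns are kept and
    relabeled to their transcript id, all multi-transcript classes are
    discarded, and values pass through unchanged.
    """
    missing = tcc.feature_ids.difference(pd.Index(ec_map))
    if len(missing):
        raise ValueError(f"equivalence classes missing from ec_map: {missing.tolist()[:10]}")
    singleton = [ec for ec in tcc.feature_ids if len(ec_map[ec]) == 1]
    tids = [ec_map[ec][0] for ec in singleton]
    if len(set(tids)) != len(tids):
        dup = pd.Index(tids)
        raise ValueError(
            f"transcript in multiple singleton classes: "
            f"{dup[dup.duplicated()].unique().tolist()[:5]}"
        )
    out = tcc.subset_features(np.asarray(singleton, dtype=object))
    return ExpressionMatrix(
        values=out.values,
        cell_ids=out.cell_ids,
        feature_ids=pd.Index(tids),
        feature_level="isoform",
        state=tcc.state,
    )


def compare_naive_em(
    m: ExpressionMatrix,
    annotation: pd.DataFrame,
    labels: pd.Series,
    level: str = "class",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Compare naive and length-normalized gene quantification decisions.

    Builds two gene matrices from the same isoform counts — naive (sum of
    raw counts per gene) and length-normalized (divide by transcript length,
    then sum) — runs the same group-vs-complement differential procedure on
    each, and returns one row per (gene, group) whose significance decision
    differs between the two quantifications.
    """
    from .diffexp import cluster_vs_rest_test

    gene_map = annotation["gene_id"]
    naive = aggregate_genes(m, gene_map)
    normalized = aggregate_genes(length_normalize(m, annotation), gene_map)
    results = []
    for name, gm in (("naive", naive), ("length_normalized", normalized)):
        _, logm, _ = normalize_log_scale(gm)
        tab = cluster_vs_rest_test(logm, labels, level=level)
        tab["quantification"] = name
        results.append(tab)
    merged = results[0].merge(
        results[1],
        on=["feature_id", "group"],
        suffixes=("_naive", "_norm"),
    )
    sig_n = merged["p_adj_naive"] < alpha
    sig_e = merged["p_adj_norm"] < alpha
    disc = merged[sig_n != sig_e]
    return disc[
        ["feature_id", "group", "t_statistic_naive", "p_adj_naive",
         "t_statistic_norm", "p_adj_norm"]
    ].reset_index(drop=True)
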