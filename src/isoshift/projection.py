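"""Supervised projection with a permutation control, and isoform reclustering.

Neighbourhood component analysis (NCA) learns a linear projection that
maximizes leave-one-out nearest-neighbour label agreement — useful for
visualizing cells under a supervised ontology, but at risk of overfitting.
:func:`permutation_control` quantifies that risk: with labels permuted, the
neighbour label purity in the embedding should fall to the closed-form
chance rate sum(f_l^2) implied by the label frequencies.

:func:`recluster_by_isoform` asks whether a gene-derived cluster hides
isoform-level substructure: cells are re-partitioned in isoform space
(PCA of scaled log1p values, kNN graph, Leiden communities) and a split is
accepted only when it is statistics-gated — at least one isoform must be
Bonferroni-significant between the two candidate subclusters on counts
held out from the partition discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors, NeighborhoodComponentsAnalysis, kneighbors_graph

from .containers import ExpressionMatrix
from .stats import bonferroni, ttest_matrix

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """Cells x k coordinates plus provenance."""

    coords: np.ndarray
    cell_ids: pd.Index
    provenance: dict = field(default_factory=dict)


@dataclass
class RefinementResult:
    cluster_id: str
    split: bool
    reason: str = ""
    subcluster_labels: pd.Series | None = None
    isoform_effect_size: float = float("nan")
    gene_effect_size: float = float("nan")
    n_significant_isoforms: int = 0
    n_significant_genes: int = 0


def supervised_projection(
    m: ExpressionMatrix,
    labels: pd.Series,
    k: int = 10,
    seed: int = 0,
    max_iter: int = 50,
) -> Embedding:
    """NCA projection of scaled expression to ``k`` components.

    Deterministic given ``seed``.  Labels with a single cell contribute no
    neighbour pairs and are warned about.  2-D layouts (t-SNE/UMAP) are a
    separate visualization step, not performed here.
    """
    lab = pd.Series(labels).reindex(m.cell_ids)
    if lab.isna().any():
        raise ValueError("labels must cover all cells")
    counts = lab.value_counts()
    singles = counts[counts == 1].index.tolist()
    if singles:
        logger.warning("labels with a single cell contribute no neighbour pairs: %s", singles[:5])
    if k > m.n_features:
        raise ValueError(f"k={k} exceeds feature count {m.n_features}")
    nca = NeighborhoodComponentsAnalysis(
        n_components=k, random_state=seed, max_iter=max_iter
    )
    coords = nca.fit_transform(m.dense(), lab.to_numpy())
    return Embedding(
        coords=coords,
        cell_ids=m.cell_ids,
        provenance={"method": "nca", "k": k, "seed": seed, "labels": "supplied"},
    )


def neighbour_label_purity(
    embedding: Embedding, labels: pd.Series, n_neighbors: int = 15
) -> float:
    """Mean fraction of same-label cells among each cell's nearest neighbours."""
    lab = pd.Series(labels).reindex(embedding.cell_ids).to_numpy()
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(embedding.coords)
    _, idx = nn.kneighbors(embedding.coords)
    neigh = lab[idx[:, 1:]]  # drop self
    return float((neigh == lab[:, None]).mean())


def chance_purity(labels: pd.Series) -> float:
    """Closed-form chance neighbour purity: sum of squared label frequencies."""
    f = pd.Series(labels).value_counts(normalize=True).to_numpy()
    return float((f**2).sum())


def permutation_control(
    m: ExpressionMatrix,
    labels: pd.Series,
    k: int = 10,
    seed: int = 0,
    n_neighbors: int = 15,
    max_iter: int = 50,
) -> float:
    """Overfitting control: purity of an embedding trained on permuted labels.

    Labels are permuted uniformly at random (seeded), the projection is
    recomputed, and the neighbour label purity of the *permuted* labels in
    the new embedding is returned.  A non-overfitting projection yields a
    score at the chance rate ``sum(f_l^2)``.
    """
    rng = np.random.default_rng(seed)
    lab = pd.Series(labels).reindex(m.cell_ids)
    permuted = pd.Series(rng.permutation(lab.to_numpy()), index=m.cell_ids)
    emb = supervised_projection(m, permuted, k=k, seed=seed, max_iter=max_iter)
    return neighbour_label_purity(emb, permuted, n_neighbors=n_neighbors)


def _leiden_partition(x: np.ndarray, n_neighbors: int, resolution: float, seed: int) -> np.ndarray:
    n_neighbors = min(n_neighbors, x.shape[0] - 1)
    adj = kneighbors_graph(x, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    g = igraph.Graph(n=x.shape[0], edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    return np.asarray(part.membership)


def recluster_by_isoform(
    m_iso: ExpressionMatrix,
    cells: pd.DataFrame,
    cluster_id: str,
    gene_map: pd.Series,
    seed: int = 0,
    n_pcs: int = 10,
    n_neighbors: int = 15,
    resolution: float = 0.6,
    alpha: float = 0.01,
    min_subcluster: int = 6,
    exclude_prefix: str | None = "mt-",
    split_dispersion: float | None = None,
) -> RefinementResult:
    """Attempt to split one cluster using isoform-level expression.

    Discovering a partition and testing it on the same values makes the
    significance gate meaningless (the partition is chosen to maximize
    separation), so the raw counts are first split by binomial thinning
    into independent discovery and validation halves (count splitting;
    exact under Poisson noise).  On the discovery half: log1p
    per-cell-normalized values are scaled, the log library size is
    regressed out feature-wise (sequencing depth leaves a signature in
    the zero pattern that otherwise dominates the partition), the
    residuals are projected to ``n_pcs`` principal components and
    partitioned into Leiden communities of a kNN graph; the two largest
    communities are the candidate subclusters.  The split is accepted only if both have more than 5
    cells and at least one isoform is Bonferroni-significant between them
    at ``alpha`` *on the validation half*.  Effect sizes (difference of
    subcluster means on the log1p scale, averaged over significant
    features) are computed on the validation half in parallel at the
    isoform and gene level.

    Plain binomial thinning yields independent halves only for Poisson
    counts; under negative-binomial noise the halves share the latent rate
    and a little selection leakage remains.  When the NB size parameter is
    known (e.g. simulated data), pass it as ``split_dispersion`` to use
    Beta-Binomial thinning, which restores exact independence of the
    halves for NB counts.
    """
    from sklearn.decomposition import PCA

    from .preprocess import aggregate_genes, log1p, scale as scale_features, to_tpm

    if m_iso.state != "raw_counts":
        raise ValueError("recluster_by_isoform needs raw counts (for count splitting)")
    in_cluster = (cells["cluster_label"].reindex(m_iso.cell_ids) == cluster_id).to_numpy()
    n = int(in_cluster.sum())
    if n < 2 * min_subcluster:
        return RefinementResult(cluster_id, False, reason=f"only {n} cells")
    sub = m_iso.subset_cells(in_cluster)
    if exclude_prefix:
        # mitochondrial content is a technical covariate, not cell identity
        sub = sub.subset_features(~sub.feature_ids.str.startswith(exclude_prefix))

    rng = np.random.default_rng(seed)
    counts = sub.dense().astype(np.int64)
    if split_dispersion is None:
        p = 0.5
    else:
        half = split_dispersion / 2.0
        p = rng.beta(half, half, size=counts.shape)
    train_counts = rng.binomial(counts, p)
    test_counts = counts - train_counts
    train = ExpressionMatrix(train_counts, sub.cell_ids, sub.feature_ids,
                             feature_level="isoform")
    test = ExpressionMatrix(test_counts, sub.cell_ids, sub.feature_ids,
                            feature_level="isoform")
    if (train.cell_totals() == 0).any() or (test.cell_totals() == 0).any():
        return RefinementResult(cluster_id, False, reason="cells with empty count half")

    train_scaled = scale_features(log1p(to_tpm(train))).dense()
    covariates = np.column_stack([np.ones(train_scaled.shape[0]),
                                  np.log(train.cell_totals())])
    beta, *_ = np.linalg.lstsq(covariates, train_scaled, rcond=None)
    residuals = train_scaled - covariates @ beta
    pca = PCA(n_components=min(n_pcs, *residuals.shape), random_state=seed)
    x = pca.fit_transform(residuals)
    membership = _leiden_partition(x, n_neighbors, resolution, seed)

    sizes = pd.Series(membership).value_counts()
    big = sizes[sizes > min_subcluster - 1]
    if len(big) < 2:
        return RefinementResult(cluster_id, False, reason="no two viable subclusters")
    a_id, b_id = big.index[:2]
    mask_a, mask_b = membership == a_id, membership == b_id

    iso_dense = log1p(to_tpm(test)).dense()
    _, p_iso = ttest_matrix(iso_dense[mask_a], iso_dense[mask_b])
    sig_iso = bonferroni(p_iso) < alpha
    if not sig_iso.any():
        return RefinementResult(
            cluster_id, False, reason="no significant isoform between subclusters"
        )

    gdense = log1p(to_tpm(aggregate_genes(test, gene_map))).dense()
    _, p_gene = ttest_matrix(gdense[mask_a], gdense[mask_b])
    sig_gene = bonferroni(p_gene) < alpha

    def _effect(dense: np.ndarray, sig: np.ndarray) -> float:
        if not sig.any():
            return 0.0
        diff = np.abs(dense[mask_a].mean(axis=0) - dense[mask_b].mean(axis=0))
        return float(diff[sig].mean())

    labels = pd.Series("other", index=sub.cell_ids)
    labels.iloc[np.flatnonzero(mask_a)] = "A"
    labels.iloc[np.flatnonzero(mask_b)] = "B"
    return RefinementResult(
        cluster_id=cluster_id,
        split=True,
        subcluster_labels=labels,
        isoform_effect_size=_effect(iso_dense, sig_iso),
        gene_effect_size=_effect(gdense, sig_gene),
        n_significant_isoforms=int(sig_iso.sum()),
        n_significant_genes=int(sig_gene.sum()),
    )
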