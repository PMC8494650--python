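"""Synthetic multi-platform single-cell isoform data with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a three-level cell ontology (class / subclass / cluster), genes with
several isoforms grouped by shared transcription start sites (TSS) and shared
3' end sites, negative-binomial counts with per-cell library-size variation
and a mitochondrial fraction, equivalence classes (singleton for transcripts
with a unique 3' end, shared otherwise), and spatially layered subclasses
with planted depth gradients.

Every planted effect is recorded in a :class:`PlantedTruth` table so that
recovery tests can compare detections against ground truth.

Planted effect kinds
--------------------
``gene_constant_shift``
    Isoform proportions within a gene are swapped between a target ontology
    group and its complement while the expected gene-level mean is identical
    in both — the signal the gene-level analysis is blind to.
``marker``
    A fold change on one isoform in a target group, gene total unconstrained.
``sex_effect``
    A fold change on one (autosomal) isoform in male cells of one subclass.
``tss_transcriptional``
    A uniform fold on every member of a TSS group in a target class: the
    summed TSS signal is detectable while each (low-abundance) member is
    individually underpowered — the signature of differential promoter usage.
``tss_post_transcriptional``
    A proportion swap between the members of one TSS group with the TSS-group
    expected total conserved — the signature of differential splicing.
``cluster_split``
    A gene-constant proportion swap between two halves of one cluster,
    invisible at gene level, used to test isoform-driven cluster refinement.
``depth_gradient``
    Panel-gene expression linear in normalized cortical depth (spatial data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .containers import ExpressionMatrix, validate_annotation, validate_cells

EFFECT_KINDS = (
    "gene_constant_shift",
    "marker",
    "sex_effect",
    "tss_transcriptional",
    "tss_post_transcriptional",
    "depth_gradient",
    "cluster_split",
)


@dataclass
class PlantedEffect:
    """One planted effect; ``params`` carries kind-specific structure.

    ``target`` uses the generator's deterministic naming scheme: genes are
    ``g001``..., transcripts ``g001-t1``..., TSS groups ``g001:ts1``....
    """

    kind: str
    target: str
    group: str
    magnitude: float
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass
class CountModel:
    """Log-normal per-gene mean expression with NB(theta) count noise.

    ``dispersion`` is the NB size parameter theta: Var = mu + mu^2 / theta.
    """

    mean_log_mu: float = 0.7   # median gene mean ~ 2 counts/cell
    mean_log_sigma: float = 1.0
    dispersion: float = 10.0


@dataclass
class SpatialConfig:
    """Slice geometry and layered subclasses for the spatial simulator.

    Coordinates are 2-D per slice with y increasing downward from the pial
    boundary (depth 0 at the top edge).  Subclasses occupy equal-height
    depth bands in ``layer_order``.
    """

    layer_order: list[str] = field(default_factory=list)
    cells_per_subclass: int = 300
    n_slices: int = 1
    slice_width: float = 1000.0
    slice_height: float = 1000.0
    panel_base_mean: float = 20.0
    marker_fold: float = 5.0


@dataclass
class SimulationConfig:
    seed: int = 0
    #: class -> subclass -> cluster -> cells per cluster
    ontology: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    n_genes: int = 100
    #: value -> probability, e.g. {1: 0.4, 2: 0.4, 3: 0.2}
    isoforms_per_gene: dict[int, float] = field(default_factory=lambda: {1: 0.4, 2: 0.4, 3: 0.2})
    tss_groups_per_gene: dict[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.4})
    length_range: tuple[int, int] = (500, 3000)
    count_model: CountModel = field(default_factory=CountModel)
    library_size_cv: float = 0.3
    #: Beta(a, b) parameters for the per-cell mitochondrial fraction
    mito_fraction: dict[str, float] = field(default_factory=lambda: {"a": 2.0, "b": 48.0})
    n_mito_genes: int = 5
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    spatial: SpatialConfig | None = None
    #: fraction of multi-isoform-gene transcripts given a singleton (unique-3')
    #: equivalence class; the rest share one class per gene
    ec_structure: float = 0.7
    batch_dates: list[str] = field(default_factory=lambda: ["d1"])
    platform: str = "smartseq"

    # -- validation / (de)serialization -----------------------------------
    def __post_init__(self) -> None:
        for dist, name in ((self.isoforms_per_gene, "isoforms_per_gene"),
                           (self.tss_groups_per_gene, "tss_groups_per_gene")):
            if not dist:
                raise ValueError(f"{name} distribution is empty")
            if any(int(k) < 1 for k in dist):
                raise ValueError(f"{name} must not put mass on values < 1")
            total = sum(dist.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if not (0.0 <= self.ec_structure <= 1.0):
            raise ValueError("ec_structure must be a fraction in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "count_model" in raw and isinstance(raw["count_model"], dict):
            raw["count_model"] = CountModel(**raw["count_model"])
        if raw.get("spatial") is not None and isinstance(raw["spatial"], dict):
            raw["spatial"] = SpatialConfig(**raw["spatial"])
        if "planted_effects" in raw:
            raw["planted_effects"] = [
                e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
                for e in raw["planted_effects"]
            ]
        for key in ("isoforms_per_gene", "tss_groups_per_gene"):
            if key in raw:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        if "length_range" in raw:
            raw["length_range"] = tuple(raw["length_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh, sort_keys=False)

    # -- ontology helpers --------------------------------------------------
    def cell_table(self) -> pd.DataFrame:
        rows = []
        i = 0
        for cls, subs in self.ontology.items():
            for sub, clusters in subs.items():
                for clu, n in clusters.items():
                    for _ in range(int(n)):
                        rows.append((f"cell{i:05d}", cls, sub, clu))
                        i += 1
        if not rows:
            raise ValueError("ontology defines no cells")
        return pd.DataFrame(
            rows, columns=["cell_id", "class_label", "subclass_label", "cluster_label"]
        )

    def ontology_nodes(self) -> dict[str, str]:
        """Map every ontology node name to its level."""
        nodes: dict[str, str] = {}
        for cls, subs in self.ontology.items():
            nodes[cls] = "class"
            for sub, clusters in subs.items():
                nodes[sub] = "subclass"
                for clu in clusters:
                    nodes[clu] = "cluster"
        return nodes


@dataclass
class PlantedTruth:
    """Realized planted effects, for recovery tests only."""

    effects: list[dict[str, Any]] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[dict[str, Any]]:
        return [e for e in self.effects if e["kind"] == kind]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"effects": self.effects}, fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(effects=json.load(fh)["effects"])


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _draw_discrete(rng: np.random.Generator, dist: dict[int, float], n: int) -> np.ndarray:
    vals = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[int(v)] for v in vals], dtype=float)
    return rng.choice(vals, size=n, p=probs / probs.sum())


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Generate a transcript annotation table from the config.

    Deterministic given (seed, config).  Planted effects may force structure
    on their target genes (isoform count, TSS membership) via
    ``params['n_members']`` / ``params['n_tss']``; targets must use the
    generator's naming scheme.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    genes = _gene_names(config.n_genes)
    n_iso = _draw_discrete(rng, config.isoforms_per_gene, config.n_genes)
    n_tss = _draw_discrete(rng, config.tss_groups_per_gene, config.n_genes)

    forced_iso: dict[str, int] = {}
    forced_tss: dict[str, int] = {}
    for eff in config.planted_effects:
        gene = eff.target.split(":")[0].rsplit("-t", 1)[0]
        if eff.kind in ("gene_constant_shift", "cluster_split"):
            forced_iso[gene] = max(forced_iso.get(gene, 0), int(eff.params.get("n_isoforms", 2)))
        elif eff.kind in ("marker", "sex_effect") and "-t" in eff.target:
            t_index = int(eff.target.rsplit("-t", 1)[1])
            forced_iso[gene] = max(forced_iso.get(gene, 0), t_index)
        elif eff.kind in ("tss_transcriptional", "tss_post_transcriptional"):
            members = int(eff.params.get("n_members", 2))
            forced_iso[gene] = max(forced_iso.get(gene, 0), members)
            forced_tss[gene] = 1  # keep all members in the first TSS group

    rows = []
    origin = 10_000
    for g, gene in enumerate(genes):
        k = forced_iso.get(gene, int(n_iso[g]))
        if k < 1:
            raise ValueError(f"isoforms_per_gene drew 0 for {gene}; reject config")
        m = forced_tss.get(gene, min(int(n_tss[g]), k))
        strand = "+" if rng.random() < 0.5 else "-"
        # TSS-group membership: first m transcripts seed distinct groups,
        # remaining transcripts join a random existing group
        tss_assign = np.concatenate([np.arange(m), rng.integers(0, m, size=k - m)])
        length_lo, length_hi = config.length_range
        lengths = rng.integers(length_lo, length_hi + 1, size=k)
        if gene in forced_iso:
            lengths[:] = lengths[0]  # equal lengths on planted genes
        # 3' uniqueness: singleton equivalence class for unique3p transcripts,
        # one shared class for the rest; a single leftover is promoted to
        # unique so that "singleton class" and "unique3p" coincide exactly
        if k == 1:
            unique3p = np.array([True])
        else:
            unique3p = rng.random(k) < config.ec_structure
            if (~unique3p).sum() == 1:
                unique3p[:] = True
        end_coord = np.where(
            unique3p,
            origin + 50_000 + 500 * np.arange(k),
            origin + 40_000,
        )
        for t in range(k):
            rows.append({
                "transcript_id": f"{gene}-t{t + 1}",
                "gene_id": gene,
                "length": int(lengths[t]),
                "strand": strand,
                "tss_coord": origin + 1_000 * int(tss_assign[t]),
                "tss_group": f"{gene}:ts{int(tss_assign[t]) + 1}",
                "end_group": f"{gene}:es{int(end_coord[t])}",
                "unique3p": bool(unique3p[t]),
            })
        origin += 100_000

    # mitochondrial genes: single-isoform, singleton classes
    for j in range(config.n_mito_genes):
        gene = f"mt-{j + 1}"
        rows.append({
            "transcript_id": f"{gene}-t1",
            "gene_id": gene,
            "length": int(rng.integers(*config.length_range)),
            "strand": "+",
            "tss_coord": origin,
            "tss_group": f"{gene}:ts1",
            "end_group": f"{gene}:es{origin + 40_000}",
            "unique3p": True,
        })
        origin += 100_000

    ann = pd.DataFrame(rows)
    return validate_annotation(ann)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _cells_in(cells: pd.DataFrame, group: str, config: SimulationConfig) -> np.ndarray:
    level = config.ontology_nodes().get(group)
    if level is None:
        raise ValueError(f"planted effect group {group!r} is not an ontology node")
    col = {"class": "class_label", "subclass": "subclass_label", "cluster": "cluster_label"}[level]
    return (cells[col] == group).to_numpy()


def simulate_counts(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame, PlantedTruth]:
    """Simulate a cells x isoform NB count matrix with all planted effects.

    Returns the count matrix, the cell annotation table, and the
    :class:`PlantedTruth` record of every realized effect.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    cells = config.cell_table()
    n_cells = len(cells)
    tids = annotation.index.to_numpy()
    n_feat = len(tids)
    col_of = {t: j for j, t in enumerate(tids)}
    gene_of = annotation["gene_id"]
    is_mito = gene_of.str.startswith("mt-").to_numpy()

    # cell-level covariates
    sex = np.where(rng.random(n_cells) < 0.5, "M", "F")
    batch = np.array(config.batch_dates)[np.arange(n_cells) % len(config.batch_dates)]
    cv = max(config.library_size_cv, 1e-12)
    sigma2 = np.log1p(cv**2)
    size_factor = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n_cells)
    mito_frac = rng.beta(config.mito_fraction["a"], config.mito_fraction["b"], size=n_cells)

    # baseline per-transcript means: gene mean split by Dirichlet proportions
    cm = config.count_model
    base = np.zeros(n_feat)
    gene_groups = annotation.groupby("gene_id", sort=False).indices
    gene_mean: dict[str, float] = {}
    base_props: dict[str, np.ndarray] = {}
    for gene, idx in gene_groups.items():
        mu = float(rng.lognormal(cm.mean_log_mu, cm.mean_log_sigma))
        props = rng.dirichlet(np.full(len(idx), 5.0)) if len(idx) > 1 else np.array([1.0])
        gene_mean[gene] = mu
        base_props[gene] = props
        base[idx] = mu * props

    # expected-mean matrix, then planted modifications on (rows, cols) blocks
    mean = np.tile(base, (n_cells, 1))
    truth = PlantedTruth()
    cluster_sub: dict[str, pd.Series] = {}

    for eff in config.planted_effects:
        realized: dict[str, Any] = {
            "kind": eff.kind, "target": eff.target, "group": eff.group,
            "magnitude": float(eff.magnitude),
        }
        if eff.kind in ("gene_constant_shift", "cluster_split"):
            gene = eff.target
            if gene not in gene_groups:
                raise ValueError(f"planted effect targets unknown gene {gene!r}")
            idx = gene_groups[gene]
            if len(idx) < 2:
                raise ValueError(f"{eff.kind} needs >= 2 isoforms on {gene!r}")
            mu = float(eff.params.get("gene_mean", gene_mean[gene]))
            hi = float(eff.magnitude)
            props = np.full(len(idx), (1.0 - hi) / (len(idx) - 1))
            props[0] = hi
            swapped = props.copy()
            swapped[[0, 1]] = swapped[[1, 0]]
            if eff.kind == "gene_constant_shift":
                rows_in = _cells_in(cells, eff.group, config)
                mean[np.ix_(~rows_in, idx)] = mu * props
                mean[np.ix_(rows_in, idx)] = mu * swapped
                realized.update({
                    "gene": gene,
                    "up_transcript": tids[idx[1]],
                    "down_transcript": tids[idx[0]],
                    "gene_mean": mu,
                })
            else:  # cluster_split: swap between two halves of one cluster
                in_cluster = np.flatnonzero(_cells_in(cells, eff.group, config))
                if len(in_cluster) < 12:
                    raise ValueError(f"cluster {eff.group!r} too small to split")
                half = len(in_cluster) // 2
                a, b = in_cluster[:half], in_cluster[half:]
                mean[np.ix_(a, idx)] = mu * props
                mean[np.ix_(b, idx)] = mu * swapped
                sub = pd.Series("A", index=cells["cell_id"])
                sub.iloc[b] = "B"
                sub = sub.iloc[in_cluster]
                cluster_sub[eff.group] = sub
                realized.update({
                    "gene": gene, "cluster": eff.group, "gene_mean": mu,
                    "transcripts": tids[idx].tolist(),
                    "subcluster_of": {c: s for c, s in sub.items()},
                })
        elif eff.kind == "marker":
            if eff.target not in col_of:
                raise ValueError(f"planted effect targets unknown transcript {eff.target!r}")
            j = col_of[eff.target]
            rows_in = _cells_in(cells, eff.group, config)
            mean[rows_in, j] *= float(eff.magnitude)
            realized["transcript"] = eff.target
        elif eff.kind == "sex_effect":
            if eff.target not in col_of:
                raise ValueError(f"planted effect targets unknown transcript {eff.target!r}")
            j = col_of[eff.target]
            rows = _cells_in(cells, eff.group, config) & (sex == "M")
            mean[rows, j] *= float(eff.magnitude)
            realized.update({"transcript": eff.target, "up_sex": "M"})
        elif eff.kind in ("tss_transcriptional", "tss_post_transcriptional"):
            members = np.flatnonzero((annotation["tss_group"] == eff.target).to_numpy())
            if len(members) == 0:
                raise ValueError(f"planted effect targets unknown TSS group {eff.target!r}")
            rows_in = _cells_in(cells, eff.group, config)
            if eff.kind == "tss_transcriptional":
                member_mean = eff.params.get("member_mean")
                if member_mean is not None:
                    mean[:, members] = float(member_mean)
                mean[np.ix_(rows_in, members)] *= float(eff.magnitude)
            else:
                if len(members) < 2:
                    raise ValueError(f"TSS group {eff.target!r} needs >= 2 members for a swap")
                total = float(eff.params.get("tss_mean", base[members].sum()))
                hi = float(eff.params.get("high_proportion", 0.8))
                props = np.full(len(members), (1.0 - hi) / (len(members) - 1))
                props[0] = hi
                swapped = props.copy()
                swapped[[0, 1]] = swapped[[1, 0]]
                mean[np.ix_(~rows_in, members)] = total * props
                mean[np.ix_(rows_in, members)] = total * swapped
                realized.update({
                    "up_transcript": tids[members[1]],
                    "down_transcript": tids[members[0]],
                    "tss_mean": total,
                })
            realized["members"] = tids[members].tolist()
        elif eff.kind == "depth_gradient":
            continue  # realized by simulate_spatial
        truth.effects.append(realized)

    # mitochondrial content: mito columns carry fraction f_c of the cell total
    non_mito_total = mean[:, ~is_mito].sum(axis=1)
    n_mito = int(is_mito.sum())
    if n_mito:
        per_mito = (mito_frac / (1.0 - mito_frac)) * non_mito_total / n_mito
        mean[:, is_mito] = per_mito[:, None]
    mean *= size_factor[:, None]

    # NB sampling via gamma-Poisson mixture
    theta = float(cm.dispersion)
    lam = rng.gamma(theta, mean / theta)
    counts = rng.poisson(lam).astype(np.float64)

    matrix = ExpressionMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=pd.Index(cells["cell_id"]),
        feature_ids=pd.Index(tids),
        feature_level="isoform",
        state="raw_counts",
    )
    cells = cells.assign(
        sex=sex,
        batch_date=batch,
        platform=config.platform,
        total_counts=counts.sum(axis=1),
        mito_fraction=counts[:, is_mito].sum(axis=1) / np.maximum(counts.sum(axis=1), 1),
    )
    return matrix, validate_cells(cells), truth


# ---------------------------------------------------------------------------
# equivalence classes (TCC)
# ---------------------------------------------------------------------------

def simulate_tcc(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    counts: ExpressionMatrix,
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Route isoform counts into equivalence classes.

    Unique-3' transcripts get singleton classes; the remaining transcripts of
    each gene share one class.  Per-cell totals are conserved exactly.
    """
    if counts.feature_level != "isoform":
        raise ValueError("simulate_tcc expects an isoform-level matrix")
    ann = annotation.loc[counts.feature_ids]
    ec_map: dict[str, list[str]] = {}
    assign: dict[str, str] = {}
    k = 0
    for gene, sub in ann.groupby("gene_id", sort=False):
        shared = sub.index[~sub["unique3p"]].tolist()
        for tid in sub.index[sub["unique3p"]]:
            ec = f"ec{k:05d}"
            k += 1
            ec_map[ec] = [tid]
            assign[tid] = ec
        if shared:
            ec = f"ec{k:05d}"
            k += 1
            ec_map[ec] = shared
            for tid in shared:
                assign[tid] = ec

    ec_ids = pd.Index(sorted(ec_map))
    ec_pos = {e: j for j, e in enumerate(ec_ids)}
    cols = np.array([ec_pos[assign[t]] for t in counts.feature_ids])
    routing = sp.csr_matrix(
        (np.ones(len(cols)), (np.arange(len(cols)), cols)),
        shape=(len(cols), len(ec_ids)),
    )
    tcc = ExpressionMatrix(
        values=(counts.values @ routing).tocsr(),
        cell_ids=counts.cell_ids,
        feature_ids=ec_ids,
        feature_level="equivalence_class",
        state="raw_counts",
    )
    return tcc, ec_map


# ---------------------------------------------------------------------------
# spatial
# ---------------------------------------------------------------------------

def simulate_spatial(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, ExpressionMatrix, pd.DataFrame]:
    """Simulate layered MERFISH-like slices with a targeted gene panel.

    Returns ``(spatial, panel, cells)`` where ``spatial`` has columns
    cell_id / slice_id / x / y (y grows downward from the pial surface),
    ``panel`` is a cells x panel-gene count matrix, and ``cells`` carries the
    subclass labels.  Subclasses occupy equal-height depth bands in
    ``spatial.layer_order``; each subclass gets a planted marker gene; every
    ``depth_gradient`` effect makes its panel gene's expected expression
    linear in the subclass's normalized depth.
    """
    spc = config.spatial
    if spc is None:
        raise ValueError("config.spatial is not set")
    layers = list(spc.layer_order)
    if not layers:
        layers = [s for subs in config.ontology.values() for s in subs]
    if not layers:
        raise ValueError("no subclasses available for spatial layers")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))

    n_layers = len(layers)
    rows = []
    for s in range(spc.n_slices):
        for li, sub in enumerate(layers):
            n = spc.cells_per_subclass
            lo, hi = li / n_layers, (li + 1) / n_layers
            y = rng.uniform(lo * spc.slice_height, hi * spc.slice_height, size=n)
            # the slice tapers with depth (widest at the pia), so the hull's
            # upward-facing edges trace the pial surface
            margin = 0.15 * spc.slice_width * (y / spc.slice_height)
            x = rng.uniform(margin, spc.slice_width - margin)
            for i in range(n):
                rows.append((f"sp{s}_{sub}_{i:04d}", f"slice{s}", x[i], y[i], sub))
    df = pd.DataFrame(rows, columns=["cell_id", "slice_id", "x", "y", "subclass_label"])
    if df[["x", "y"]].drop_duplicates().shape[0] < 3:
        raise ValueError("fewer than 3 distinct cell positions; hull undefined downstream")

    # normalized depth per subclass = band centre / deepest band centre,
    # matching the downstream centroid-distance normalization
    band_centre = {sub: (li + 0.5) / n_layers for li, sub in enumerate(layers)}
    max_centre = max(band_centre.values())
    sub_depth = {sub: c / max_centre for sub, c in band_centre.items()}

    panel_genes = [f"panel-{sub}" for sub in layers]
    gradients = [e for e in config.planted_effects if e.kind == "depth_gradient"]
    for eff in gradients:
        if eff.target not in panel_genes:
            panel_genes.append(eff.target)
    mean = np.full((len(df), len(panel_genes)), spc.panel_base_mean, dtype=float)
    for j, sub in enumerate(layers):  # subclass marker genes
        mean[(df["subclass_label"] == sub).to_numpy(), j] *= spc.marker_fold
    for eff in gradients:
        j = panel_genes.index(eff.target)
        depth = df["subclass_label"].map(sub_depth).to_numpy()
        intercept = float(eff.params.get("intercept", spc.panel_base_mean))
        mean[:, j] = np.maximum(intercept + float(eff.magnitude) * depth, 0.0)
    counts = rng.poisson(mean).astype(float)

    panel = ExpressionMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=pd.Index(df["cell_id"]),
        feature_ids=pd.Index(panel_genes),
        feature_level="panel_gene",
        state="raw_counts",
    )
    cells = pd.DataFrame({
        "cell_id": df["cell_id"],
        "class_label": "glutamatergic",
        "subclass_label": df["subclass_label"],
        "cluster_label": df["subclass_label"],
        "sex": "unknown",
        "batch_date": df["slice_id"],
        "platform": "merfish",
    })
    return df[["cell_id", "slice_id", "x", "y"]], panel, validate_cells(cells)
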