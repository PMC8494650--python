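"""Recovery benchmarks on synthetic data with planted ground truth.

Each function builds a simulated dataset under fixed study conditions, runs
the corresponding analysis end to end, and measures how well the planted
truth is recovered (or how well a null is calibrated).  They back both the
acceptance test suite and ``scripts/acceptance.py``; all randomness is
derived from the ``seed`` argument.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    PlantedEffect,
    SimulationConfig,
    SpatialConfig,
    aggregate_genes,
    build_tss_matrix,
    chance_purity,
    classify_regulation,
    cluster_correlation,
    cluster_vs_rest_test,
    depth_regression,
    detect_gene_constant_shifts,
    fit_boundary,
    neighbour_label_purity,
    normalize_log_scale,
    permutation_control,
    simulate_annotation,
    simulate_counts,
    simulate_spatial,
    simulate_tcc,
    subclass_depths,
    supervised_projection,
    tcc_to_isoform,
)
from .containers import ExpressionMatrix


def _sub_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0] % (2**31))


def _log_matrices(m, ann):
    _, iso_log, _ = normalize_log_scale(m)
    gene_log = normalize_log_scale(aggregate_genes(m, ann["gene_id"]))[1]
    tss_log = normalize_log_scale(build_tss_matrix(m, ann))[1]
    return iso_log, gene_log, tss_log


def null_calibration(seed: int, n_genes: int = 1100, cells_per_cluster: int = 200,
                     n_clusters: int = 4, alpha: float = 0.01) -> dict:
    """Fraction of Bonferroni-significant features per null comparison.

    Four clusters of identically distributed cells, ~2,000 isoforms, no
    planted effects: gene, isoform, and TSS cluster-vs-complement tests
    should flag ~alpha of comparisons' families in total.
    """
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 1),
        ontology={"glut": {"L": {f"c{i}": cells_per_cluster for i in range(n_clusters)}}},
        n_genes=n_genes,
        isoforms_per_gene={1: 0.3, 2: 0.4, 3: 0.3},
    )
    ann = simulate_annotation(cfg)
    m, cells, _ = simulate_counts(cfg, ann)
    iso_log, gene_log, tss_log = _log_matrices(m, ann)
    out = {"n_isoforms": int(iso_log.n_features)}
    for name, mat in (("isoform", iso_log), ("gene", gene_log), ("tss", tss_log)):
        tests = cluster_vs_rest_test(mat, cells, level="cluster")
        per_group = tests.groupby("group")["p_adj"].apply(lambda p: (p < alpha).mean())
        out[f"{name}_flagged_fraction"] = float(per_group.max())
    return out


def shift_recovery(seed: int, n_replicates: int = 20, n_shift_genes: int = 50,
                   gene_mean: float = 10.0, cells_per_group: int = 500,
                   swap_high: float = 0.8) -> dict:
    """Recall of planted gene-constant proportion swaps and the parent-gene
    false-flag rate, over independent replicates."""
    recalls, flags = [], []
    for rep in range(n_replicates):
        effects = [PlantedEffect("gene_constant_shift", f"g{i + 1:03d}", "glut",
                                 swap_high, {"gene_mean": gene_mean})
                   for i in range(n_shift_genes)]
        cfg = SimulationConfig(
            seed=_sub_seed(seed, 100 + rep),
            ontology={"glut": {"Lg": {"cg": cells_per_group}},
                      "gaba": {"Lb": {"cb": cells_per_group}}},
            n_genes=200,
            planted_effects=effects,
        )
        ann = simulate_annotation(cfg)
        m, cells, truth = simulate_counts(cfg, ann)
        _, iso_log, _ = normalize_log_scale(m)
        gene_log = normalize_log_scale(aggregate_genes(m, ann["gene_id"]))[1]
        iso_tests = cluster_vs_rest_test(iso_log, cells, level="class")
        gene_tests = cluster_vs_rest_test(gene_log, cells, level="class")
        shifts = detect_gene_constant_shifts(iso_tests, gene_tests, ann["gene_id"])
        found = set(map(tuple, shifts[["feature_id", "group"]].values))
        planted = truth.of_kind("gene_constant_shift")
        recalls.append(np.mean([(e["up_transcript"], e["group"]) in found
                                for e in planted]))
        sig_genes = set(gene_tests.loc[gene_tests["p_adj"] < 0.01, "feature_id"])
        flags.append(np.mean([e["gene"] in sig_genes for e in planted]))
    return {
        "recall": float(np.mean(recalls)),
        "gene_false_flag_rate": float(np.mean(flags)),
        "n_replicates": n_replicates,
        "n_planted": n_replicates * n_shift_genes,
    }


def regulation_classification(seed: int, n_each: int = 20,
                              cells_per_class: int = 500, fold: float = 4.0) -> dict:
    """Accuracy of transcriptional vs post-transcriptional classification.

    Transcriptional effects are uniform folds on TSS groups of many
    low-abundance members (the member-level tests are underpowered while the
    summed TSS signal is strong); post-transcriptional effects are
    proportion swaps with conserved TSS totals.
    """
    effects = []
    for i in range(n_each):
        effects.append(PlantedEffect(
            "tss_transcriptional", f"g{i + 1:03d}:ts1",
            "glut" if i % 2 == 0 else "gaba", fold,
            {"n_members": 24, "member_mean": 0.0025}))
    for i in range(n_each, 2 * n_each):
        effects.append(PlantedEffect(
            "tss_post_transcriptional", f"g{i + 1:03d}:ts1",
            "glut" if i % 2 == 0 else "gaba", fold,
            {"n_members": 2, "tss_mean": 10.0, "high_proportion": 0.8}))
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 2),
        ontology={"glut": {"Lg": {"cg": cells_per_class}},
                  "gaba": {"Lb": {"cb": cells_per_class}}},
        n_genes=260,
        planted_effects=effects,
    )
    ann = simulate_annotation(cfg)
    m, cells, truth = simulate_counts(cfg, ann)
    _, iso_log, _ = normalize_log_scale(m)
    tss_log = normalize_log_scale(build_tss_matrix(m, ann))[1]
    iso_tests = cluster_vs_rest_test(iso_log, cells, level="class")
    tss_tests = cluster_vs_rest_test(tss_log, cells, level="class")
    reg = classify_regulation(tss_tests, iso_tests, ann)

    trans = set(map(tuple, reg.loc[reg["category"] == "tss_transcriptional",
                                   ["tss_group", "group"]].values))
    post = reg[reg["category"] == "tss_post_transcriptional"]
    post_set = set(map(tuple, post[["tss_group", "group"]].values))
    n_correct = confusions = 0
    for e in truth.of_kind("tss_transcriptional"):
        key = (e["target"], e["group"])
        n_correct += key in trans
        confusions += key in post_set
    for e in truth.of_kind("tss_post_transcriptional"):
        key = (e["target"], e["group"])
        hits = post[(post["tss_group"] == e["target"]) & (post["group"] == e["group"])]
        n_correct += e["up_transcript"] in set(hits["feature_id"])
        confusions += key in trans
    return {
        "accuracy": n_correct / (2 * n_each),
        "confusions": int(confusions),
        "n_planted": 2 * n_each,
    }


def tcc_exactness(seed: int, n_seeds: int = 3) -> dict:
    """Whether TCC->isoform extraction equals the simulator truth restricted
    to unique-3' transcripts, bit-exactly, over several seeds."""
    exact = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=_sub_seed(seed, 300 + k),
            ontology={"glut": {"L": {"c": 100}}},
            n_genes=80,
            ec_structure=0.6,
        )
        ann = simulate_annotation(cfg)
        m, _, _ = simulate_counts(cfg, ann)
        tcc, ec_map = simulate_tcc(cfg, ann, m)
        got = tcc_to_isoform(tcc, ec_map)
        unique = sorted(ann.index[ann["unique3p"]])
        same_features = sorted(got.feature_ids) == unique
        order = np.asarray(unique, dtype=object)
        same_values = (
            got.subset_features(order).dense() == m.subset_features(order).dense()
        ).all()
        exact.append(bool(same_features and same_values))
    return {"exact_fraction": float(np.mean(exact)), "n_seeds": n_seeds}


def depth_geometry(seed: int, planted_slope: float = 9.0,
                   cells_per_subclass: int = 400) -> dict:
    """Depth-model geometry: rigid-motion invariance of subclass depths,
    recovery of a planted depth gradient, and the equal-weight WLS path
    against the OLS closed form."""
    layers = ["L1", "L23", "L4", "L5", "L6a", "L6b"]
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 4),
        ontology={"glut": {s: {f"{s}_c": 10} for s in layers}},
        planted_effects=[PlantedEffect("depth_gradient", "ggrad", "glut",
                                       planted_slope, {"intercept": 25.0})],
        spatial=SpatialConfig(layer_order=layers,
                              cells_per_subclass=cells_per_subclass),
    )
    sp_map, panel, cells = simulate_spatial(cfg)
    model = subclass_depths(sp_map, cells, fit_boundary(sp_map))

    rng = np.random.default_rng(_sub_seed(seed, 5))
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    shift = rng.uniform(-500, 500, size=2)
    moved = sp_map.copy()
    moved[["x", "y"]] = sp_map[["x", "y"]].to_numpy() @ rot.T + shift
    model2 = subclass_depths(moved, cells, model.transformed(rot, shift))
    invariance_error = max(abs(model.depths[s] - model2.depths[s])
                           for s in model.depths)

    reg = depth_regression(panel, cells, model, expressed_fraction=0.0,
                           weights="equal")
    row = reg.set_index("isoform_id").loc["ggrad"]
    d = np.array([model.depths[s] for s in model.depths])
    wls_vs_ols = []
    for _, r in reg.iterrows():
        y = r["subclass_means"]
        slope = ((d - d.mean()) * (y - y.mean())).sum() / ((d - d.mean()) ** 2).sum()
        wls_vs_ols.append(abs(r["slope"] - slope))
    return {
        "invariance_error": float(invariance_error),
        "planted_slope": float(planted_slope),
        "recovered_slope": float(row["slope"]),
        "slope_se": float(row["slope_se"]),
        "wls_ols_max_diff": float(max(wls_vs_ols)),
    }


def crossplat_concordance(seed: int, noise_levels=(0, 0.5, 1, 2, 4),
                          n_noise_seeds: int = 3) -> dict:
    """Duplicate-input correlation and monotone decay along a noise ladder."""
    from .simulate import CountModel

    # well-expressed features so the 50%-presence set is stable across the
    # ladder and the decay reflects the added noise alone
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 6),
        ontology={"glut": {"L": {f"c{i}": 150 for i in range(3)}}},
        n_genes=200,
        count_model=CountModel(mean_log_mu=2.0, mean_log_sigma=0.7),
    )
    ann = simulate_annotation(cfg)
    m, cells, _ = simulate_counts(cfg, ann)
    dup = cluster_correlation(m, m, cells, cells, level="cluster")
    dup_err = float(np.abs(dup["r"].to_numpy() - 1).max())
    monotone = []
    for k in range(n_noise_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 700 + k))
        ladder = []
        for level in noise_levels:
            noisy = m.dense() + rng.poisson(level, size=m.values.shape)
            b = ExpressionMatrix(noisy, m.cell_ids, m.feature_ids)
            rep = cluster_correlation(m, b, cells, cells, level="cluster")
            ladder.append(float(rep["r"].mean()))
        monotone.append(all(ladder[i] > ladder[i + 1]
                            for i in range(len(ladder) - 1)))
    return {
        "duplicate_r_error": dup_err,
        "monotone_fraction": float(np.mean(monotone)),
        "n_noise_seeds": n_noise_seeds,
    }


def projection_control(seed: int, n_per_label: int = 150, n_labels: int = 3,
                       n_features: int = 12, separation: float = 6.0,
                       n_permutations: int = 8) -> dict:
    """Permutation control of the supervised projection on separable data."""
    rng = np.random.default_rng(_sub_seed(seed, 8))
    n = n_per_label * n_labels
    x = rng.normal(size=(n, n_features))
    labels = np.repeat([f"l{i}" for i in range(n_labels)], n_per_label)
    for i in range(n_labels):
        x[labels == f"l{i}", i * 2:(i * 2 + 2)] += separation
    m = ExpressionMatrix(x, pd.Index([f"c{i}" for i in range(n)]),
                         pd.Index([f"f{j}" for j in range(n_features)]),
                         state="scaled")
    lab = pd.Series(labels, index=m.cell_ids)
    chance = chance_purity(lab)
    scores = [permutation_control(m, lab, k=10, seed=_sub_seed(seed, 900 + j))
              for j in range(n_permutations)]
    emb = supervised_projection(m, lab, k=10, seed=_sub_seed(seed, 9))
    purity = neighbour_label_purity(emb, lab)
    return {
        "chance_rate": float(chance),
        "permuted_purity_mean": float(np.mean(scores)),
        "permuted_purity_sd": float(np.std(scores, ddof=1)),
        "unpermuted_purity": float(purity),
        "n_permutations": n_permutations,
    }


def pipeline_end_to_end(seed: int, outdir=None) -> dict:
    """Run the full pipeline from one config and count the emitted tables."""
    from .pipeline import run_pipeline

    layers = ["L23", "L5", "L6b"]
    ontology = {"glut": {s: {f"{s}_a": 60, f"{s}_b": 60} for s in layers}}
    ontology["gaba"] = {"Pvalb": {"Pvalb_a": 60, "Pvalb_b": 60}}
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 10),
        ontology=ontology,
        n_genes=80,
        planted_effects=[PlantedEffect("gene_constant_shift", "g001", "L23", 0.8,
                                       {"gene_mean": 10.0})],
        spatial=SpatialConfig(layer_order=layers, cells_per_subclass=150),
        batch_dates=["d1", "d2"],
    )
    expected = ["annotation.tsv", "cells.tsv", "truth.json", "iso_tests.tsv",
                "gene_tests.tsv", "shifts.tsv", "markers.tsv",
                "sex_differential.tsv", "regulation.tsv", "atlas.tsv",
                "merfish_markers.tsv", "depth_regression.tsv", "crossplat.tsv",
                "batch_mixing.tsv", "refinement.tsv", "spatial.tsv",
                "ec_map.json"]
    if outdir is None:
        with tempfile.TemporaryDirectory() as td:
            run_pipeline(cfg, td)
            present = [f for f in expected if (Path(td) / f).exists()]
    else:
        run_pipeline(cfg, outdir)
        present = [f for f in expected if (Path(outdir) / f).exists()]
    return {"n_tables_expected": len(expected), "n_tables_written": len(present)}
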