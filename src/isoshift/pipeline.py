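"""End-to-end pipeline: simulate -> preprocess -> differential -> TSS ->
spatial -> cross-platform -> refinement, from a single config.

Primarily a convenience for the CLI and for schema-level smoke tests; each
stage is just a call into the corresponding module, and every output table
is written under the output directory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import crossplatform, diffexp, io, preprocess, simulate, spatial

logger = logging.getLogger(__name__)


def run_pipeline(config: simulate.SimulationConfig, outdir) -> dict[str, object]:
    """Run every stage on one simulated dataset and write all output tables.

    Returns a dict of the in-memory results keyed by stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}

    # -- simulate ---------------------------------------------------------
    ann = simulate.simulate_annotation(config)
    counts, cells, truth = simulate.simulate_counts(config, ann)
    tcc, ec_map = simulate.simulate_tcc(config, ann, counts)
    io.write_annotation(ann, outdir / "annotation.tsv")
    io.write_cells(cells, outdir / "cells.tsv")
    io.write_mtx(counts, outdir / "isoform_counts")
    io.write_mtx(tcc, outdir / "tcc")
    io.write_ec_map(ec_map, outdir / "ec_map.json")
    truth.to_json(outdir / "truth.json")
    results.update(annotation=ann, cells=cells, counts=counts, truth=truth)

    # -- preprocess -------------------------------------------------------
    filtered = preprocess.filter_features(counts, ann["gene_id"])
    gene_counts = preprocess.aggregate_genes(filtered, ann["gene_id"])
    gene_kept, kept_cells = preprocess.filter_cells(gene_counts, min_counts=50, max_mito=0.25)
    iso_kept = filtered.subset_cells(kept_cells.to_numpy(dtype=object))
    cells_kept = cells.loc[kept_cells]
    _, iso_log, iso_scaled = preprocess.normalize_log_scale(iso_kept)
    _, gene_log, _ = preprocess.normalize_log_scale(gene_kept)
    iso_from_tcc = preprocess.tcc_to_isoform(tcc, ec_map)
    results.update(iso_log=iso_log, gene_log=gene_log, iso_from_tcc=iso_from_tcc)

    # -- differential -----------------------------------------------------
    level = "cluster" if sum(len(c) for s in config.ontology.values()
                             for c in s.values()) > 1 else "class"
    iso_tests = diffexp.cluster_vs_rest_test(iso_log, cells_kept, level=level)
    gene_tests = diffexp.cluster_vs_rest_test(gene_log, cells_kept, level=level)
    shifts = diffexp.detect_gene_constant_shifts(iso_tests, gene_tests, ann["gene_id"])
    markers = diffexp.detect_markers(iso_tests)
    sex = diffexp.sex_differential(iso_log, cells_kept)
    for name, tab in (("iso_tests", iso_tests), ("gene_tests", gene_tests),
                      ("shifts", shifts), ("markers", markers), ("sex_differential", sex)):
        tab.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        results[name] = tab

    # -- TSS --------------------------------------------------------------
    tss_counts = diffexp.build_tss_matrix(iso_kept, ann)
    _, tss_log, _ = preprocess.normalize_log_scale(tss_counts)
    class_iso = diffexp.cluster_vs_rest_test(iso_log, cells_kept, level="class")
    class_tss = diffexp.cluster_vs_rest_test(tss_log, cells_kept, level="class")
    regulation = diffexp.classify_regulation(class_tss, class_iso, ann)
    regulation.to_csv(outdir / "regulation.tsv", sep="\t", index=False)
    results["regulation"] = regulation

    # -- spatial ----------------------------------------------------------
    if config.spatial is not None:
        sp_map, panel, sp_cells = simulate.simulate_spatial(config)
        io.write_spatial(sp_map, outdir / "spatial.tsv")
        io.write_mtx(panel, outdir / "panel")
        rep = spatial.representative_slice(sp_map)
        one = sp_map[sp_map["slice_id"] == rep]
        _, panel_log, _ = preprocess.normalize_log_scale(panel)
        sp_markers = spatial.merfish_subclass_markers(panel_log, sp_cells)
        model = spatial.fit_boundary(one)
        model = spatial.subclass_depths(one, sp_cells, model)
        if len(model.depths) >= 3:
            gradient = spatial.depth_regression(panel, sp_cells, model,
                                                expressed_fraction=0.0)
        else:
            logger.warning("fewer than 3 spatial layers; depth regression skipped")
            gradient = pd.DataFrame(
                columns=["isoform_id", "slope", "slope_se", "intercept", "F_p_raw",
                         "F_p_adj", "monotonic", "subclass_means", "subclass_variances"])
        sub_markers = diffexp.cluster_vs_rest_test(iso_log, cells_kept, level="subclass")
        atlas = spatial.extrapolate_isoforms(
            sp_markers,
            diffexp.detect_markers(sub_markers, expressed_fraction=0.0),
            pd.concat([ann, _panel_annotation(panel)]),
        )
        atlas.to_csv(outdir / "atlas.tsv", sep="\t", index=False)
        sp_markers.to_csv(outdir / "merfish_markers.tsv", sep="\t", index=False)
        gradient.drop(columns=["subclass_means", "subclass_variances"]).to_csv(
            outdir / "depth_regression.tsv", sep="\t", index=False)
        results.update(atlas=atlas, depth_model=model, depth_regression=gradient,
                       merfish_markers=sp_markers)

    # -- cross-platform ---------------------------------------------------
    report = crossplatform.cluster_correlation(iso_kept, iso_kept, cells_kept,
                                               cells_kept, level=level)
    mixing = crossplatform.batch_mixing_check(cells_kept)
    report.to_csv(outdir / "crossplat.tsv", sep="\t", index=False)
    mixing.to_csv(outdir / "batch_mixing.tsv", sep="\t", index=False)
    results.update(crossplat=report, batch_mixing=mixing)

    # -- refinement -------------------------------------------------------
    from .projection import recluster_by_isoform

    refine_rows = []
    for cluster in pd.unique(cells_kept["cluster_label"]):
        res = recluster_by_isoform(iso_kept, cells_kept, cluster, ann["gene_id"],
                                   seed=config.seed)
        refine_rows.append({
            "cluster_id": res.cluster_id, "split": res.split, "reason": res.reason,
            "isoform_effect_size": res.isoform_effect_size,
            "gene_effect_size": res.gene_effect_size,
        })
    refinement = pd.DataFrame(refine_rows)
    refinement.to_csv(outdir / "refinement.tsv", sep="\t", index=False)
    results["refinement"] = refinement
    return results


def _panel_annotation(panel) -> pd.DataFrame:
    """Minimal annotation rows for panel genes (gene id = its own feature)."""
    import pandas as pd

    ann = pd.DataFrame({
        "transcript_id": panel.feature_ids,
        "gene_id": panel.feature_ids,
        "length": 1000,
        "strand": "+",
        "tss_coord": 0,
        "tss_group": [f"{g}:ts1" for g in panel.feature_ids],
        "end_group": [f"{g}:es1" for g in panel.feature_ids],
        "unique3p": True,
    })
    return ann.set_index("transcript_id")
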