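"""Differential testing: t-test oracles, shift/marker rules, TSS regulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import isoshift as iso
from isoshift.stats import bonferroni, ttest_matrix

from conftest import make_matrix


def hand_pooled_t(x, y):
    """Textbook pooled-variance two-sample t, evaluated longhand."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sps.t.sf(abs(t), nx + ny - 2)
    return t, p


class TestTtest:
    def test_identical_samples_t0_p1(self):
        x = np.array([[1.0], [2.0], [3.0]])
        t, p = ttest_matrix(x, x.copy())
        assert t[0] == 0.0 and p[0] == 1.0

    def test_hand_computed_toy(self):
        x = np.array([2, 2, 2, 2, 2, 2, 3], dtype=float)[:, None]
        y = np.array([0, 0, 0, 0, 0, 0, 1], dtype=float)[:, None]
        t, p = ttest_matrix(x, y)
        ht, hp = hand_pooled_t(x.ravel(), y.ravel())
        assert abs(t[0] - ht) < 1e-10 and abs(p[0] - hp) < 1e-10

    def test_matches_scipy_on_random_toys(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=(7, 12))
            y = rng.normal(size=(9, 12))
            t, p = ttest_matrix(x, y)
            st, sp_ = sps.ttest_ind(x, y)
            np.testing.assert_allclose(t, st, atol=1e-10)
            np.testing.assert_allclose(p, sp_, atol=1e-10)
            tw, pw = ttest_matrix(x, y, equal_var=False)
            stw, spw = sps.ttest_ind(x, y, equal_var=False)
            np.testing.assert_allclose(tw, stw, atol=1e-10)
            np.testing.assert_allclose(pw, spw, atol=1e-10)

    def test_degenerate_constant_unequal(self):
        x = np.full((3, 1), 2.0)
        y = np.full((4, 1), 5.0)
        t, p = ttest_matrix(x, y)
        assert np.isinf(t[0]) and t[0] < 0 and p[0] == 0.0

    def test_bonferroni_caps_at_one(self):
        np.testing.assert_array_equal(bonferroni(np.array([0.5, 1e-4]), 10),
                                      [1.0, 1e-3])


class TestClusterVsRest:
    def test_small_group_skipped(self, caplog):
        vals = np.random.default_rng(1).poisson(5, size=(20, 4)).astype(float)
        m = make_matrix(np.log1p(vals), feature_ids=list("abcd"))
        labels = pd.Series(["big"] * 15 + ["tiny"] * 5, index=m.cell_ids)
        tab = iso.cluster_vs_rest_test(m, labels, level="cluster")
        assert set(tab["group"]) == {"big"}

    def test_family_is_per_comparison(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(30, 10)), state="log1p")
        labels = pd.Series(["a"] * 15 + ["b"] * 15, index=m.cell_ids)
        tab = iso.cluster_vs_rest_test(m, labels, level="cluster")
        np.testing.assert_allclose(tab["p_adj"],
                                   np.minimum(1.0, tab["p_raw"] * 10))


def _tests_row(fid, group, p_adj, mean_in, mean_out, frac=1.0, level="isoform"):
    return {"feature_id": fid, "feature_level": level, "ontology_level": "class",
            "group": group, "mean_in": mean_in, "mean_out": mean_out,
            "t_statistic": 1.0, "p_raw": p_adj, "p_adj": p_adj,
            "expressed_fraction_in": frac, "category": "test"}


class TestGeneConstantShifts:
    def test_rule_logic_on_constructed_tables(self):
        iso_tests = pd.DataFrame([
            _tests_row("t1", "A", 1e-5, 5, 1),            # qualifies
            _tests_row("t2", "A", 1e-5, 5, 1, frac=0.8),  # fails 90% rule
            _tests_row("t3", "A", 1e-5, 1, 5),            # downregulated
            _tests_row("t4", "A", 0.5, 5, 1),             # not significant
            _tests_row("t5", "A", 1e-5, 5, 1),            # gene significant
        ])
        gene_tests = pd.DataFrame([
            _tests_row("g1", "A", 0.9, 3, 3, level="gene"),
            _tests_row("g5", "A", 1e-6, 9, 1, level="gene"),
        ])
        gmap = pd.Series({"t1": "g1", "t2": "g1", "t3": "g1", "t4": "g1", "t5": "g5"})
        out = iso.detect_gene_constant_shifts(iso_tests, gene_tests, gmap)
        assert list(out["feature_id"]) == ["t1"]
        assert (out["category"] == "gene_constant_shift").all()

    def test_missing_parent_gene_errors(self):
        iso_tests = pd.DataFrame([_tests_row("t1", "A", 1e-5, 5, 1)])
        gene_tests = pd.DataFrame([_tests_row("gOther", "A", 0.5, 1, 1, level="gene")])
        with pytest.raises(ValueError, match="g1"):
            iso.detect_gene_constant_shifts(iso_tests, gene_tests,
                                            pd.Series({"t1": "g1"}))

    def test_single_isoform_gene_never_reported(self, two_class_config):
        """Isoform == gene values, so isoform significance implies gene
        significance and the gene-constant filter removes it."""
        cfg = two_class_config(seed=13, n_cells=200, n_genes=40,
                               effects=[iso.PlantedEffect("marker", "g001-t1",
                                                          "glut", 5.0)])
        cfg.isoforms_per_gene = {1: 1.0}
        ann = iso.simulate_annotation(cfg)
        m, cells, _ = iso.simulate_counts(cfg, ann)
        _, iso_log, _ = iso.normalize_log_scale(m)
        gene_log = iso.log1p(iso.to_tpm(iso.aggregate_genes(m, ann["gene_id"])))
        it = iso.cluster_vs_rest_test(iso_log, cells, level="class")
        gt = iso.cluster_vs_rest_test(gene_log, cells, level="class")
        out = iso.detect_gene_constant_shifts(it, gt, ann["gene_id"])
        assert "g001-t1" not in set(out["feature_id"])

    def test_planted_swap_recovered(self, two_class_config):
        eff = iso.PlantedEffect("gene_constant_shift", "g003", "gaba", 0.8,
                                {"gene_mean": 10.0})
        cfg = two_class_config(seed=14, n_cells=500, n_genes=50, effects=[eff])
        ann = iso.simulate_annotation(cfg)
        m, cells, truth = iso.simulate_counts(cfg, ann)
        _, iso_log, _ = iso.normalize_log_scale(m)
        gene_log = iso.log1p(iso.to_tpm(iso.aggregate_genes(m, ann["gene_id"])))
        it = iso.cluster_vs_rest_test(iso_log, cells, level="class")
        gt = iso.cluster_vs_rest_test(gene_log, cells, level="class")
        out = iso.detect_gene_constant_shifts(it, gt, ann["gene_id"])
        up = truth.effects[0]["up_transcript"]
        assert ((out["feature_id"] == up) & (out["group"] == "gaba")).any()


class TestMarkers:
    def test_shifts_are_subset_of_markers(self, two_class_config):
        eff = iso.PlantedEffect("gene_constant_shift", "g002", "glut", 0.8,
                                {"gene_mean": 12.0})
        cfg = two_class_config(seed=15, n_cells=300, n_genes=40, effects=[eff])
        ann = iso.simulate_annotation(cfg)
        m, cells, _ = iso.simulate_counts(cfg, ann)
        _, iso_log, _ = iso.normalize_log_scale(m)
        gene_log = iso.log1p(iso.to_tpm(iso.aggregate_genes(m, ann["gene_id"])))
        it = iso.cluster_vs_rest_test(iso_log, cells, level="class")
        gt = iso.cluster_vs_rest_test(gene_log, cells, level="class")
        shifts = iso.detect_gene_constant_shifts(it, gt, ann["gene_id"])
        markers = iso.detect_markers(it)
        key = lambda t: set(map(tuple, t[["feature_id", "group"]].values))
        assert key(shifts) <= key(markers)

    def test_planted_marker_recovered(self, two_class_config):
        eff = iso.PlantedEffect("marker", "g004-t1", "glut", 4.0)
        cfg = two_class_config(seed=16, n_cells=100, n_genes=40, effects=[eff])
        ann = iso.simulate_annotation(cfg)
        m, cells, _ = iso.simulate_counts(cfg, ann)
        _, iso_log, _ = iso.normalize_log_scale(m)
        it = iso.cluster_vs_rest_test(iso_log, cells, level="class")
        markers = iso.detect_markers(it, expressed_fraction=0.0)
        assert ((markers["feature_id"] == "g004-t1")
                & (markers["group"] == "glut")).any()


class TestSexDifferential:
    def test_planted_effect_localized_and_exclusions(self, two_class_config):
        eff = iso.PlantedEffect("sex_effect", "g001-t1", "Lg", 6.0)
        cfg = two_class_config(seed=17, n_cells=300, n_genes=40, effects=[eff])
        ann = iso.simulate_annotation(cfg)
        m, cells, _ = iso.simulate_counts(cfg, ann)
        _, iso_log, _ = iso.normalize_log_scale(m)
        tab = iso.sex_differential(iso_log, cells)
        hits = tab[tab["feature_id"] == "g001-t1"]
        assert set(hits["group"]) == {"Lg"}
        excluded = iso.sex_differential(iso_log, cells, exclusions={"Lg"})
        assert "Lg" not in set(excluded["group"])

    def test_null_few_findings(self, two_class_config):
        cfg = two_class_config(seed=18, n_cells=300, n_genes=60)
        ann = iso.simulate_annotation(cfg)
        m, cells, _ = iso.simulate_counts(cfg, ann)
        _, iso_log, _ = iso.normalize_log_scale(m)
        tab = iso.sex_differential(iso_log, cells)
        assert len(tab) <= 2


class TestTssMatrix:
    def test_hand_sums_and_conservation(self):
        ann = pd.DataFrame({
            "transcript_id": ["t1", "t2", "t3"],
            "gene_id": "g1", "length": 1000, "strand": "+",
            "tss_coord": [100, 100, 500],
            "tss_group": ["g1:ts1", "g1:ts1", "g1:ts2"],
            "end_group": ["g1:es1", "g1:es2", "g1:es3"],
            "unique3p": True,
        }).set_index("transcript_id")
        m = make_matrix([[1, 2, 5], [3, 0, 4]], feature_ids=["t1", "t2", "t3"])
        out = iso.build_tss_matrix(m, ann)
        assert out.feature_level == "tss_group"
        got = pd.DataFrame(out.dense(), columns=out.feature_ids)
        np.testing.assert_array_equal(got["g1:ts1"], [3, 3])
        np.testing.assert_array_equal(got["g1:ts2"], [5, 4])
        np.testing.assert_allclose(out.cell_totals(), m.cell_totals())


class TestClassifyRegulation:
    @staticmethod
    def _setup(effects, seed, n_cells=500):
        cfg = iso.SimulationConfig(
            seed=seed,
            ontology={"glut": {"Lg": {"cg": n_cells}},
                      "gaba": {"Lb": {"cb": n_cells}}},
            n_genes=80, planted_effects=effects,
        )
        ann = iso.simulate_annotation(cfg)
        m, cells, truth = iso.simulate_counts(cfg, ann)
        _, iso_log, _ = iso.normalize_log_scale(m)
        tss_log = iso.log1p(iso.to_tpm(iso.build_tss_matrix(m, ann)))
        it = iso.cluster_vs_rest_test(iso_log, cells, level="class")
        tt = iso.cluster_vs_rest_test(tss_log, cells, level="class")
        return iso.classify_regulation(tt, it, ann), truth

    def test_planted_transcriptional_classified(self):
        eff = iso.PlantedEffect("tss_transcriptional", "g001:ts1", "glut", 4.0,
                                {"n_members": 24, "member_mean": 0.0025})
        reg, _ = self._setup([eff], seed=19)
        hit = reg[(reg["tss_group"] == "g001:ts1") & (reg["group"] == "glut")]
        assert set(hit["category"]) == {"tss_transcriptional"}

    def test_planted_post_transcriptional_classified(self):
        eff = iso.PlantedEffect("tss_post_transcriptional", "g001:ts1", "glut", 4.0,
                                {"n_members": 2, "tss_mean": 10.0})
        reg, truth = self._setup([eff], seed=20)
        hit = reg[(reg["tss_group"] == "g001:ts1") & (reg["group"] == "glut")]
        assert set(hit["category"]) == {"tss_post_transcriptional"}
        assert truth.effects[0]["up_transcript"] in set(hit["feature_id"])

    def test_categories_disjoint_per_tss_and_group(self):
        effs = [
            iso.PlantedEffect("tss_transcriptional", "g001:ts1", "glut", 4.0,
                              {"n_members": 24, "member_mean": 0.0025}),
            iso.PlantedEffect("tss_post_transcriptional", "g002:ts1", "gaba", 4.0,
                              {"n_members": 2, "tss_mean": 10.0}),
        ]
        reg, _ = self._setup(effs, seed=21)
        combos = reg.groupby(["tss_group", "group"])["category"].nunique()
        assert (combos == 1).all()

    def test_single_isoform_tss_never_post_transcriptional(self):
        eff = iso.PlantedEffect("marker", "g001-t1", "glut", 5.0)
        cfg = iso.SimulationConfig(
            seed=22, ontology={"glut": {"Lg": {"cg": 200}},
                               "gaba": {"Lb": {"cb": 200}}},
            n_genes=40, isoforms_per_gene={1: 1.0}, planted_effects=[eff],
        )
        ann = iso.simulate_annotation(cfg)
        m, cells, _ = iso.simulate_counts(cfg, ann)
        _, iso_log, _ = iso.normalize_log_scale(m)
        tss_log = iso.log1p(iso.to_tpm(iso.build_tss_matrix(m, ann)))
        it = iso.cluster_vs_rest_test(iso_log, cells, level="class")
        tt = iso.cluster_vs_rest_test(tss_log, cells, level="class")
        # align feature ids: single-isoform TSS tests equal isoform tests
        reg = iso.classify_regulation(tt, it, ann)
        assert not (reg["category"] == "tss_post_transcriptional").any()
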