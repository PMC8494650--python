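"""Normalization, filtering, HVG selection and TCC extraction."""

import numpy as np
import pandas as pd
import pytest

import isoshift as iso
from isoshift.preprocess import log1p, scale, to_tpm

from conftest import make_matrix


def _ann(gene_of: dict, lengths: dict | None = None):
    tids = list(gene_of)
    return pd.DataFrame({
        "transcript_id": tids,
        "gene_id": [gene_of[t] for t in tids],
        "length": [(lengths or {}).get(t, 1000) for t in tids],
        "strand": "+",
        "tss_coord": range(len(tids)),
        "tss_group": [f"{gene_of[t]}:ts{i}" for i, t in enumerate(tids)],
        "end_group": [f"{gene_of[t]}:es{i}" for i, t in enumerate(tids)],
        "unique3p": True,
    }).set_index("transcript_id")


class TestLengthNormalize:
    def test_definition_and_zero(self):
        m = make_matrix([[10, 0], [5, 3]], feature_ids=["t1", "t2"])
        ann = _ann({"t1": "g1", "t2": "g1"}, {"t1": 1000, "t2": 100})
        out = iso.length_normalize(m, ann)
        np.testing.assert_allclose(out.dense(), [[0.01, 0.0], [0.005, 0.03]])
        assert out.state == "length_normalized"

    def test_homogeneity_doubling_lengths_halves(self):
        m = make_matrix([[10, 4], [5, 3]], feature_ids=["t1", "t2"])
        a = iso.length_normalize(m, _ann({"t1": "g1", "t2": "g1"},
                                         {"t1": 500, "t2": 200}))
        b = iso.length_normalize(m, _ann({"t1": "g1", "t2": "g1"},
                                         {"t1": 1000, "t2": 400}))
        np.testing.assert_allclose(b.dense(), a.dense() / 2)

    def test_missing_length_lists_transcripts(self):
        m = make_matrix([[1, 2]], feature_ids=["t1", "tX"])
        with pytest.raises(ValueError, match="tX"):
            iso.length_normalize(m, _ann({"t1": "g1"}))


class TestFilterFeatures:
    def test_all_zero_isoform_dropped(self):
        m = make_matrix([[5, 0], [3, 0]], feature_ids=["t1", "t2"])
        out = iso.filter_features(m, pd.Series({"t1": "g1", "t2": "g2"}))
        assert list(out.feature_ids) == ["t1"]

    def test_constant_gene_dropped_by_dispersion(self):
        # g2 constant across cells: dispersion 0 < 0.001 -> dropped with isoform
        m = make_matrix([[5, 2], [3, 2], [9, 2]], feature_ids=["t1", "t2"])
        out = iso.filter_features(m, pd.Series({"t1": "g1", "t2": "g2"}))
        assert list(out.feature_ids) == ["t1"]

    def test_toy_matches_hand_evaluation(self):
        # oracle: per-gene variance/mean computed by hand.
        # g1 = t1+t2 -> [3, 3, 3]: dispersion 0 -> dropped.
        # g2 = t3    -> [0, 4, 8]: mean 4, var 32/3 -> dispersion 8/3 -> kept.
        m = make_matrix([[1, 2, 0], [2, 1, 4], [0, 3, 8]],
                        feature_ids=["t1", "t2", "t3"])
        out = iso.filter_features(m, pd.Series({"t1": "g1", "t2": "g1", "t3": "g2"}))
        assert list(out.feature_ids) == ["t3"]

    def test_idempotent(self, simulated):
        _, ann, m, _, _ = simulated
        once = iso.filter_features(m, ann["gene_id"])
        twice = iso.filter_features(once, ann["gene_id"])
        assert list(once.feature_ids) == list(twice.feature_ids)
        assert (once.values != twice.values).nnz == 0

    def test_empty_result_advises(self):
        m = make_matrix([[1], [1]], feature_ids=["t1"])
        with pytest.raises(ValueError, match="min_count|min_dispersion"):
            iso.filter_features(m, pd.Series({"t1": "g1"}))


class TestFilterCells:
    def test_boundary_semantics(self):
        # row 0: total 249 -> removed; row 1: total 250, mito exactly 10% -> kept
        m = make_matrix([[249, 0], [225, 25]], feature_ids=["g1", "mt-1"],
                        feature_level="gene")
        kept, ids = iso.filter_cells(m, min_counts=250, max_mito=0.10)
        assert list(ids) == ["c1"]

    def test_identity_when_all_pass(self):
        m = make_matrix([[300, 1], [400, 2]], feature_ids=["g1", "mt-1"],
                        feature_level="gene")
        kept, ids = iso.filter_cells(m, min_counts=250, max_mito=0.10)
        assert list(ids) == ["c0", "c1"]


class TestAggregateGenes:
    def test_single_isoform_gene_passthrough_and_hand_sums(self):
        m = make_matrix([[1, 2, 5], [3, 4, 0]], feature_ids=["t1", "t2", "t3"])
        out = iso.aggregate_genes(m, pd.Series({"t1": "g1", "t2": "g1", "t3": "g2"}))
        np.testing.assert_array_equal(out.dense(), [[3, 5], [7, 0]])
        assert out.feature_level == "gene"

    def test_totals_conserved(self, simulated):
        _, ann, m, _, _ = simulated
        out = iso.aggregate_genes(m, ann["gene_id"])
        np.testing.assert_allclose(out.cell_totals(), m.cell_totals())

    def test_unmapped_isoform_errors(self):
        m = make_matrix([[1, 2]], feature_ids=["t1", "tX"])
        with pytest.raises(ValueError, match="tX"):
            iso.aggregate_genes(m, pd.Series({"t1": "g1"}))


class TestNormalizeLogScale:
    def test_tpm_arithmetic(self):
        m = make_matrix([[1, 1, 2]])
        tpm, _, _ = iso.normalize_log_scale(m)
        np.testing.assert_allclose(tpm.dense(), [[250000, 250000, 500000]])

    def test_tpm_scale_invariance(self):
        a = make_matrix([[1, 3], [2, 2]])
        b = make_matrix([[7, 21], [2, 2]])
        np.testing.assert_allclose(to_tpm(a).dense(), to_tpm(b).dense())

    def test_tpm_sums_exact_one_million(self, simulated):
        _, _, m, _, _ = simulated
        tpm, _, _ = iso.normalize_log_scale(m)
        np.testing.assert_allclose(tpm.cell_totals(), 1e6, rtol=1e-9)

    def test_scaled_features_standardized(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.poisson(5, size=(40, 6)) + 1)
        _, _, scaled = iso.normalize_log_scale(m)
        dense = scaled.dense()
        np.testing.assert_allclose(dense.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(dense.var(axis=0), 1, atol=1e-12)

    def test_zero_total_cell_listed(self):
        m = make_matrix([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="c0"):
            iso.normalize_log_scale(m)

    def test_zero_variance_feature_scaled_to_zero(self):
        m = make_matrix([[2, 1], [2, 3], [2, 5]])
        out = scale(m)
        np.testing.assert_array_equal(out.dense()[:, 0], 0.0)


def brute_force_hvg(values: np.ndarray, feature_ids, n_top: int, n_bins: int):
    """Independent reimplementation of the binned dispersion z-score."""
    mean = values.mean(axis=0)
    var = values.var(axis=0)
    disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="stable")
    nf = len(mean)
    bin_of = np.empty(nf, dtype=int)
    for rank, j in enumerate(order):
        bin_of[j] = (rank * n_bins) // nf
    z = np.zeros(nf)
    for b in set(bin_of):
        members = np.flatnonzero(bin_of == b)
        if len(members) < 2 or disp[members].std() == 0:
            continue
        z[members] = (disp[members] - disp[members].mean()) / disp[members].std()
    ranked = np.argsort(-z, kind="stable")
    return [feature_ids[j] for j in ranked[:min(n_top, nf)]]


class TestSelectHvg:
    def test_clamps_to_available_features(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.poisson(3, size=(30, 25)))
        got = iso.select_hvg(m, n_top=5000, n_bins=5)
        assert len(got) == 25

    def test_inflated_variance_feature_ranked_first(self):
        # one bin: all features are same-mean peers, one with inflated spread
        rng = np.random.default_rng(2)
        base = rng.poisson(10, size=(200, 20)).astype(float)
        base[:, 7] = np.maximum(10 + (base[:, 7] - 10) * 6, 0)
        m = make_matrix(base)
        got = iso.select_hvg(m, n_top=5, n_bins=1)
        assert got[0] == "f7"

    def test_constant_feature_ranks_below_varying(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(5, size=(50, 20)).astype(float)
        vals[:, 3] = 5.0
        m = make_matrix(vals)
        ranking = list(iso.select_hvg(m, n_top=20, n_bins=4))
        assert ranking.index("f3") > 9

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        vals = np.log1p(rng.poisson(4, size=(60, 48)).astype(float))
        m = make_matrix(vals)
        got = list(iso.select_hvg(m, n_top=48, n_bins=8))
        expected = brute_force_hvg(vals, list(m.feature_ids), 48, 8)
        assert got == expected


class TestTccToIsoform:
    def test_all_singletons_relabel(self):
        m = make_matrix([[1, 2], [3, 4]], feature_ids=["ec1", "ec2"],
                        feature_level="equivalence_class")
        out = iso.tcc_to_isoform(m, {"ec1": ["tA"], "ec2": ["tB"]})
        assert list(out.feature_ids) == ["tA", "tB"]
        np.testing.assert_array_equal(out.dense(), m.dense())

    def test_multi_transcript_class_discarded(self):
        m = make_matrix([[1, 2]], feature_ids=["ec1", "ec2"],
                        feature_level="equivalence_class")
        out = iso.tcc_to_isoform(m, {"ec1": ["tA"], "ec2": ["tB", "tC"]})
        assert list(out.feature_ids) == ["tA"]

    def test_ambiguous_singletons_error(self):
        m = make_matrix([[1, 2]], feature_ids=["ec1", "ec2"],
                        feature_level="equivalence_class")
        with pytest.raises(ValueError, match="multiple singleton"):
            iso.tcc_to_isoform(m, {"ec1": ["tA"], "ec2": ["tA"]})

    def test_recovers_simulator_truth(self, simulated):
        cfg, ann, m, _, _ = simulated
        tcc, ec_map = iso.simulate_tcc(cfg, ann, m)
        out = iso.tcc_to_isoform(tcc, ec_map)
        unique = sorted(ann.index[ann["unique3p"]])
        assert sorted(out.feature_ids) == unique
        order = np.asarray(unique, dtype=object)
        a = out.subset_features(order).dense()
        b = m.subset_features(order).dense()
        np.testing.assert_array_equal(a, b)

    def test_total_count_never_exceeds_input(self, simulated):
        cfg, ann, m, _, _ = simulated
        tcc, ec_map = iso.simulate_tcc(cfg, ann, m)
        out = iso.tcc_to_isoform(tcc, ec_map)
        assert out.values.sum() <= tcc.values.sum()


class TestCompareNaiveEm:
    @staticmethod
    def _cells(n_per_class):
        rows = []
        for cls in ("A", "B"):
            for i in range(n_per_class):
                rows.append((f"{cls}{i}", cls, f"{cls}s", f"{cls}c"))
        return pd.DataFrame(rows, columns=["cell_id", "class_label",
                                           "subclass_label", "cluster_label"]
                            ).set_index("cell_id")

    def test_equal_lengths_concordant(self):
        rng = np.random.default_rng(5)
        n = 60
        vals = rng.poisson(20, size=(2 * n, 4)).astype(float)
        cells = self._cells(n)
        m = make_matrix(vals, cell_ids=list(cells.index),
                        feature_ids=["t1", "t2", "t3", "t4"])
        ann = _ann({"t1": "g1", "t2": "g1", "t3": "g2", "t4": "g2"})
        disc = iso.compare_naive_em(m, ann, cells, level="class")
        assert len(disc) == 0

    def test_length_confounded_shift_flagged_by_naive_only(self):
        # constant molecule count per gene; reads scale with length, and the
        # long<->short isoform swap between classes moves the naive sum only
        rng = np.random.default_rng(6)
        n = 100
        cells = self._cells(n)
        mol = rng.poisson(20, size=(2 * n, 2)).astype(float)
        lengths = {"t_long": 2000, "t_short": 200}
        counts = np.zeros((2 * n, 2))
        is_a = np.arange(2 * n) < n
        # class A expresses the long isoform, class B the short one
        counts[is_a, 0] = mol[is_a, 0] * (lengths["t_long"] / 100)
        counts[~is_a, 1] = mol[~is_a, 1] * (lengths["t_short"] / 100)
        # a stable reference gene so the result is not a single-feature family
        ref = rng.poisson(50, size=(2 * n, 1)).astype(float)
        m = make_matrix(np.hstack([counts, ref]), cell_ids=list(cells.index),
                        feature_ids=["t_long", "t_short", "t_ref"])
        ann = _ann({"t_long": "g1", "t_short": "g1", "t_ref": "g2"},
                   {**lengths, "t_ref": 100})
        disc = iso.compare_naive_em(m, ann, cells, level="class")
        g1 = disc[disc["feature_id"] == "g1"]
        assert len(g1) > 0
        # naive (base-count) quantification flags it; normalized does not
        assert (g1["p_adj_naive"] < 0.01).all()
        assert (g1["p_adj_norm"] >= 0.01).all()
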