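"""Regulatory-potential model: closed forms, the auto half-decay rule,
enhanced-model rules, differential targets and GRN assembly."""

import numpy as np
import pandas as pd
import pytest

from screg.intervals import GenomicInterval, PeakSet
from screg.simulate import make_rp_groups
from screg.targets import (
    GeneModel,
    build_grn,
    classify_tr_type,
    differential_targets,
    impute_tr_peaks,
    rank_targets,
    rp_score,
)


def peak_at(center, width=100, chrom="chr1"):
    return GenomicInterval(chrom, center - width // 2, center + width - width // 2)


GENE = GeneModel("G", "chr1", "+", 1_000_000)


class TestRpSimple:
    def test_peak_at_tss_scores_one(self):
        s = rp_score(PeakSet([peak_at(GENE.tss)]), [GENE], d0=1000)
        assert s["G"] == pytest.approx(1.0)

    def test_peak_at_d0_scores_half(self):
        s = rp_score(PeakSet([peak_at(GENE.tss + 1000)]), [GENE], d0=1000)
        assert s["G"] == pytest.approx(0.5)

    def test_peak_at_15d0_tiny_but_counted(self):
        s = rp_score(PeakSet([peak_at(GENE.tss + 15_000)]), [GENE], d0=1000)
        assert s["G"] == pytest.approx(2.0**-15)
        assert s["G"] < 0.0005

    def test_peak_beyond_cutoff_ignored(self):
        s = rp_score(PeakSet([peak_at(GENE.tss + 15_001)]), [GENE], d0=1000)
        assert s["G"] == 0.0

    def test_upstream_and_downstream_symmetric(self):
        up = rp_score(PeakSet([peak_at(GENE.tss - 3000)]), [GENE], d0=1000)
        down = rp_score(PeakSet([peak_at(GENE.tss + 3000)]), [GENE], d0=1000)
        assert up["G"] == down["G"] == pytest.approx(2.0**-3)

    def test_term_by_term_sum(self):
        peaks = PeakSet([peak_at(GENE.tss + 1000), peak_at(GENE.tss + 2000)])
        assert rp_score(peaks, [GENE], d0=1000)["G"] == pytest.approx(0.75)

    def test_additive_over_partitions(self):
        rng = np.random.default_rng(0)
        offsets = rng.integers(-14_000, 14_000, 30)
        peaks = [peak_at(GENE.tss + int(o)) for o in offsets]
        whole = rp_score(PeakSet(peaks), [GENE], d0=1000)["G"]
        parts = sum(
            rp_score(PeakSet(chunk), [GENE], d0=1000)["G"]
            for chunk in (peaks[:10], peaks[10:17], peaks[17:])
        )
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_truncation_bound(self):
        """Disabling the cutoff adds < 0.0005 per omitted peak."""
        offsets = [15_200, 20_000, 40_000, 100_000]
        peaks = PeakSet([peak_at(GENE.tss + o) for o in offsets])
        capped = rp_score(peaks, [GENE], d0=1000)["G"]
        uncapped = rp_score(peaks, [GENE], d0=1000, cutoff_multiplier=1e9)["G"]
        assert capped == 0.0
        assert uncapped - capped < 0.0005 * len(offsets)

    def test_halves_per_d0_step(self):
        d0 = 2000
        vals = [
            rp_score(PeakSet([peak_at(GENE.tss + k * d0)]), [GENE], d0=d0)["G"]
            for k in range(5)
        ]
        for a, b in zip(vals, vals[1:]):
            assert b == pytest.approx(a / 2)


class TestClassifyTrType:
    def _genes(self, n=10):
        return [
            GeneModel(f"g{i}", "chr1", "+", 100_000 + i * 200_000) for i in range(n)
        ]

    def _peaks(self, n_promoter, n_total):
        genes = self._genes()
        peaks = [peak_at(genes[i % 10].tss) for i in range(n_promoter)]
        peaks += [
            peak_at(genes[i % 10].tss + 50_000) for i in range(n_total - n_promoter)
        ]
        return PeakSet(peaks), genes

    def test_thirty_percent_is_promoter_type(self):
        peaks, genes = self._peaks(3, 10)
        assert classify_tr_type(peaks, genes) == ("promoter", 1000)

    def test_ten_percent_is_enhancer_type(self):
        peaks, genes = self._peaks(1, 10)
        assert classify_tr_type(peaks, genes) == ("enhancer", 10000)

    def test_exactly_twenty_percent_is_enhancer_type(self):
        peaks, genes = self._peaks(2, 10)
        assert classify_tr_type(peaks, genes) == ("enhancer", 10000)

    def test_empty_peaks_error(self):
        with pytest.raises(ValueError, match="no peaks"):
            classify_tr_type(PeakSet(), self._genes())


class TestRpEnhanced:
    def test_exon_peak_normalised_by_exon_kb(self):
        g = GeneModel(
            "G", "chr1", "+", 1_000_000,
            exons=(GenomicInterval("chr1", 1_002_000, 1_004_000),),  # 2 kb
        )
        s = rp_score(PeakSet([peak_at(1_003_000)]), [g], d0=1000, model="enhanced")
        assert s["G"] == pytest.approx(0.5)  # 1 / 2kb

    def test_peak_in_neighbor_promoter_contributes_zero(self):
        g = GeneModel("G", "chr1", "+", 1_000_000)
        neighbor = GeneModel("H", "chr1", "+", 1_005_000)
        s = rp_score(
            PeakSet([peak_at(neighbor.tss)]), [g, neighbor], d0=1000, model="enhanced"
        )
        assert s["G"] == 0.0
        assert s["H"] == pytest.approx(1.0)

    def test_degenerates_to_simple_when_rules_inactive(self):
        rng = np.random.default_rng(1)
        genes = [
            GeneModel(f"g{i}", "chr1", "+", 500_000 + i * 400_000) for i in range(5)
        ]
        peaks = PeakSet(
            [peak_at(g.tss + int(o)) for g in genes for o in rng.integers(3000, 14_000, 4)]
        )
        simple = rp_score(peaks, genes, d0=1000)
        enhanced = rp_score(peaks, genes, d0=1000, model="enhanced")
        pd.testing.assert_series_equal(simple, enhanced)

    def test_gene_without_exons_uses_decay(self):
        # the exon rule cannot fire for a gene with no exon spans
        g = GeneModel("G", "chr1", "+", 1_000_000, exons=())
        s = rp_score(PeakSet([peak_at(1_000_100)]), [g], d0=1000, model="enhanced")
        assert s["G"] > 0


class TestImputeTrPeaks:
    def test_cell_covers_all_dataset_peaks(self):
        ds = PeakSet([peak_at(10_000), peak_at(20_000)])
        cell = PeakSet([GenomicInterval("chr1", 0, 50_000)])
        assert list(impute_tr_peaks(cell, ds)) == list(ds)

    def test_disjoint_gives_empty(self):
        ds = PeakSet([peak_at(10_000)])
        cell = PeakSet([peak_at(500_000)])
        assert len(impute_tr_peaks(cell, ds)) == 0

    def test_output_subset_of_dataset(self):
        rng = np.random.default_rng(2)
        ds = PeakSet([peak_at(int(p)) for p in rng.integers(1000, 900_000, 50)])
        cell = PeakSet([peak_at(int(p), width=400) for p in rng.integers(1000, 900_000, 50)])
        out = impute_tr_peaks(cell, ds)
        assert all(iv in ds.intervals for iv in out)
        expected = [iv for iv in ds if any(iv.overlaps(c) for c in cell)]
        assert list(out) == expected

    def test_extended_pools_datasets(self):
        ds_a = PeakSet([peak_at(10_000)])
        ds_b = PeakSet([peak_at(20_000)])
        cell = PeakSet([GenomicInterval("chr1", 0, 50_000)])
        out = impute_tr_peaks(
            cell, ds_a, extended=True, all_best_datasets=[ds_a, ds_b]
        )
        assert len(out) == 2


class TestRankTargets:
    def test_orders_and_truncates(self):
        rp = pd.Series({"A": 2.0, "B": 1.0, "C": 0.0})
        assert rank_targets(rp, 2) == ["A", "B"]

    def test_zero_scores_never_reported(self):
        rp = pd.Series({"A": 2.0, "B": 0.0})
        assert rank_targets(rp, 1000) == ["A"]

    def test_ties_break_by_symbol(self):
        rp = pd.Series({"Z": 1.0, "A": 1.0, "M": 1.0})
        assert rank_targets(rp, 3) == ["A", "M", "Z"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        rp = pd.Series(rng.random(50), index=[f"g{i}" for i in range(50)])
        out = rank_targets(rp, 50)
        oracle = sorted(rp.index, key=lambda g: (-rp[g], g))
        assert out == oracle


class TestDifferentialTargets:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(4)
        rp = pd.DataFrame(
            rng.gamma(2, 1, (30, 10)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"c{i}" for i in range(10)],
        )
        out = differential_targets(rp, rp.rename(columns=lambda c: c + "b"))
        assert not out["significant"].any()

    def test_planted_shift_recovered(self):
        rp_a, rp_b, shifted = make_rp_groups(seed=5)
        out = differential_targets(rp_a, rp_b)
        sig = set(out.index[out["significant"]])
        assert len(sig & set(shifted)) >= 18
        # false positives stay near the nominal level of the joint threshold
        assert len(sig - set(shifted)) <= 4

    def test_all_zero_genes_dropped(self):
        rp_a, rp_b, _ = make_rp_groups(n_zero=7, seed=6)
        out = differential_targets(rp_a, rp_b)
        assert len(out) == len(rp_a) - 7

    def test_small_group_errors(self):
        rp_a, rp_b, _ = make_rp_groups(seed=7)
        with pytest.raises(ValueError, match="need >= 3"):
            differential_targets(rp_a.iloc[:, :2], rp_b)

    def test_boundaries_inclusive(self):
        out = pd.DataFrame({"logFC": [0.25], "p": [0.005]})
        sig = (out["logFC"].abs() >= 0.25) & (out["p"] <= 0.01)
        assert sig.all()
        rp_a, rp_b, _ = make_rp_groups(seed=8)
        table = differential_targets(rp_a, rp_b, logfc_cutoff=0.25, p_cutoff=0.01)
        manual = (table["logFC"].abs() >= 0.25) & (table["p"] <= 0.01)
        assert (table["significant"] == manual).all()


class TestBuildGrn:
    def _rp(self, data, cells):
        return pd.DataFrame(data, index=["g1", "g2", "g3"], columns=cells)

    def test_shared_target_one_node_two_edges(self):
        cells = ["c1", "c2", "c3"]
        labels = pd.Series("T", index=cells)
        rp_a = self._rp([[3, 3, 3], [0, 0, 0], [1, 1, 1]], cells)
        rp_b = self._rp([[2, 2, 2], [0, 0, 0], [0, 0, 0]], cells)
        grn = build_grn({"TFA": rp_a, "TFB": rp_b}, labels, top_cells=5, top_n=1)
        assert grn.genes == ["g1"]
        assert len(grn) == 2

    def test_top_cells_clamped(self):
        cells = [f"c{i}" for i in range(4)]
        labels = pd.Series("T", index=cells)
        rp = self._rp(np.ones((3, 4)), cells)
        grn = build_grn({"TFA": rp}, labels, top_cells=500, top_n=3)
        assert len(grn) == 3

    def test_unknown_label_errors(self):
        cells = ["c1", "c2"]
        rp = self._rp(np.ones((3, 2)), cells)
        with pytest.raises(ValueError, match="no label"):
            build_grn({"TFA": rp}, pd.Series({"c1": "T"}), top_cells=5, top_n=1)

    def test_manual_toy_construction(self):
        cells = ["x1", "x2", "y1", "y2"]
        labels = pd.Series(["X", "X", "Y", "Y"], index=cells)
        rp = pd.DataFrame(
            [[5.0, 4.0, 0.0, 0.0], [1.0, 1.0, 9.0, 8.0]],
            index=["gA", "gB"],
            columns=cells,
        )
        grn = build_grn({"TF": rp}, labels, top_cells=1, top_n=2, agg="max")
        edges = grn.edges.set_index(["context", "gene"])["weight"]
        assert edges[("X", "gA")] == 5.0
        assert edges[("Y", "gB")] == 9.0
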