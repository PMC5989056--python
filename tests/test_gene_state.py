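"""Gene filtering, state assignment, peak breadth, TSS AUC, metagene."""

import math

import numpy as np
import pandas as pd
import pytest

import epistate as es
from epistate.gene_state import GeneModel
from epistate.segmentation import GenomeBins, StateTrack


def track_from_states(states, bin_size=200, chrom="chrS"):
    bins = GenomeBins(chrom=chrom, n_bins=len(states), bin_size=bin_size)
    return StateTrack(bins=bins, states=np.asarray(states))


GTF_LINES = """\
1\tsrc\tgene\t1001\t3000\t.\t+\t.\tgene_id "gA"; gene_name "A"; gene_biotype "protein_coding"; tag "basic";
1\tsrc\tgene\t5001\t6000\t.\t-\t.\tgene_id "gB"; gene_name "B"; gene_biotype "lincRNA"; tag "basic";
1\tsrc\tgene\t7001\t8000\t.\t+\t.\tgene_id "gC"; gene_name "C"; gene_biotype "pseudogene"; tag "basic";
X\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "gD"; gene_name "D"; gene_biotype "protein_coding"; tag "basic";
1\tsrc\tgene\t9001\t9500\t.\t+\t.\tgene_id "gE"; gene_name "E"; gene_biotype "antisense";
"""


class TestLoadGeneModels:
    def test_filters_and_coordinate_conversion(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text(GTF_LINES)
        genes = es.load_gene_models(path)
        ids = [g.gene_id for g in genes]
        assert ids == ["gA", "gB"]  # pseudogene, chrX, and non-basic dropped
        assert genes[0].start == 1000 and genes[0].end == 3000
        assert genes[1].tss == 5999  # minus strand: TSS at interval end

    def test_filters_can_be_disabled(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text(GTF_LINES)
        genes = es.load_gene_models(path, allowed_biotypes=None,
                                    require_basic=False, allowed_chroms=None)
        assert len(genes) == 5

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\tonly\tthree\n")
        with pytest.raises(ValueError, match="line 1"):
            es.load_gene_models(path)


class TestAssignGeneStates:
    def test_direct_counting(self):
        track = track_from_states([1, 1, 2, 3])
        g = GeneModel("g", "g", "chrS", 0, 800, "+")
        table = es.assign_gene_states([g], track)
        row = table.iloc[0]
        assert row["genebody_state"] == 1
        assert row[["cov_state_1", "cov_state_2", "cov_state_3"]].tolist() == \
            [0.5, 0.25, 0.25]

    def test_tie_breaks_to_lower_state(self):
        track = track_from_states([2, 1])
        g = GeneModel("g", "g", "chrS", 0, 400, "+")
        assert es.assign_gene_states([g], track).iloc[0]["genebody_state"] == 1

    def test_tss_state_is_bin_state(self):
        track = track_from_states([1, 2, 3])
        g = GeneModel("g", "g", "chrS", 250, 550, "+")
        assert es.assign_gene_states([g], track).iloc[0]["tss_state"] == 2

    def test_partial_bin_weighting(self):
        track = track_from_states([1, 2])
        g = GeneModel("g", "g", "chrS", 150, 250, "+")  # 50 bp in each bin
        row = es.assign_gene_states([g], track).iloc[0]
        assert row["cov_state_1"] == pytest.approx(0.5)

    def test_off_chromosome_gene_excluded(self):
        track = track_from_states([1, 2])
        g = GeneModel("g", "g", "chrS", 5000, 5400, "+")
        assert len(es.assign_gene_states([g], track)) == 0

    def test_vector_matrix_rows_normalized(self, state_track, genes_truth):
        genes, _ = genes_truth
        table = es.assign_gene_states(genes, state_track)
        mat = es.gene_state_vector_matrix(table)
        assert np.abs(mat.sum(axis=1) - 1).max() < 1e-9
        # identical coverage -> identical rows
        hom = table[table["cov_state_1"] == 1.0]
        if len(hom) >= 2:
            assert np.allclose(mat[hom.index[0]], mat[hom.index[1]])


class TestPeakBreadth:
    peaks = pd.DataFrame({"chrom": "chrS",
                          "start": [100, 2000, 2300],
                          "end": [700, 2400, 3200]})
    genes = [GeneModel("g1", "G1", "chrS", 300, 1500, "+"),     # peak (100,700)
             GeneModel("g2", "G2", "chrS", 2350, 4000, "+"),    # two peaks
             GeneModel("g3", "G3", "chrS", 8000, 9000, "+")]    # no peak

    def test_breadth_definition_and_ranking(self):
        df = es.peak_breadth_rank(self.peaks, self.genes, tss_window=100)
        by = df.set_index("gene_id")
        assert by.loc["g1", "breadth"] == 600
        assert by.loc["g2", "breadth"] == 900  # widest overlapping peak wins
        assert by.loc["g3", "breadth"] == 0 and by.loc["g3", "rank"] == 3

    def test_rank_invariant_to_peak_order(self):
        shuffled = self.peaks.sample(frac=1, random_state=7)
        a = es.peak_breadth_rank(self.peaks, self.genes, 100)
        b = es.peak_breadth_rank(shuffled, self.genes, 100)
        pd.testing.assert_frame_equal(a, b)

    def test_ties_share_min_rank(self):
        peaks = pd.DataFrame({"chrom": "chrS", "start": [0, 1000],
                              "end": [500, 1500]})
        genes = [GeneModel("a", "a", "chrS", 100, 300, "+"),
                 GeneModel("b", "b", "chrS", 1100, 1300, "+")]
        df = es.peak_breadth_rank(peaks, genes, 100)
        assert (df["rank"] == 1).all()

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            es.peak_breadth_rank(self.peaks, self.genes, -1)


class TestTopBroadGeneset:
    def ranked(self, n):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                             "name": [f"G{i}" for i in range(n)],
                             "breadth": np.arange(n, 0, -1) * 10,
                             "rank": np.arange(1, n + 1)})

    def test_two_percent_of_100(self):
        assert len(es.top_broad_geneset(self.ranked(100))) == 2

    def test_exclusion_replaced_by_next_ranked(self):
        got = es.top_broad_geneset(self.ranked(100), exclude=["G0"])
        assert got == ["G1", "G2"]

    def test_full_slice(self):
        assert len(es.top_broad_geneset(self.ranked(10), top_pct=100)) == 10

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            es.top_broad_geneset(self.ranked(0))


class TestTssAuc:
    def test_zero_and_constant_coverage(self):
        g = GeneModel("g", "g", "chrS", 500, 900, "+")
        assert es.tss_auc(np.zeros(2000), g, 100, 10_000) == 0
        cov = np.full(2000, 3.0)
        expected = 3.0 * 201 * 1e6 / 10_000
        assert es.tss_auc(cov, g, 100, 10_000) == pytest.approx(expected)

    def test_depth_normalization_invariance(self):
        g = GeneModel("g", "g", "chrS", 500, 900, "+")
        cov = np.random.default_rng(0).poisson(4, 2000).astype(float)
        a = es.tss_auc(cov, g, 100, 5_000)
        b = es.tss_auc(2 * cov, g, 100, 10_000)
        assert a == pytest.approx(b)

    def test_window_truncated_at_chromosome_edge(self):
        g = GeneModel("g", "g", "chrS", 30, 400, "+")
        cov = np.ones(2000)
        assert es.tss_auc(cov, g, 100, 1e6) == pytest.approx(131.0)


class TestMetageneProfile:
    def test_constant_coverage_flat(self):
        cov = np.full(10_000, 2.0)
        genes = [GeneModel("g", "g", "chrS", 4000, 6000, "+")]
        prof = es.metagene_profile(cov, genes, library_size=1_000_000)
        assert np.allclose(prof, 2.0)

    def test_minus_strand_reverses_ramp(self):
        cov = np.arange(10_000, dtype=float)
        gp = GeneModel("g", "g", "chrS", 4000, 6000, "+")
        gm = GeneModel("g", "g", "chrS", 4000, 6000, "-")
        a = es.metagene_profile(cov, [gp])
        b = es.metagene_profile(cov, [gm])
        assert np.allclose(a, b[::-1])

    def test_union_is_weighted_mean(self):
        rng = np.random.default_rng(1)
        cov = rng.poisson(5, 20_000).astype(float)
        set_a = [GeneModel(f"a{i}", "", "chrS", 3000 + i * 500,
                           5000 + i * 500, "+") for i in range(3)]
        set_b = [GeneModel("b", "", "chrS", 9000, 12_000, "-")]
        pa = es.metagene_profile(cov, set_a)
        pb = es.metagene_profile(cov, set_b)
        pu = es.metagene_profile(cov, set_a + set_b)
        assert np.allclose(pu, (3 * pa + 1 * pb) / 4)
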