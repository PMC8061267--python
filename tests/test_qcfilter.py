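"""Filter-chain behaviour on hand-constructed matrices and simulated data."""

import numpy as np
import pytest

import stockscan as ss
from stockscan.datasets import MISSING, ReadCountTable
from stockscan.qcfilter import (build_microhaplotypes, filter_fis,
                                filter_microhap, filter_missingness, hdplot,
                                select_one_snp_per_tag, snp_fis)

from conftest import make_dataset


class TestMissingness:
    def test_complete_matrix_is_noop(self):
        g = np.tile([0, 1, 2, 1, 1, 2], (8, 1)).T
        ds = make_dataset(g, ["p"] * 6)
        out, report = filter_missingness(ds)
        assert out.genotypes.shape == (6, 8)
        assert report["individuals_dropped"] == 0
        assert report["snps_out"] == 8

    def test_toy_matrix_exact_removals(self):
        """6x8: one individual half-missing and one singleton SNP go; the
        oracle is an exhaustive per-row / per-column tally."""
        g = np.tile([1, 1, 1, 1, 2, 2], (8, 1)).T.astype(np.int8)
        g[0, :4] = MISSING                       # individual 0: rate 0.5
        g[:, 5] = [0, 0, 0, 0, 0, 1]             # SNP 5: singleton (MAC 1)
        ds = make_dataset(g, ["p"] * 6)
        out, _ = filter_missingness(ds)
        # oracle tallies
        keep_ind = [(row != MISSING).mean() > 0.8 for row in g]
        assert keep_ind == [False, True, True, True, True, True]
        assert out.n_individuals == 5
        assert out.n_snps == 7
        assert 5 not in out.snps["pos"].to_numpy() - 1

    def test_mac_recomputed_after_individual_pass(self):
        """A SNP at MAC 3 that drops to MAC 2 when a low-rate individual is
        removed must be dropped (individual pass precedes SNP pass)."""
        g = np.array([
            [1, 1, MISSING],     # low-rate individual, carries a minor allele
            [1, 2, 1],
            [1, 2, 1],
            [0, 2, 1],
        ], dtype=np.int8)
        ds = make_dataset(g, ["p"] * 4)
        out, _ = filter_missingness(ds, ind_rate=0.7, snp_rate=0.5, mac=3)
        assert out.n_individuals == 3
        assert 1 not in out.snps["pos"].to_numpy()   # SNP 0 (pos 1) removed

    def test_idempotent(self, filtered_sim):
        _, _, res = filtered_sim
        again, report = filter_missingness(res.single_snp)
        assert report["individuals_dropped"] == 0
        assert again.n_snps == res.single_snp.n_snps

    def test_all_individuals_removed_raises(self):
        g = np.full((3, 4), MISSING, dtype=np.int8)
        g[:, 0] = 1
        ds = make_dataset(g, ["p"] * 3)
        with pytest.raises(ValueError, match="all individuals"):
            filter_missingness(ds)


class TestHDplot:
    def _counts(self, ref, alt):
        return ReadCountTable(ref=np.asarray(ref), alt=np.asarray(alt))

    def test_balanced_heterozygotes(self):
        g = np.array([[1], [1], [1], [1], [0], [0], [0], [0]], dtype=np.int8)
        ds = make_dataset(g, ["p"] * 8)
        counts = self._counts(np.full((8, 1), 10), np.full((8, 1), 10))
        stat = hdplot(counts, ds)
        row = stat.per_snp.iloc[0]
        assert row["H"] == pytest.approx(4 / 8)
        assert row["D"] == pytest.approx(0.0)
        assert not row["flagged"]

    def test_skewed_reads_flagged(self):
        """Five heterozygotes at (18, 2) reads: D = (90-10)/sqrt(100) = 8."""
        g = np.array([[1]] * 5 + [[0]] * 5, dtype=np.int8)
        ds = make_dataset(g, ["p"] * 10)
        ref = np.where(g == 1, 18, 20)
        alt = np.where(g == 1, 2, 0)
        stat = hdplot(self._counts(ref, alt), ds)
        row = stat.per_snp.iloc[0]
        assert row["D"] == pytest.approx(8.0)
        assert row["flagged"]
        assert stat.flagged_tags.tolist() == [0]

    def test_all_heterozygous_flagged_by_h(self):
        g = np.ones((6, 1), dtype=np.int8)
        ds = make_dataset(g, ["p"] * 6)
        stat = hdplot(self._counts(np.full((6, 1), 10), np.full((6, 1), 10)), ds)
        assert stat.per_snp.iloc[0]["H"] == 1.0
        assert stat.per_snp.iloc[0]["flagged"]

    def test_no_heterozygotes_passes_d(self):
        g = np.array([[0], [0], [2], [2]], dtype=np.int8)
        ds = make_dataset(g, ["p"] * 4)
        stat = hdplot(self._counts(np.full((4, 1), 9), np.zeros((4, 1))), ds)
        assert not stat.per_snp.iloc[0]["flagged"]

    def test_simulated_separation(self):
        """>= 80% of collapsed tags flagged, < 2% of clean tags flagged
        (depth 40, 1,000 tags)."""
        cfg = ss.default_scenario(seed=21, n_tags=1000, paralog_fraction=0.1)
        ds, truth = ss.simulate_metapopulation(cfg)
        counts = ss.simulate_read_counts(ds, truth)
        stat = hdplot(counts, ds)
        true_par = np.flatnonzero(truth.paralog_flags)
        hit_rate = np.isin(true_par, stat.flagged_tags).mean()
        false_rate = (~np.isin(stat.flagged_tags, true_par)).sum() / (1000 - len(true_par))
        assert hit_rate >= 0.80
        assert false_rate < 0.02


class TestOneSnpPerTag:
    def test_highest_maf_wins_first_on_tie(self):
        # tag 0 MAFs: 0.10, 0.30, 0.30 -> within-tag index 1 retained
        g = np.array([
            [1, 1, 0],
            [0, 1, 1],
            [0, 1, 2],
            [0, 0, 0],
            [0, 0, 0],
        ], dtype=np.int8)
        ds = make_dataset(g, ["p"] * 5, tag=[0, 0, 0])
        maf = ds.minor_allele_freq()
        assert maf.tolist() == [0.1, 0.3, 0.3]
        out = select_one_snp_per_tag(ds)
        assert out.n_snps == 1
        assert out.snps["tag_index"].tolist() == [1]

    def test_single_snp_tag_kept(self):
        g = np.array([[1], [0], [1]], dtype=np.int8)
        out = select_one_snp_per_tag(make_dataset(g, ["p"] * 3))
        assert out.n_snps == 1

    def test_tag_count_preserved_and_maf_dominates(self, default_sim):
        _, ds, _, _ = default_sim
        out = select_one_snp_per_tag(ds)
        assert out.n_snps == ds.snps["tag"].nunique()
        # the kept SNP's MAF is the maximum over its tag mates
        maf_full = ds.minor_allele_freq()
        best_by_tag = (ds.snps.assign(maf=maf_full)
                       .groupby("tag")["maf"].max())
        kept = out.snps.assign(maf=out.minor_allele_freq())
        for row in kept.itertuples():
            assert row.maf == pytest.approx(best_by_tag[row.tag])


class TestFisFilter:
    def test_total_heterozygote_deficit_removed(self):
        g = np.array([[0], [0], [2], [2], [0], [2]], dtype=np.int8)
        ds = make_dataset(g, ["p"] * 6)
        assert snp_fis(ds)[0] == pytest.approx(1.0)
        assert filter_fis(ds).n_snps == 0

    def test_hwe_locus_retained(self):
        g = np.array([[0], [1], [1], [2]] * 3, dtype=np.int8)
        ds = make_dataset(g, ["p"] * 12)
        assert abs(snp_fis(ds)[0]) < 0.1
        assert filter_fis(ds).n_snps == 1

    def test_microhap_allele_count_cap(self):
        """A tag with 11 observed haplotypes is removed regardless of F_IS."""
        k = 10
        hap = np.zeros((11, k, 2), dtype=np.int8)
        for i in range(10):
            hap[i + 1, i, 0] = 1      # each individual adds one new haplotype
        g = hap.sum(axis=2)
        ds = make_dataset(g, ["p"] * 11, tag=[0] * k, haplotypes=hap)
        mh = build_microhaplotypes(ds)
        assert mh.tags[0].n_alleles == 11
        assert filter_microhap(mh).n_tags == 0


class TestMicrohaplotypes:
    def test_single_snp_tag_is_degenerate(self):
        hap = np.zeros((3, 1, 2), dtype=np.int8)
        hap[0, 0] = [0, 1]
        hap[1, 0] = [1, 1]
        ds = make_dataset(hap.sum(axis=2), ["p"] * 3, haplotypes=hap)
        mh = build_microhaplotypes(ds)
        tag = mh.tags[0]
        assert tag.alleles == ["0", "1"]
        assert tag.genos[0].tolist() == [0, 1]
        assert tag.genos[2].tolist() == [0, 0]

    def test_phase_distinguishes_cis_trans(self):
        """0|1 + 1|0 at two SNPs gives haplotypes '01' and '10' - two
        distinct microhap alleles despite identical doses."""
        hap = np.zeros((2, 2, 2), dtype=np.int8)
        hap[0, 0] = [0, 1]; hap[0, 1] = [1, 0]     # ind0: 01 / 10
        hap[1, 0] = [0, 0]; hap[1, 1] = [0, 0]     # ind1: 00 / 00
        ds = make_dataset(hap.sum(axis=2), ["p"] * 2, tag=[0, 0], haplotypes=hap)
        mh = build_microhaplotypes(ds)
        tag = mh.tags[0]
        a0, a1 = tag.genos[0]
        assert {tag.alleles[a0], tag.alleles[a1]} == {"01", "10"}

    def test_allele_codes_dense_in_observation_order(self):
        hap = np.zeros((3, 2, 2), dtype=np.int8)
        # shared haplotypes AA ('00') and AT ('01')
        hap[0, :, 0] = [0, 0]; hap[0, :, 1] = [0, 1]
        hap[1, :, 0] = [0, 1]; hap[1, :, 1] = [0, 0]
        hap[2, :, 0] = [0, 0]; hap[2, :, 1] = [0, 1]
        ds = make_dataset(hap.sum(axis=2), ["p"] * 3, tag=[0, 0], haplotypes=hap)
        tag = build_microhaplotypes(ds).tags[0]
        assert tag.n_alleles == 2
        assert sorted(np.unique(tag.genos)) == [0, 1]

    def test_missing_genotype_voids_haplotype(self):
        hap = np.zeros((3, 2, 2), dtype=np.int8)
        hap[0, 0] = [MISSING, MISSING]
        g = hap.sum(axis=2)
        g[0, 0] = MISSING
        ds = make_dataset(g, ["p"] * 3, tag=[0, 0], haplotypes=hap)
        tag = build_microhaplotypes(ds).tags[0]
        assert (tag.genos[0] == MISSING).all()

    def test_unphased_dataset_rejected(self):
        ds = make_dataset(np.zeros((3, 2), dtype=np.int8), ["p"] * 3)
        with pytest.raises(ValueError, match="phase"):
            build_microhaplotypes(ds)

    def test_allele_count_bounds(self, filtered_sim):
        _, _, res = filtered_sim
        n = res.microhaps.n_individuals
        for tag in res.microhaps.tags:
            assert 1 <= tag.n_alleles <= 2 * n
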