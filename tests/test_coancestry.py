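"""Co-ancestry painting, group contrasts, clustering, and the ancestry EM."""

import numpy as np
import pandas as pd
import pytest

import stockscan as ss
from stockscan.datasets import (MISSING, GenotypeDataset, MicrohapDataset,
                                MicrohapTag)
from stockscan.coancestry import (cluster_coancestry, coancestry_group_stats,
                                  cut_clusters, paint_coancestry,
                                  supervised_ancestry_em, tukey_hsd)

from conftest import make_dataset


def make_mh(tag_specs, n, pops=None, drainages=None):
    """Build a MicrohapDataset from [(alleles, genos), ...]."""
    tags = []
    for t, (alleles, genos) in enumerate(tag_specs):
        tags.append(MicrohapTag(tag=t, chrom="chr1", pos=100 * (t + 1),
                                alleles=list(alleles),
                                genos=np.asarray(genos, dtype=np.int16)))
    pops = pops or ["p"] * n
    individuals = pd.DataFrame({
        "id": [f"i{k}" for k in range(n)],
        "population": pops,
        "drainage": drainages or pops,
        "group": pops,
    })
    return MicrohapDataset(tags=tags, individuals=individuals)


class TestPainting:
    def test_three_individual_hand_enumeration(self):
        """i=(00,00), j=(00,01), k=(11,11): both of i's alleles find their
        nearest haplotype in j (distance 0), so M[i,j] = 2, M[i,k] = 0."""
        mh = make_mh([(["00", "01", "11"],
                       [[0, 0], [0, 1], [2, 2]])], n=3)
        cm = paint_coancestry(mh)
        i, j, k = 0, 1, 2
        assert cm.matrix[i, j] == pytest.approx(2.0)
        assert cm.matrix[i, k] == pytest.approx(0.0)
        # j's '00' allele ties i (x2 alleles) -> goes to i; j's '01' is
        # nearer i's '00' (d=1) than k's '11' (d=1)? both d=1: split
        assert cm.matrix.sum(axis=1) == pytest.approx(2 * cm.loci_used)

    def test_private_shared_haplotype_attracts_full_unit(self):
        # i and j share a private allele; k and l are far away
        mh = make_mh([(["000", "111", "001"],
                       [[0, 0], [0, 2], [1, 1], [1, 1]])], n=4)
        cm = paint_coancestry(mh)
        assert cm.matrix[0, 1] == pytest.approx(2.0)   # both alleles exact in j
        assert cm.matrix[0, 2] == 0.0

    def test_identical_individuals_spread_evenly(self):
        n, L = 5, 3
        specs = [(["01"], [[0, 0]] * n) for _ in range(L)]
        cm = paint_coancestry(make_mh(specs, n))
        off = cm.matrix[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, 2 * L / (n - 1))

    def test_conservation_and_tag_order_invariance(self, filtered_sim):
        _, _, res = filtered_sim
        mh = res.microhaps
        sub = mh.take_tags(np.arange(0, mh.n_tags, 7))
        cm = paint_coancestry(sub)
        np.testing.assert_allclose(cm.matrix.sum(axis=1), 2.0 * cm.loci_used,
                                   atol=1e-6)
        rng = np.random.default_rng(0)
        shuffled = sub.take_tags(rng.permutation(sub.n_tags))
        cm2 = paint_coancestry(shuffled)
        np.testing.assert_allclose(cm.matrix, cm2.matrix, atol=1e-9)

    def test_missing_individuals_skip_tags(self):
        genos = [[0, 0], [0, 1], [MISSING, MISSING], [1, 1]]
        mh = make_mh([(["00", "01"], genos), (["00", "01"], genos)], n=4)
        cm = paint_coancestry(mh)
        assert cm.loci_used.tolist() == [2, 2, 0, 2]
        assert cm.matrix[2].sum() == 0.0
        assert cm.matrix[:, 2].sum() == 0.0


class TestGroupStats:
    def test_identical_individuals_equal_intra_means(self):
        n = 6
        specs = [(["01"], [[0, 0]] * n) for _ in range(4)]
        mh = make_mh(specs, n, pops=["a"] * 3 + ["b"] * 3)
        stats = coancestry_group_stats(paint_coancestry(mh))
        assert stats.per_population["a"] == pytest.approx(stats.per_population["b"])

    def test_per_population_column_emitted(self, filtered_sim):
        _, _, res = filtered_sim
        cm = paint_coancestry(res.microhaps.take_tags(np.arange(150)))
        stats = coancestry_group_stats(cm)
        assert set(stats.per_population.index) == set(res.microhaps.populations())

    def test_two_lineage_intra_exceeds_inter(self, filtered_sim):
        _, truth, res = filtered_sim
        cm = paint_coancestry(res.microhaps.take_tags(np.arange(300)))
        M = cm.matrix
        lin = cm.individuals["group"].to_numpy()
        same = lin[:, None] == lin[None, :]
        off = ~np.eye(len(lin), dtype=bool)
        assert M[same & off].mean() > M[~same].mean()

    def test_singleton_population_reports_nan(self):
        n = 4
        specs = [(["01"], [[0, 0]] * n)]
        mh = make_mh(specs, n, pops=["a", "a", "a", "b"])
        stats = coancestry_group_stats(paint_coancestry(mh))
        assert np.isnan(stats.per_population["b"])


class TestTukeyHsd:
    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        false_flags = 0
        reps = 200
        for _ in range(reps):
            groups = {k: rng.normal(0, 1, 12) for k in "abc"}
            out = tukey_hsd(groups, alpha=0.001)
            false_flags += out["significant"].any()
        assert false_flags / reps <= 0.01

    def test_matches_reference_implementation(self):
        """q statistics and p-values against statsmodels to 1e-6."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(0, 1, 14), "b": rng.normal(0.9, 1, 9),
                  "c": rng.normal(-0.4, 1.2, 11)}
        ours = tukey_hsd(groups).set_index(["group_a", "group_b"])
        vals = np.concatenate(list(groups.values()))
        labs = np.concatenate([[k] * len(v) for k, v in groups.items()])
        ref = pairwise_tukeyhsd(vals, labs)
        names = [(str(a), str(b)) for a, b in
                 zip(np.asarray(ref.groupsunique)[np.array(ref._multicomp.pairindices[0])],
                     np.asarray(ref.groupsunique)[np.array(ref._multicomp.pairindices[1])])]
        for (g1, g2), p_ref, diff_ref in zip(names, ref.pvalues, ref.meandiffs):
            mine = ours.loc[(g1, g2)] if (g1, g2) in ours.index else ours.loc[(g2, g1)]
            assert abs(mine["p"] - p_ref) < 1e-6
            assert abs(abs(mine["mean_diff"]) - abs(diff_ref)) < 1e-9

    def test_two_groups_match_pooled_t(self):
        """With two groups, q = |t| * sqrt(2) and the HSD p equals the
        two-sided pooled t-test p."""
        from scipy import stats
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(0.7, 1, 13)
        out = tukey_hsd({"a": a, "b": b}).iloc[0]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert out["q"] == pytest.approx(abs(t) * np.sqrt(2), abs=1e-9)
        assert out["p"] == pytest.approx(p, abs=1e-9)

    def test_zero_variance_exact_comparison(self):
        out = tukey_hsd({"a": np.ones(4), "b": np.full(4, 2.0)})
        assert out.iloc[0]["p"] == 0.0
        same = tukey_hsd({"a": np.ones(4), "b": np.ones(4)})
        assert same.iloc[0]["p"] == 1.0


class TestClustering:
    def test_two_lineage_recovery(self, filtered_sim):
        _, truth, res = filtered_sim
        cm = paint_coancestry(res.microhaps.take_tags(np.arange(300)))
        Z, newick = cluster_coancestry(cm)
        labels = cut_clusters(Z, 2)
        lineage = (cm.individuals["group"] == "wisconsin").to_numpy()
        split1 = labels[lineage]
        split2 = labels[~lineage]
        majority = (np.mean(split1 == np.bincount(split1).argmax())
                    + np.mean(split2 == np.bincount(split2).argmax())) / 2
        assert majority >= 0.95
        assert newick.endswith(";")

    def test_identical_individuals_equal_heights(self):
        n = 5
        specs = [(["01"], [[0, 0]] * n) for _ in range(3)]
        cm = paint_coancestry(make_mh(specs, n))
        Z, _ = cluster_coancestry(cm)
        assert np.allclose(Z[:, 2], Z[0, 2])


class TestAncestryEm:
    def test_pure_individual_assigned_to_its_panel(self):
        rng = np.random.default_rng(0)
        L = 500
        fa = np.full(L, 0.02)
        fb = np.full(L, 0.98)              # near-fixed A/B differences
        g = (rng.random((6, L)) < fa).astype(np.int8) + (rng.random((6, L)) < fa).astype(np.int8)
        ds = make_dataset(g, ["x"] * 6)
        res = supervised_ancestry_em(ds, {"A": fa, "B": fb})
        assert (res.q["A"] >= 0.99).all()

    def test_f1_hybrid_half_and_half(self):
        rng = np.random.default_rng(1)
        L = 1000
        fa = np.where(rng.random(L) < 0.5, 0.05, 0.95)
        fb = 1.0 - fa                       # informative, opposite panels
        g = (rng.random((8, L)) < fa).astype(np.int8) + (rng.random((8, L)) < fb).astype(np.int8)
        ds = make_dataset(g, ["f1"] * 8)
        res = supervised_ancestry_em(ds, {"A": fa, "B": fb})
        assert res.q["A"].mean() == pytest.approx(0.5, abs=0.05)

    def test_loglik_nondecreasing(self, default_sim):
        _, ds, truth, _ = default_sim
        sub = ds.take(ind_idx=np.arange(0, ds.n_individuals, 12))
        panels = {p: truth.pop_freqs[p] for p in ["wisconsin_pop1", "minnesota_pop1"]}
        res = supervised_ancestry_em(sub, panels, max_iter=60)
        assert (np.diff(res.log_likelihood) >= -1e-6).all()

    def test_mismatched_panel_length_rejected(self):
        ds = make_dataset(np.zeros((3, 5), dtype=np.int8), ["p"] * 3)
        with pytest.raises(ValueError, match="cover"):
            supervised_ancestry_em(ds, {"A": np.full(4, 0.5), "B": np.full(4, 0.5)})
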