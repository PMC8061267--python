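"""F_ST, D_A/NJ, and AMOVA against brute-force transcription oracles."""

import numpy as np
import pandas as pd
import pytest

import stockscan as ss
from stockscan.structure import (_bipartitions, _nj_tree, amova, da_matrix,
                                 nei_da, theta_from_nested_anova,
                                 variance_percentages, wc_theta)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent literal transcription of the W&C (1984) component formulas
# ---------------------------------------------------------------------------

def wc_oracle(doses, labels):
    """Brute-force multilocus theta: per-locus loop, scalar arithmetic."""
    pops = sorted(set(labels))
    labels = np.asarray(labels)
    num = den = 0.0
    for l in range(doses.shape[1]):
        g = doses[:, l]
        ni, pi, hi = [], [], []
        for pop in pops:
            gp = g[(labels == pop) & (g >= 0)]
            if len(gp) == 0:
                continue
            ni.append(len(gp))
            pi.append(gp.sum() / (2 * len(gp)))
            hi.append(np.mean(gp == 1))
        r = len(ni)
        if r < 2:
            continue
        ni, pi, hi = map(np.asarray, (ni, pi, hi))
        nbar = ni.mean()
        if nbar <= 1:
            continue
        nc = (ni.sum() - (ni ** 2).sum() / ni.sum()) / (r - 1)
        pbar = (ni * pi).sum() / ni.sum()
        s2 = (ni * (pi - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ni * hi).sum() / ni.sum()
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                         / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den


class TestWcTheta:
    def test_fixed_difference_gives_one(self):
        g = np.array([[0, 0]] * 6 + [[2, 2]] * 6, dtype=np.int8)
        ds = make_dataset(g, ["a"] * 6 + ["b"] * 6)
        assert wc_theta(ds).theta == pytest.approx(1.0)

    def test_identical_tables_nonpositive(self):
        block = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], dtype=np.int8)
        ds = make_dataset(np.vstack([block, block]), ["a"] * 4 + ["b"] * 4)
        assert wc_theta(ds).theta <= 0

    def test_toy_case_matches_literal_transcription(self):
        """pop1: 5 AA + 5 Aa; pop2: 2 Aa + 8 aa (single SNP)."""
        g = np.array([[0]] * 5 + [[1]] * 5 + [[1]] * 2 + [[2]] * 8, dtype=np.int8)
        labels = ["p1"] * 10 + ["p2"] * 10
        ds = make_dataset(g, labels)
        assert wc_theta(ds).theta == pytest.approx(wc_oracle(g, labels), abs=1e-12)

    def test_random_data_matches_oracle(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(40, 25)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = -1
        labels = (["a"] * 11 + ["b"] * 17 + ["c"] * 12)
        ds = make_dataset(g, labels)
        assert wc_theta(ds).theta == pytest.approx(wc_oracle(g, labels), abs=1e-10)

    def test_agrees_with_nested_anova_route(self):
        """Internal consistency: the sums-of-squares nested-ANOVA path
        reproduces the W&C closed-form theta to 1e-9."""
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
        labels = ["a"] * 9 + ["b"] * 13 + ["c"] * 8
        ds = make_dataset(g, labels)
        assert theta_from_nested_anova(ds) == pytest.approx(
            wc_theta(ds).theta, abs=1e-9)


class TestPermutationTest:
    def test_fixed_difference_minimal_p(self):
        g = np.array([[0, 0, 0]] * 10 + [[2, 2, 2]] * 10, dtype=np.int8)
        ds = make_dataset(g, ["a"] * 10 + ["b"] * 10)
        res = ss.fst_permutation_test(ds, "a", "b", n_perm=199, seed=0)
        # the exact complement split also attains theta = 1, so a draw can
        # add one tie to the minimal achievable p
        assert res.p_value <= 2 / 200

    def test_null_is_calibrated(self):
        """Identical populations: p > 0.05 in >= 90% of seeded replicates."""
        rng = np.random.default_rng(17)
        hits = 0
        reps = 30
        for rep in range(reps):
            g = rng.binomial(2, 0.3, size=(20, 30)).astype(np.int8)
            ds = make_dataset(g, ["a"] * 10 + ["b"] * 10)
            res = ss.fst_permutation_test(ds, "a", "b", n_perm=199, seed=rep)
            hits += res.p_value > 0.05
        assert hits / reps >= 0.90

    def test_power_at_moderate_divergence(self):
        """F_between = 0.05, n = 30/pop, 1,000 SNPs: p < 0.0001."""
        cfg = ss.ScenarioConfig(n_tags=1000, snps_per_tag=(1, 1),
                                sample_sizes=30, F_between=0.05,
                                F_within=0.02, seed=23)
        ds, _ = ss.simulate_metapopulation(cfg)
        res = ss.fst_permutation_test(ds, "wisconsin_pop1", "minnesota_pop1",
                                      n_perm=10_000, seed=1)
        assert res.p_value < 0.0001


class TestNeiDa:
    def test_identical_frequencies_zero(self):
        f = [np.array([0.3, 0.7]), np.array([0.5, 0.5])]
        assert nei_da(f, f) == pytest.approx(0.0)

    def test_hand_evaluated_single_locus(self):
        d = nei_da([np.array([1.0, 0.0])], [np.array([0.5, 0.5])])
        assert d == pytest.approx(1 - np.sqrt(0.5), abs=1e-9)

    def test_opposite_fixation_is_one(self):
        a = [np.array([1.0, 0.0])] * 4
        b = [np.array([0.0, 1.0])] * 4
        assert nei_da(a, b) == pytest.approx(1.0)

    def test_matrix_symmetric_zero_diagonal(self, filtered_sim):
        _, _, res = filtered_sim
        D = da_matrix(res.single_snp)
        M = D.to_numpy()
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 0)
        assert (M >= -1e-12).all()


class TestNjBootstrap:
    def test_recovers_additive_topology(self):
        """Four taxa with additive distances: NJ finds the unique unrooted
        topology AB|CD (exhaustive three-topology oracle)."""
        D = np.array([[0, 2, 5, 6], [2, 0, 5, 6], [5, 5, 0, 3], [6, 6, 3, 0]],
                     dtype=float)
        ids = ["A", "B", "C", "D"]
        tree = _nj_tree(D, ids)
        parts = _bipartitions(tree, frozenset(ids))
        # oracle: score each of the 3 topologies by four-point condition
        ab_cd = D[0, 1] + D[2, 3]
        ac_bd = D[0, 2] + D[1, 3]
        ad_bc = D[0, 3] + D[1, 2]
        assert ab_cd == min(ab_cd, ac_bd, ad_bc)
        assert parts == {frozenset({"A", "B"})}

    def test_duplicated_population_full_support(self):
        rng = np.random.default_rng(3)
        freqs = rng.uniform(0.1, 0.9, size=(4, 120))
        g = np.concatenate([
            rng.binomial(2, freqs[i], size=(6, 120)).astype(np.int8)
            for i in [0, 0, 1, 2, 3]      # population 'a2' duplicates 'a1'
        ])
        pops = sum([[p] * 6 for p in ["a1", "a2", "b", "c", "d"]], [])
        ds = make_dataset(g, pops)
        # make the twins literally identical tables -> D_A(a1, a2) = 0
        ds.genotypes[6:12] = ds.genotypes[:6]
        res = ss.nj_bootstrap(ds, n_boot=100, seed=0)
        assert res.supports[frozenset({"a1", "a2"})] == pytest.approx(100.0)

    def test_lineage_clades_high_support(self, filtered_sim):
        _, _, res = filtered_sim
        tree = ss.nj_bootstrap(res.single_snp, n_boot=200, seed=1)
        pops = res.single_snp.populations()
        wi = frozenset(p for p in pops if p.startswith("wisconsin"))
        mn = frozenset(pops) - wi
        key = min(wi, mn, key=lambda s: tuple(sorted(s)))
        assert tree.supports.get(key, 0.0) >= 95.0

    def test_degenerate_matrix_star_tree(self):
        g = np.ones((4, 10), dtype=np.int8)    # identical individuals
        ds = make_dataset(g, ["a", "b", "c", "d"])
        res = ss.nj_bootstrap(ds, n_boot=10, seed=0)
        assert res.supports == {}
        assert res.newick.count("(") == 1


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def amova_oracle(doses, labels, grouping):
    """Brute-force nested gene-copy ANOVA via explicit deviation sums."""
    copies, pop, grp = [], [], []
    for i, lab in enumerate(labels):
        for allele in range(2):
            dose = doses[i].copy()
            copies.append([(1 if dose[l] > allele else 0) for l in range(doses.shape[1])])
            pop.append(lab)
            grp.append(grouping[lab])
    y = np.asarray(copies, float)
    pop = np.asarray(pop)
    grp = np.asarray(grp)

    def ss_dev(values):
        return ((values - values.mean(axis=0)) ** 2).sum()

    ss_total = ss_dev(y)
    ss_wg = sum(ss_dev(y[grp == g]) for g in set(grp))
    ss_wp = sum(ss_dev(y[pop == p]) for p in set(pop))
    ss_ag, ss_ap = ss_total - ss_wg, ss_wg - ss_wp
    P, G = len(set(pop)), len(set(grp))
    M = len(y)
    df_ag, df_ap, df_wp = G - 1, P - G, M - P
    m_p = {p: np.sum(pop == p) for p in set(pop)}
    m_g = {g: np.sum(grp == g) for g in set(grp)}
    s = sum(sum(m_p[p] ** 2 for p in set(pop[grp == g])) / m_g[g] for g in set(grp))
    n1 = (M - s) / df_ap
    n2 = (s - sum(v ** 2 for v in m_p.values()) / M) / df_ag
    n3 = (M - sum(v ** 2 for v in m_g.values()) / M) / df_ag
    sc = ss_wp / df_wp
    sb = (ss_ap / df_ap - sc) / n1
    sa = (ss_ag / df_ag - sc - n2 * sb) / n3
    return sa, sb, sc


class TestAmova:
    def test_percent_reconstruction_from_published_components(self):
        pct = variance_percentages((54.08, 67.26, 1605.17))
        assert np.round(pct, 2).tolist() == [3.13, 3.90, 92.97]

    def test_identical_populations_put_variation_within(self):
        block = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], dtype=np.int8)
        g = np.vstack([block] * 4)
        pops = sum([[f"p{i}"] * 4 for i in range(4)], [])
        ds = make_dataset(g, pops)
        res = amova(ds, {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"})
        assert res.table["percent"].iloc[2] > 99.0

    def test_toy_matches_brute_force(self):
        """2 groups x 2 pops x 10 individuals against the deviation-sum
        oracle (different code path: explicit copies, no count identity)."""
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(40, 12)).astype(np.int8)
        pops = sum([[f"p{i}"] * 10 for i in range(4)], [])
        grouping = {"p0": "A", "p1": "A", "p2": "B", "p3": "B"}
        ds = make_dataset(g, pops)
        res = amova(ds, grouping)
        oracle = amova_oracle(g, pops, grouping)
        np.testing.assert_allclose(res.components, oracle, atol=1e-9)
        assert res.table["percent"].sum() == pytest.approx(100.0, abs=0.01)
        assert res.table["df"].sum() == 2 * 40 - 1

    def test_unbalanced_sizes_match_brute_force(self):
        rng = np.random.default_rng(4)
        sizes = [5, 9, 7, 12, 6]
        pops = sum([[f"p{i}"] * s for i, s in enumerate(sizes)], [])
        g = rng.integers(0, 3, size=(len(pops), 8)).astype(np.int8)
        grouping = {"p0": "A", "p1": "A", "p2": "B", "p3": "B", "p4": "B"}
        ds = make_dataset(g, pops)
        res = amova(ds, grouping)
        oracle = amova_oracle(g, pops, grouping)
        np.testing.assert_allclose(res.components, oracle, atol=1e-9)

    def test_singleton_group_allowed_and_flagged(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(12, 6)).astype(np.int8)
        pops = ["p0"] * 4 + ["p1"] * 4 + ["p2"] * 4
        ds = make_dataset(g, pops)
        res = amova(ds, {"p0": "A", "p1": "A", "p2": "B"})
        assert res.singleton_groups == ["B"]

    def test_simulated_hierarchy_orders_thetas(self, filtered_sim):
        """Within-lineage pairwise theta < between-lineage pairwise theta."""
        _, _, res = filtered_sim
        ds = res.single_snp
        within = wc_theta(ds, ["wisconsin_pop1", "wisconsin_pop2"]).theta
        between = wc_theta(ds, ["wisconsin_pop1", "minnesota_pop1"]).theta
        assert within < between


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st_


@settings(derandomize=True, max_examples=40)
@given(st_.lists(st_.floats(min_value=1e-6, max_value=1e6), min_size=2,
                 max_size=6))
def test_variance_percentages_sum_to_100(components):
    pct = variance_percentages(components)
    assert np.isclose(pct.sum(), 100.0)
    assert (pct >= 0).all()


@settings(derandomize=True, max_examples=40)
@given(st_.lists(st_.floats(min_value=0.0, max_value=1.0), min_size=2,
                 max_size=30), st_.lists(st_.floats(min_value=0.0, max_value=1.0),
                                         min_size=2, max_size=30))
def test_nei_da_symmetric_and_bounded(pa, pb):
    L = min(len(pa), len(pb))
    fa = [np.array([p, 1 - p]) for p in pa[:L]]
    fb = [np.array([p, 1 - p]) for p in pb[:L]]
    d_ab = nei_da(fa, fb)
    d_ba = nei_da(fb, fa)
    assert d_ab == pytest.approx(d_ba, abs=1e-12)
    assert -1e-12 <= d_ab <= 1.0 + 1e-12
    assert nei_da(fa, fa) == pytest.approx(0.0, abs=1e-12)
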