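"""Population differentiation: Weir-Cockerham theta, permutation tests,
Nei's D_A with bootstrapped neighbor-joining, and hierarchical AMOVA.

Estimators
----------
``wc_theta``
    Weir & Cockerham's (1984) variance-component estimator of F_ST for
    unequal sample sizes.  Per locus the allelic variance splits into
    ``a`` (among populations), ``b`` (among individuals within
    populations) and ``c`` (within individuals); the multilocus estimate
    is the ratio of sums, theta = sum(a) / sum(a + b + c).

``amova``
    Three-level analysis of molecular variance on gene copies (allele
    mismatch distance, loci summed): among groups / among populations
    within groups / within populations, with variance components from
    mean squares and unequal-size coefficients.  Negative components are
    reported as-is.

``nei_da``
    D_A = 1 - (1/L) sum_loci sum_alleles sqrt(x_a * y_a); the
    neighbor-joining dendrogram bootstraps loci (tags, for
    microhaplotype data) and reports bipartition support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .datasets import MISSING, GenotypeDataset, MicrohapDataset


# ---------------------------------------------------------------------------
# Weir-Cockerham components
# ---------------------------------------------------------------------------

def _pop_summaries(genotypes: np.ndarray, pop_labels: np.ndarray,
                   pops: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per population x locus: sample size, alt-allele frequency, het share."""
    r, L = len(pops), genotypes.shape[1]
    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    for k, pop in enumerate(pops):
        g = genotypes[pop_labels == pop]
        called = g != MISSING
        nk = called.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, np.where(called, g, 0).sum(axis=0) / (2 * np.maximum(nk, 1)), 0.0)
            h[k] = np.where(nk > 0, (g == 1).sum(axis=0) / np.maximum(nk, 1), 0.0)
    return n, p, h


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus W&C (1984) a, b, c from per-pop summaries.

    Populations with no data at a locus drop out of that locus; loci
    with fewer than two populated samples, or with ``nbar == 1``, are
    marked invalid.  Returns (a, b, c, valid).
    """
    present = n > 0
    r_l = present.sum(axis=0).astype(float)
    nsum = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nsum / np.maximum(r_l, 1)
        nc = (nsum - (n ** 2).sum(axis=0) / np.maximum(nsum, 1)) / np.maximum(r_l - 1, 1)
        pbar = (n * p).sum(axis=0) / np.maximum(nsum, 1)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / (np.maximum(r_l - 1, 1) * np.maximum(nbar, 1e-12))
        hbar = (n * h).sum(axis=0) / np.maximum(nsum, 1)
        inner = pbar * (1 - pbar) - (r_l - 1) / np.maximum(r_l, 1) * s2
        a = nbar / np.maximum(nc, 1e-12) * (s2 - (inner - hbar / 4) / np.maximum(nbar - 1, 1e-12))
        b = nbar / np.maximum(nbar - 1, 1e-12) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    valid = (r_l >= 2) & (nbar > 1) & (nc > 0)
    return a, b, c, valid


@dataclass
class FstResult:
    """Multilocus theta with per-locus variance components."""

    theta: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    n_loci: int
    p_value: float | None = None
    n_permutations: int = 0


def wc_theta(ds: GenotypeDataset, populations: list[str] | None = None) -> FstResult:
    """Multilocus Weir-Cockerham theta over ``populations`` (default: all).

    Loci with zero total variance are skipped from the ratio of sums.
    """
    pops = populations if populations is not None else ds.populations()
    if len(pops) < 2:
        raise ValueError("theta needs at least two populations")
    labels = ds.individuals["population"].to_numpy()
    for pop in pops:
        if not (labels == pop).any():
            raise ValueError(f"population {pop!r} has no individuals")
    mask = np.isin(labels, pops)
    n, p, h = _pop_summaries(ds.genotypes[mask], labels[mask], pops)
    a, b, c, valid = wc_components(n, p, h)
    total = a + b + c
    use = valid & (total != 0) & np.isfinite(total)
    if not use.any():
        raise ValueError("no locus with defined variance components")
    theta = float(a[use].sum() / total[use].sum())
    return FstResult(theta=theta, a=a[use], b=b[use], c=c[use], n_loci=int(use.sum()))


def per_locus_theta(ds: GenotypeDataset, populations: list[str] | None = None
                    ) -> tuple[pd.DataFrame, int]:
    """Per-SNP multi-population theta; loci with undefined components are
    dropped and counted.  Returns (records, n_dropped)."""
    pops = populations if populations is not None else ds.populations()
    labels = ds.individuals["population"].to_numpy()
    mask = np.isin(labels, pops)
    n, p, h = _pop_summaries(ds.genotypes[mask], labels[mask], pops)
    a, b, c, valid = wc_components(n, p, h)
    total = a + b + c
    use = valid & (total != 0) & np.isfinite(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / total
    rec = pd.DataFrame({
        "chrom": ds.snps["chrom"].to_numpy()[use],
        "pos": ds.snps["pos"].to_numpy()[use],
        "tag": ds.snps["tag"].to_numpy()[use],
        "theta": theta[use],
    })
    return rec, int((~use).sum())


def fst_permutation_test(ds: GenotypeDataset, pop_a: str, pop_b: str,
                         n_perm: int = 10_000, seed: int = 0) -> FstResult:
    """Permutation test of pairwise theta.

    Individuals are permuted between the two labels preserving sample
    sizes; p = (1 + #{theta_perm >= theta_obs}) / (1 + n_perm).
    """
    labels = ds.individuals["population"].to_numpy()
    mask = np.isin(labels, [pop_a, pop_b])
    g = ds.genotypes[mask]
    lab = labels[mask]
    if g.shape[0] < 4:
        raise ValueError("need at least four pooled individuals")
    n_a = int((lab == pop_a).sum())
    obs = _theta_of_split(g, np.arange(g.shape[0]) < 0, n_a, observed_labels=lab == pop_a)
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(g.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        is_a = np.zeros(g.shape[0], dtype=bool)
        is_a[perm[:n_a]] = True
        if _theta_of_split(g, None, n_a, observed_labels=is_a) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    res = wc_theta_pair_from_matrix(g, lab == pop_a)
    res.p_value = p
    res.n_permutations = n_perm
    return res


def _theta_of_split(g: np.ndarray, _unused, n_a: int, observed_labels: np.ndarray) -> float:
    return wc_theta_pair_from_matrix(g, observed_labels).theta


def wc_theta_pair_from_matrix(g: np.ndarray, is_a: np.ndarray) -> FstResult:
    """Pairwise multilocus theta from a genotype matrix and a boolean split."""
    lab = np.where(is_a, "A", "B")
    n, p, h = _pop_summaries(g, lab, ["A", "B"])
    a, b, c, valid = wc_components(n, p, h)
    total = a + b + c
    use = valid & (total != 0) & np.isfinite(total)
    if not use.any():
        return FstResult(theta=0.0, a=a[:0], b=b[:0], c=c[:0], n_loci=0)
    return FstResult(theta=float(a[use].sum() / total[use].sum()),
                     a=a[use], b=b[use], c=c[use], n_loci=int(use.sum()))


def pairwise_fst(ds: GenotypeDataset, n_perm: int = 0, seed: int = 0
                 ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise theta matrix over all populations; optional permutation
    p-values (``n_perm > 0``)."""
    pops = ds.populations()
    theta = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops) if n_perm else None
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            if n_perm:
                res = fst_permutation_test(ds, a, b, n_perm=n_perm,
                                           seed=seed + 7919 * i)
                pvals.loc[a, b] = pvals.loc[b, a] = res.p_value
            else:
                res = wc_theta(ds, [a, b])
            theta.loc[a, b] = theta.loc[b, a] = res.theta
    return theta, pvals


# ---------------------------------------------------------------------------
# Nei's D_A and neighbor-joining
# ---------------------------------------------------------------------------

def _affinity_tensor_snp(ds: GenotypeDataset, pops: list[str]) -> np.ndarray:
    """Per-locus Bhattacharyya affinity sum_alleles sqrt(x*y): (L, P, P)."""
    labels = ds.individuals["population"].to_numpy()
    freqs = np.stack([ds.allele_freq(labels == pop) for pop in pops])  # (P, L)
    p = np.nan_to_num(freqs, nan=0.0)
    q = np.where(np.isnan(freqs), 0.0, 1.0 - freqs)
    aff = (np.sqrt(p[:, None, :] * p[None, :, :])
           + np.sqrt(q[:, None, :] * q[None, :, :]))       # (P, P, L)
    return np.moveaxis(aff, 2, 0)


def _affinity_tensor_mh(mh: MicrohapDataset, pops: list[str]) -> np.ndarray:
    masks = [mh.pop_mask(pop) for pop in pops]
    L, P = mh.n_tags, len(pops)
    aff = np.zeros((L, P, P))
    for t, tag in enumerate(mh.tags):
        fr = np.stack([tag.allele_freqs(m) for m in masks])  # (P, k)
        aff[t] = np.sqrt(fr[:, None, :] * fr[None, :, :]).sum(axis=2)
    return aff


def affinity_tensor(data: GenotypeDataset | MicrohapDataset,
                    pops: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    pops = pops if pops is not None else data.populations()
    if isinstance(data, MicrohapDataset):
        return _affinity_tensor_mh(data, pops), pops
    return _affinity_tensor_snp(data, pops), pops


def nei_da(freqs_a: list[np.ndarray], freqs_b: list[np.ndarray]) -> float:
    """Nei's D_A between two populations given per-locus allele-frequency
    vectors over shared loci."""
    if len(freqs_a) != len(freqs_b) or not freqs_a:
        raise ValueError("need matching, non-empty per-locus frequency lists")
    aff = [float(np.sqrt(np.asarray(x) * np.asarray(y)).sum())
           for x, y in zip(freqs_a, freqs_b)]
    return 1.0 - float(np.mean(aff))


def da_matrix(data: GenotypeDataset | MicrohapDataset,
              pops: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Nei D_A matrix (populations x populations)."""
    aff, pops = affinity_tensor(data, pops)
    D = 1.0 - aff.mean(axis=0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=pops, columns=pops)


@dataclass
class TreeResult:
    """Unrooted NJ dendrogram with bootstrap supports on internal nodes."""

    newick: str
    tree: TreeNode
    supports: dict[frozenset, float]
    n_boot: int


def _bipartitions(tree: TreeNode, leaf_set: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, canonicalised as the
    lexicographically smaller side."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaf_set - side
        if len(side) < 2 or len(other) < 2:
            continue
        parts.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return parts


def _nj_tree(D: np.ndarray, ids: list[str]) -> TreeNode:
    dm = DistanceMatrix(np.ascontiguousarray((D + D.T) / 2.0), ids)
    return nj(dm)


def nj_bootstrap(data: GenotypeDataset | MicrohapDataset, n_boot: int = 10_000,
                 seed: int = 0, pops: list[str] | None = None) -> TreeResult:
    """Neighbor-joining on the D_A matrix with locus (tag) bootstrap.

    Node support is the percentage of replicate trees containing each
    bipartition of the point-estimate tree.  Resampling is over
    microhaplotype tags when given a :class:`MicrohapDataset`, otherwise
    over SNPs.
    """
    aff, pops = affinity_tensor(data, pops)
    if len(pops) < 4:
        raise ValueError("bootstrap bipartition support needs >= 4 populations")
    L = aff.shape[0]
    D0 = 1.0 - aff.mean(axis=0)
    np.fill_diagonal(D0, 0.0)
    leaf_set = frozenset(pops)
    if np.allclose(D0, 0.0):
        newick = "(" + ",".join(f"{p}:0.0" for p in pops) + ");"
        tree = TreeNode.read([newick])
        return TreeResult(newick=newick, tree=tree, supports={}, n_boot=n_boot)
    tree = _nj_tree(D0, pops)
    target = _bipartitions(tree, leaf_set)
    counts = {part: 0 for part in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        pick = rng.integers(0, L, size=L)
        Db = 1.0 - aff[pick].mean(axis=0)
        np.fill_diagonal(Db, 0.0)
        Db = np.maximum(Db, 0.0)
        parts = _bipartitions(_nj_tree(Db, pops), leaf_set)
        for part in target & parts:
            counts[part] += 1
    supports = {part: 100.0 * counts[part] / n_boot for part in target}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, leaf_set - side, key=lambda s: tuple(sorted(s)))
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    newick = str(tree).strip()
    return TreeResult(newick=newick, tree=tree, supports=supports, n_boot=n_boot)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Nested gene-copy ANOVA table: among groups / among populations
    within groups / within populations."""

    table: pd.DataFrame        # stratum, df, ssq, variance, percent
    components: tuple[float, float, float]
    singleton_groups: list[str]

    @property
    def percents(self) -> tuple[float, float, float]:
        return tuple(self.table["percent"])


def variance_percentages(components: tuple[float, ...] | list[float] | np.ndarray
                         ) -> np.ndarray:
    """Percent of total variation per stratum from variance components."""
    comp = np.asarray(components, dtype=float)
    return 100.0 * comp / comp.sum()


def _ss_within(counts: np.ndarray, copies: np.ndarray) -> np.ndarray:
    """Per-locus mismatch sum of squares within units given alt-allele
    counts and total copy counts per unit x locus."""
    ref = copies - counts
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = (copies - (counts ** 2 + ref ** 2) / np.maximum(copies, 1)) / 2.0
    return np.where(copies > 0, ss, 0.0)


def amova(ds: GenotypeDataset, grouping: dict[str, str]) -> AmovaResult:
    """Three-level AMOVA: groups / populations within groups / within
    populations, on allele-mismatch distances summed over loci.

    ``grouping`` maps every population to exactly one group.  Groups
    holding a single population are allowed (their among-population df
    contribution is zero) and reported in ``singleton_groups``.
    Negative variance components are retained, not truncated.
    """
    pops = ds.populations()
    for pop in pops:
        if pop not in grouping:
            raise ValueError(f"population {pop!r} missing from grouping")
    groups = list(dict.fromkeys(grouping[p] for p in pops))
    labels = ds.individuals["population"].to_numpy()
    g = ds.genotypes
    called = g != MISSING

    # per pop x locus alt counts and copy counts
    P, G, L = len(pops), len(groups), ds.n_snps
    alt_p = np.zeros((P, L))
    cop_p = np.zeros((P, L))
    n_ind_p = np.zeros(P)
    for k, pop in enumerate(pops):
        m = labels == pop
        n_ind_p[k] = m.sum()
        alt_p[k] = np.where(called[m], g[m], 0).sum(axis=0)
        cop_p[k] = 2 * called[m].sum(axis=0)
    grp_of = np.array([groups.index(grouping[p]) for p in pops])
    alt_g = np.zeros((G, L))
    cop_g = np.zeros((G, L))
    for gi in range(G):
        alt_g[gi] = alt_p[grp_of == gi].sum(axis=0)
        cop_g[gi] = cop_p[grp_of == gi].sum(axis=0)
    alt_t = alt_p.sum(axis=0)
    cop_t = cop_p.sum(axis=0)

    ss_wp = _ss_within(alt_p, cop_p).sum()
    ss_wg = _ss_within(alt_g, cop_g).sum()
    ss_t = _ss_within(alt_t[None, :], cop_t[None, :]).sum()
    ss_ap = ss_wg - ss_wp          # among pops within groups
    ss_ag = ss_t - ss_wg           # among groups

    N = int(n_ind_p.sum())
    df_ag = G - 1
    df_ap = P - G
    df_wp = 2 * N - P
    if df_ag < 1:
        raise ValueError("AMOVA needs at least two groups")

    # unequal-size coefficients on gene-copy counts (complete-case design)
    m_p = 2 * n_ind_p
    m_g = np.array([m_p[grp_of == gi].sum() for gi in range(G)])
    M = m_p.sum()
    sum_mp2_over_mg = sum((m_p[grp_of == gi] ** 2).sum() / m_g[gi] for gi in range(G))
    n1 = (M - sum_mp2_over_mg) / df_ap if df_ap > 0 else np.nan
    n2 = (sum_mp2_over_mg - (m_p ** 2).sum() / M) / df_ag
    n3 = (M - (m_g ** 2).sum() / M) / df_ag

    ms_wp = ss_wp / df_wp
    sigma_c = ms_wp
    if df_ap > 0:
        sigma_b = (ss_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    comps = (sigma_a, sigma_b, sigma_c)
    pct = variance_percentages(comps)
    table = pd.DataFrame({
        "stratum": ["among_groups", "among_pops_within_groups", "within_pops"],
        "df": [df_ag, df_ap, df_wp],
        "ssq": [ss_ag, ss_ap, ss_wp],
        "variance": list(comps),
        "percent": pct,
    })
    singles = [gr for gi, gr in enumerate(groups) if (grp_of == gi).sum() == 1]
    return AmovaResult(table=table, components=comps, singleton_groups=singles)


def theta_from_nested_anova(ds: GenotypeDataset,
                            populations: list[str] | None = None) -> float:
    """Multilocus theta via the gene-copy nested ANOVA with strata
    population / individual / gamete.

    This is an independent sums-of-squares route to the same estimator
    as :func:`wc_theta` (the W&C components are the method-of-moments
    solution of this nesting); the two agree to machine precision.
    """
    pops = populations if populations is not None else ds.populations()
    labels = ds.individuals["population"].to_numpy()
    mask = np.isin(labels, pops)
    g = ds.genotypes[mask]
    lab = labels[mask]
    num = den = 0.0
    for l in range(g.shape[1]):
        gl = g[:, l]
        called = gl != MISSING
        if called.sum() < 2:
            continue
        ni = np.array([np.sum(called & (lab == pop)) for pop in pops], float)
        if (ni > 0).sum() < 2:
            continue
        ni = ni[ni > 0]
        N = ni.sum()
        r = len(ni)
        # sums of squares from mismatch identities at each level
        def ss(alt, cop):
            ref = cop - alt
            return (cop - (alt ** 2 + ref ** 2) / cop) / 2.0
        alt_i = np.array([gl[called & (lab == pop)].sum() for pop in pops if
                          np.sum(called & (lab == pop)) > 0], float)
        cop_i = 2 * ni
        ss_wp = sum(ss(a, c) for a, c in zip(alt_i, cop_i))
        ss_t = ss(alt_i.sum(), cop_i.sum())
        # within individuals: heterozygotes contribute 1/2 each
        ss_wi = 0.5 * np.sum(gl[called] == 1)
        ss_b = ss_wp - ss_wi
        ss_a = ss_t - ss_wp
        if N <= r or r < 2:
            continue
        ms_a = ss_a / (r - 1)
        ms_b = ss_b / (N - r)
        ms_c = ss_wi / N
        nc = (N - (ni ** 2).sum() / N) / (r - 1)
        sigma_c = ms_c
        sigma_b = (ms_b - ms_c) / 2.0
        sigma_a = (ms_a - ms_c - 2.0 * sigma_b) / (2.0 * nc)
        tot = sigma_a + sigma_b + sigma_c
        if tot != 0 and np.isfinite(tot):
            num += sigma_a
            den += tot
    if den == 0:
        raise ValueError("no locus with defined variance components")
    return num / den
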