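"""Microhaplotype co-ancestry painting and ancestry decomposition.

The painting emphasises the most recent shared ancestry between
individuals: at every RAD tag, each of a recipient's two haplotype
alleles donates one unit of co-ancestry to whichever other individuals
carry the nearest haplotype (minimal Hamming distance over the tag's
SNPs), split equally among ties.  Row i of the resulting matrix
therefore sums to exactly two units per tag the recipient is genotyped
at - a conservation property the tests assert.

The matrix feeds three consumers: per-population mean intra-population
co-ancestry (a Table-style summary column), intra- versus inter-basin
contrasts tested with Tukey's HSD, and an average-linkage dendrogram
over individuals.  A supervised EM decomposes each individual's
genotype into ancestry proportions over reference allele-frequency
panels - plumbing for quantifying stocking-mediated introgression
(e.g. hybrid swarms at known recipient lakes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import studentized_range

from .datasets import MISSING, GenotypeDataset, MicrohapDataset


# ---------------------------------------------------------------------------
# painting
# ---------------------------------------------------------------------------

@dataclass
class CoancestryMatrix:
    """Individual x individual painting scores (rows = recipients)."""

    matrix: np.ndarray
    individuals: pd.DataFrame
    loci_used: np.ndarray          # tags each recipient was genotyped at

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.individuals["id"])
        return pd.DataFrame(self.matrix, index=ids, columns=ids)


def paint_coancestry(mh: MicrohapDataset) -> CoancestryMatrix:
    """Nearest-haplotype co-ancestry painting over all tags.

    Tags are arranged by genomic position first.  Individuals genotyped
    at zero tags are kept in the matrix (zero rows) but reported; each
    genotyped tag contributes exactly two units to its recipient's row.
    """
    mh = mh.sorted_by_position()
    n = mh.n_individuals
    if n < 3:
        raise ValueError("painting needs at least three individuals")
    M = np.zeros((n, n))
    loci_used = np.zeros(n, dtype=np.int64)
    eye = np.eye(n, dtype=bool)
    for tag in mh.tags:
        genos = tag.genos
        ok = (genos != MISSING).all(axis=1)
        if ok.sum() < 2:
            continue
        Dm = tag.code_distances().astype(float)
        A = genos.copy()
        A[~ok] = 0                                  # placeholder, masked below
        big = Dm.max() + 1.0
        for h in (0, 1):
            # dist[i, j] = min over j's two alleles of Hamming(i's h-allele, .)
            d0 = Dm[A[:, h][:, None], A[:, 0][None, :]]
            d1 = Dm[A[:, h][:, None], A[:, 1][None, :]]
            d = np.minimum(d0, d1)
            d[:, ~ok] = np.inf                      # ungenotyped can't receive
            d[~ok, :] = np.inf                      # ungenotyped don't paint
            np.fill_diagonal(d, np.inf)             # never paint yourself
            with np.errstate(invalid="ignore"):
                rowmin = d.min(axis=1)
            donors = ok & np.isfinite(rowmin)
            ties = (d == rowmin[:, None]) & ~eye
            counts = ties.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                share = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
            M[donors] += ties[donors] * share[donors, None]
        loci_used += ok.astype(np.int64)
    orphans = loci_used == 0
    if orphans.any():
        import logging
        logging.getLogger(__name__).warning(
            "%d individuals painted at zero tags", int(orphans.sum()))
    return CoancestryMatrix(matrix=M, individuals=mh.individuals.copy(),
                            loci_used=loci_used)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class CoancestryGroupStats:
    per_population: pd.Series           # mean intra-population score
    intra_basin: np.ndarray             # pairwise scores within a basin
    inter_basin: np.ndarray             # pairwise scores across basins


def coancestry_group_stats(cm: CoancestryMatrix,
                           basins: list[str] | None = None
                           ) -> CoancestryGroupStats:
    """Mean intra-population co-ancestry plus intra-/inter-basin score sets.

    ``basins`` restricts the basin contrast to individuals whose
    ``drainage`` is in the list (e.g. the two heavily stocked basins);
    by default all drainages enter.  Scores are taken over ordered pairs
    (the matrix is not symmetric).  Singleton populations have no intra
    mean and report NaN.
    """
    M = cm.matrix
    ind = cm.individuals
    pops = list(dict.fromkeys(ind["population"]))
    per_pop = {}
    for pop in pops:
        idx = np.flatnonzero((ind["population"] == pop).to_numpy())
        if len(idx) < 2:
            per_pop[pop] = np.nan
            continue
        block = M[np.ix_(idx, idx)]
        off = ~np.eye(len(idx), dtype=bool)
        per_pop[pop] = float(block[off].mean())
    drain = ind["drainage"].to_numpy()
    use = np.ones(len(ind), dtype=bool) if basins is None else np.isin(drain, basins)
    idx = np.flatnonzero(use)
    intra, inter = [], []
    for i in idx:
        for j in idx:
            if i == j:
                continue
            (intra if drain[i] == drain[j] else inter).append(M[i, j])
    return CoancestryGroupStats(per_population=pd.Series(per_pop),
                                intra_basin=np.asarray(intra),
                                inter_basin=np.asarray(inter))


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.001) -> pd.DataFrame:
    """Tukey's HSD over named groups of values (Tukey-Kramer for unequal n).

    Returns one row per pair with the mean difference, the studentized
    range statistic q, its p-value, and a significance flag at ``alpha``.
    With zero within-group variance everywhere, means are compared
    exactly (p is 0 or 1).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrs.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs at least two values")
    k = len(names)
    N = sum(len(v) for v in arrs.values())
    df = N - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in arrs.values()) / df
    rows = []
    for a, b in itertools.combinations(names, 2):
        va, vb = arrs[a], arrs[b]
        diff = va.mean() - vb.mean()
        if mse > 0:
            se = np.sqrt(mse / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
            q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df))
        else:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        rows.append({"group_a": a, "group_b": b, "mean_diff": diff,
                     "q": q, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_coancestry(cm: CoancestryMatrix) -> tuple[np.ndarray, str]:
    """Average-linkage dendrogram over individuals.

    Similarity is symmetrised as (M + M^T)/2 and converted to a
    dissimilarity by max-minus.  Returns the scipy linkage matrix and a
    newick string with individual ids as leaves.
    """
    sym = (cm.matrix + cm.matrix.T) / 2.0
    dis = sym.max() - sym
    np.fill_diagonal(dis, 0.0)
    cond = dis[np.triu_indices(cm.n, k=1)]
    Z = hierarchy.linkage(cond, method="average")
    ids = list(cm.individuals["id"])
    newick = _linkage_to_newick(Z, ids)
    return Z, newick


def cut_clusters(Z: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels from a linkage matrix (1..k)."""
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# supervised ancestry EM
# ---------------------------------------------------------------------------

@dataclass
class AncestryResult:
    """Per-individual ancestry proportions over reference panels."""

    q: pd.DataFrame                # individuals x sources, rows sum to 1
    log_likelihood: np.ndarray     # trace of the total log-likelihood
    n_iter: int
    converged: bool


def supervised_ancestry_em(ds: GenotypeDataset, panels: dict[str, np.ndarray],
                           max_iter: int = 500, tol: float = 1e-6,
                           freq_floor: float = 1e-3,
                           accelerate: bool = True) -> AncestryResult:
    """Decompose genotypes into panel ancestry proportions by EM.

    ``panels`` maps each source name to per-SNP alternate-allele
    frequencies over the dataset's loci.  Each of an individual's 2L
    allele copies is modelled as drawn from source k with probability
    q_k and emitting its allele with the panel frequency; the EM
    maximises the resulting mixture likelihood per individual.

    Plain EM crawls along the nearly flat likelihood ridge that closely
    related panels create, so by default each iteration takes a SQUAREM
    extrapolation step (two EM sub-steps, a per-individual step length,
    then one stabilising EM sub-step) with a monotonicity safeguard:
    any extrapolation that lowers an individual's log-likelihood falls
    back to the plain EM update, so the recorded log-likelihood trace is
    non-decreasing.  Iteration stops when every individual's max
    |delta q| falls below ``tol`` or after ``max_iter`` iterations.
    """
    sources = list(panels)
    if len(sources) < 2:
        raise ValueError("need at least two reference panels")
    F = np.stack([np.asarray(panels[s], dtype=float) for s in sources])  # (K, L)
    if F.shape[1] != ds.n_snps:
        raise ValueError("panel frequencies must cover the dataset's loci")
    F = np.clip(F, freq_floor, 1.0 - freq_floor)
    K, L = F.shape
    G = ds.genotypes
    called = G != MISSING
    if not called.any(axis=1).all():
        raise ValueError("an individual has no genotyped locus shared with the panels")
    alt = np.where(called, G, 0).astype(float)          # alt-copy counts
    ref = np.where(called, 2 - G, 0).astype(float)
    n = ds.n_individuals

    def loglik(q: np.ndarray) -> np.ndarray:
        walt = np.maximum(q @ F, 1e-300)
        wref = np.maximum(q @ (1.0 - F), 1e-300)
        return (alt * np.log(walt) + ref * np.log(wref)).sum(axis=1)

    def em_step(q: np.ndarray) -> np.ndarray:
        walt = np.maximum(q @ F, 1e-300)
        wref = np.maximum(q @ (1.0 - F), 1e-300)
        n_k = (q[:, :, None] * (alt / walt)[:, None, :] * F[None, :, :]).sum(axis=2)
        n_k += (q[:, :, None] * (ref / wref)[:, None, :] * (1.0 - F)[None, :, :]).sum(axis=2)
        return n_k / n_k.sum(axis=1, keepdims=True)

    def project(q: np.ndarray) -> np.ndarray:
        q = np.clip(q, 1e-12, None)
        return q / q.sum(axis=1, keepdims=True)

    def em_step_sub(q: np.ndarray, rows: np.ndarray) -> np.ndarray:
        a, rf = alt[rows], ref[rows]
        walt = np.maximum(q @ F, 1e-300)
        wref = np.maximum(q @ (1.0 - F), 1e-300)
        n_k = (q[:, :, None] * (a / walt)[:, None, :] * F[None, :, :]).sum(axis=2)
        n_k += (q[:, :, None] * (rf / wref)[:, None, :] * (1.0 - F)[None, :, :]).sum(axis=2)
        return n_k / n_k.sum(axis=1, keepdims=True)

    def loglik_sub(q: np.ndarray, rows: np.ndarray) -> np.ndarray:
        walt = np.maximum(q @ F, 1e-300)
        wref = np.maximum(q @ (1.0 - F), 1e-300)
        return (alt[rows] * np.log(walt) + ref[rows] * np.log(wref)).sum(axis=1)

    q = np.full((n, K), 1.0 / K)
    ll_per_ind = loglik(q)
    trace = [float(ll_per_ind.sum())]
    active = np.arange(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        qa = q[active]
        q1 = em_step_sub(qa, active)
        if accelerate:
            q2 = em_step_sub(q1, active)
            r = q1 - qa
            v = (q2 - q1) - r
            vnorm = np.linalg.norm(v, axis=1)
            rnorm = np.linalg.norm(r, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                step = np.where(vnorm > 0, -rnorm / np.maximum(vnorm, 1e-300), -1.0)
            step = np.clip(step, -64.0, -1.0)[:, None]
            q_acc = project(qa - 2.0 * step * r + step ** 2 * v)
            q_next = em_step_sub(q_acc, active)
            # safeguard: never accept a step that lowers the likelihood
            ll_next = loglik_sub(q_next, active)
            ll_plain = loglik_sub(q2, active)
            worse = ll_next < ll_plain
            q_next[worse] = q2[worse]
            ll_next[worse] = ll_plain[worse]
        else:
            q_next = q1
            ll_next = loglik_sub(q_next, active)
        delta = np.abs(q_next - qa).max(axis=1)
        q[active] = q_next
        ll_per_ind[active] = ll_next
        trace.append(float(ll_per_ind.sum()))
        active = active[delta >= tol]
        if active.size == 0:
            converged = True
            break
    qf = pd.DataFrame(q, index=ds.individuals["id"], columns=sources)
    return AncestryResult(q=qf, log_likelihood=np.asarray(trace),
                          n_iter=it, converged=converged)
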