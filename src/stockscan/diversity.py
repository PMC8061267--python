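"""Per-population genetic diversity and effective population size.

Diversity statistics follow the conventions of the standard R diversity
packages: observed heterozygosity H_O (mean over loci of the
heterozygote share), unbiased expected heterozygosity
H_E = (2n/(2n-1)) (1 - sum p^2), allelic richness A_r by rarefaction to
a standard sample of g gene copies, and the multilocus inbreeding
coefficient F_IS = 1 - mean(H_O)/mean(H_E) over polymorphic loci
(ratio of means, which is robust to loci with tiny H_E).

Effective population size uses the bias-corrected linkage-disequilibrium
method: Burrows' composite Delta between loci on *different*
chromosomes (inter-chromosomal pairs carry no physical linkage, only
drift LD), squared correlations corrected for the finite sample, and
the closed-form inversion

    N_e = (1/3 + sqrt(1/9 - 2.76 r2_drift)) / (2 r2_drift)

for samples of S >= 30 individuals (with the matching small-sample
coefficients otherwise).  ``r2_drift <= 0`` reports an infinite
estimate: the data carry no more LD than sampling alone explains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .datasets import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    """Population diversity summary (averages over retained loci)."""

    h_o: float
    h_e: float
    a_r: float
    f_is: float
    n_loci: int
    rarefaction_g: int
    #: variants restricted to polymorphic loci (the headline figures
    #: average over all retained loci, monomorphic included)
    h_o_polymorphic: float = math.nan
    h_e_polymorphic: float = math.nan


def _rarefied_richness(counts: np.ndarray, copies: np.ndarray, g: int) -> np.ndarray:
    """A_r = sum_alleles [1 - C(N - N_i, g) / C(N, g)] per locus.

    ``counts`` is (n_alleles, L) allele copy counts, ``copies`` the total
    per locus.  Uses log-gamma for the binomial ratios.
    """
    def log_comb(n, k):
        n = np.asarray(n, dtype=float)
        out = gammaln(n + 1) - gammaln(n - k + 1) - gammaln(k + 1)
        return out
    N = copies.astype(float)
    terms = np.zeros(counts.shape[1])
    for allele in range(counts.shape[0]):
        Ni = counts[allele].astype(float)
        rem = N - Ni
        with np.errstate(invalid="ignore"):
            ratio = np.where(rem >= g, np.exp(log_comb(rem, g) - log_comb(N, g)), 0.0)
        terms += np.where(Ni > 0, 1.0 - ratio, 0.0)
    return terms


def pop_diversity(ds: GenotypeDataset, population: str,
                  rarefaction_g: int | None = None) -> DiversityStats:
    """Diversity statistics for one population.

    ``rarefaction_g`` defaults to the smallest number of gene copies
    observed at any locus with data (so every locus supports the
    rarefied draw); an explicit g larger than that raises.
    """
    mask = ds.pop_mask(population)
    g_mat = ds.genotypes[mask]
    called = g_mat != MISSING
    n = called.sum(axis=0).astype(float)
    use = n >= 1
    if not use.any():
        raise ValueError(f"population {population!r} has no genotyped locus")
    n = n[use]
    sub = g_mat[:, use]
    called = called[:, use]
    het = ((sub == 1) & called).sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    copies = 2 * n
    p = alt / copies
    ho = het / n
    he = np.where(n > 1, (copies / np.maximum(copies - 1, 1)) * 2 * p * (1 - p), 0.0)

    min_copies = int(copies.min())
    g = rarefaction_g if rarefaction_g is not None else min_copies
    if g > min_copies:
        raise ValueError(
            f"rarefaction g={g} exceeds the smallest locus sample of "
            f"{min_copies} gene copies; use g <= {min_copies}")
    if g < 1:
        raise ValueError("rarefaction g must be >= 1")
    counts = np.stack([copies - alt, alt])
    a_r = _rarefied_richness(counts, copies, g)

    poly = he > 0
    f_is = 1.0 - ho[poly].mean() / he[poly].mean() if poly.any() else math.nan
    return DiversityStats(
        h_o=float(ho.mean()), h_e=float(he.mean()), a_r=float(a_r.mean()),
        f_is=float(f_is), n_loci=int(use.sum()), rarefaction_g=int(g),
        h_o_polymorphic=float(ho[poly].mean()) if poly.any() else math.nan,
        h_e_polymorphic=float(he[poly].mean()) if poly.any() else math.nan,
    )


def default_rarefaction_g(ds: GenotypeDataset) -> int:
    """Smallest per-locus gene-copy count across populations (floor 2)."""
    labels = ds.individuals["population"].to_numpy()
    g = ds.genotypes
    best = None
    for pop in ds.populations():
        called = (g[labels == pop] != MISSING).sum(axis=0)
        with_data = called[called > 0]
        if with_data.size:
            m = int(2 * with_data.min())
            best = m if best is None else min(best, m)
    return max(best or 2, 2)


def diversity_table(ds: GenotypeDataset, rarefaction_g: int | None = None
                    ) -> pd.DataFrame:
    """Per-population diversity table (one row per population)."""
    g = rarefaction_g if rarefaction_g is not None else default_rarefaction_g(ds)
    rows = []
    for pop in ds.populations():
        st = pop_diversity(ds, pop, rarefaction_g=g)
        rows.append({"population": pop, "n": int(ds.pop_mask(pop).sum()),
                     "H_O": st.h_o, "H_E": st.h_e, "A_r": st.a_r,
                     "F_IS": st.f_is, "n_loci": st.n_loci})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LD effective population size
# ---------------------------------------------------------------------------

@dataclass
class NeEstimate:
    """Linkage-disequilibrium N_e with a parametric chi-square CI."""

    r2_mean: float
    r2_drift: float
    sample_size: float
    ne: float                     # math.inf for "Infinite"
    ci_low: float
    ci_high: float
    n_pairs: int
    pcrit: float

    def formatted(self) -> str:
        def fmt(x):
            return "Infinite" if math.isinf(x) else f"{x:.1f}"
        return f"Ne={fmt(self.ne)} (95% CI {fmt(self.ci_low)}-{fmt(self.ci_high)})"


def _expected_r2(S: np.ndarray | float) -> np.ndarray | float:
    """Finite-sample expectation of r^2 under no drift LD."""
    S = np.asarray(S, dtype=float)
    large = 1.0 / S + 3.19 / S ** 2
    small = 0.0018 + 0.907 / S + 4.44 / S ** 2
    return np.where(S >= 30, large, small)


def _ne_from_r2drift(r2d: float, S: float) -> float:
    if r2d <= 0:
        return math.inf
    if S >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2d, 0.0)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2d)
    disc = max(0.308 ** 2 - 2.08 * r2d, 0.0)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2d)


def ld_ne(ds: GenotypeDataset, population: str, pcrit: float = 0.05,
          ci: str = "parametric") -> NeEstimate:
    """LD effective population size for one population.

    Only pairs of SNPs on different chromosomes enter; SNPs whose minor
    allele frequency within the population is below ``pcrit`` are
    excluded.  The composite Burrows Delta is computed pairwise-complete
    over individuals genotyped at both loci, and r-bar-squared is the
    S-weighted mean over pairs.
    """
    mask = ds.pop_mask(population)
    sub = ds.take(ind_idx=mask)
    if sub.n_individuals < 10:
        raise ValueError("LD-Ne needs at least 10 individuals")
    maf = sub.minor_allele_freq()
    keep = np.nan_to_num(maf, nan=0.0) >= pcrit
    sub = sub.take(snp_idx=keep)
    chroms = sub.snps["chrom"].to_numpy()
    if len(set(chroms)) < 2:
        raise ValueError("LD-Ne needs SNPs on at least two chromosomes")

    g = sub.genotypes.astype(float)
    called = g != MISSING
    X = np.where(called, g, 0.0)
    C = called.astype(float)
    L = g.shape[1]

    S = C.T @ C                                  # pairwise sample sizes
    sxy = X.T @ X                                # sum of dose products
    sx = X.T @ C                                 # sum of x over complete pairs
    sy = sx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        px = sx / (2.0 * S)
        py = sy / (2.0 * S)
        # Burrows composite Delta with the standard S/(S-1) correction
        delta = (sxy / (2.0 * S) - 2.0 * px * py) * S / np.maximum(S - 1.0, 1.0)
        denom = px * (1 - px) * py * (1 - py)
        r2 = np.where(denom > 0, delta ** 2 / denom, np.nan)

    inter = chroms[:, None] != chroms[None, :]
    iu = np.triu_indices(L, k=1)
    use = inter[iu] & (S[iu] >= 2) & np.isfinite(r2[iu])
    if not use.any():
        raise ValueError("no qualifying inter-chromosomal locus pairs")
    r2p = r2[iu][use]
    Sp = S[iu][use]
    w = Sp / Sp.sum()
    r2_mean = float((w * r2p).sum())
    S_mean = float((w * Sp).sum())
    r2_drift = float((w * (r2p - _expected_r2(Sp))).sum())
    ne = _ne_from_r2drift(r2_drift, S_mean)

    n_pairs = int(use.sum())
    if ci == "parametric":
        lo_r2 = r2_mean * n_pairs / chi2.ppf(0.975, n_pairs)
        hi_r2 = r2_mean * n_pairs / chi2.ppf(0.025, n_pairs)
        shift = r2_mean - r2_drift
        ci_high = _ne_from_r2drift(lo_r2 - shift, S_mean)
        ci_low = _ne_from_r2drift(hi_r2 - shift, S_mean)
    elif ci == "jackknife":
        ci_low, ci_high = _jackknife_ci(sub, pcrit, S_mean)
    else:
        raise ValueError(f"unknown CI method {ci!r}")
    return NeEstimate(r2_mean=r2_mean, r2_drift=r2_drift, sample_size=S_mean,
                      ne=ne, ci_low=ci_low, ci_high=ci_high,
                      n_pairs=n_pairs, pcrit=pcrit)


def _jackknife_ci(sub: GenotypeDataset, pcrit: float, S_mean: float
                  ) -> tuple[float, float]:
    """Delete-one-individual jackknife on r2_drift (optional, slower)."""
    n = sub.n_individuals
    vals = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        pseudo = sub.take(ind_idx=keep)
        pseudo.individuals = pseudo.individuals.assign(population="jk")
        try:
            est = ld_ne(pseudo, "jk", pcrit=pcrit, ci="parametric")
        except ValueError:
            continue
        vals.append(est.r2_drift)
    vals = np.asarray(vals)
    mean = vals.mean()
    se = math.sqrt((len(vals) - 1) / len(vals) * ((vals - mean) ** 2).sum())
    lo, hi = mean - 1.96 * se, mean + 1.96 * se
    return _ne_from_r2drift(hi, S_mean), _ne_from_r2drift(lo, S_mean)


def ne_table(ds: GenotypeDataset, pcrit: float = 0.05) -> pd.DataFrame:
    rows = []
    for pop in ds.populations():
        est = ld_ne(ds, pop, pcrit=pcrit)
        rows.append({"population": pop, "Ne": est.ne, "CI_low": est.ci_low,
                     "CI_high": est.ci_high, "r2_mean": est.r2_mean,
                     "n_pairs": est.n_pairs})
    return pd.DataFrame(rows)
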