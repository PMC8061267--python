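# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `stockscan`, in the order data flows through the
package.

## Synthetic stocked metapopulation

The generator emulates the study design the analysis chain is built for:
two deeply diverged postglacial lineages, each holding several drainages
with several populations, genotyped at RAD tags of 1–10 phased SNPs on
24 chromosomes.

**Tag haplotype model.** A tag with k SNPs carries k + 1 haplotype
alleles: haplotype 0 is all-reference and each SNP arises as a single
mutation on a uniformly chosen existing haplotype (infinite-sites
style).  This gives realistic within-tag linkage disequilibrium and caps
the allele count at 11, matching the behaviour of real short-read RAD
tags (and making the ">10 alleles" microhaplotype filter a rare event,
as it is in practice).

**Frequencies.** Ancestral haplotype frequencies are Dirichlet with the
root haplotype up-weighted (α = 14 for the root, 0.3 per derived
haplotype).  These weights were calibrated once so that the default
scenario's filtered single-SNP dataset shows a mean per-population
expected heterozygosity of ≈ 0.16, the level published RAD surveys of
midwestern walleye report; they also produce the strongly low-MAF-skewed
folded site-frequency spectrum typical of RAD data.  Drift is
hierarchical Dirichlet Balding–Nichols: a lineage-level draw
Dirichlet(f·(1−F)/F) followed by a population-level draw.  Because sums
of Dirichlet components are Beta with the same precision, SNP-level
frequencies inherit exactly the same F, so the SNP-level F_ST
calibration is preserved by construction.

**F calibration.** `F_between` and `F_within` are defined as *target
realized pairwise F_ST* between populations of different lineages and of
the same lineage.  Two stacked drift layers compose as
F_total = F_b' + (1 − F_b')·F_w, so the internal lineage-level parameter
is solved as F_b' = (F_between − F_within)/(1 − F_within).  Defaults
(0.07 between, 0.04 within) reproduce the differentiation scale of the
walleye study region; realized values on the default scenario are
0.068/0.037.

**Stocking pulses.** An admixture event leaves `fraction_pure_native` of
the recipient untouched and converts the rest into hybrids whose
haplotypes, independently per tag and per haplotype copy, descend from
the source population with probability `p_adm`.  The default
Red-Lake-style event (1/3 pure native, p_adm = 0.46) yields an expected
population-mean source ancestry of 2/3 × 0.46 ≈ 0.31.  Realized
per-individual ancestries are recorded in the truth record (rows sum
to 1).

**Collapsed paralogs.** A flagged tag is two independent loci (each with
its own drifted frequencies) whose reads merge: an individual carries
four gene copies, reads heterozygous whenever they disagree, and its
heterozygote allele balance concentrates near 1/4 or 3/4.  One mechanism
therefore produces both HDplot axes (excess H, skewed D).  Read depth is
Poisson(`mean_depth`, default 40); alternate reads are binomial with the
true dosage fraction (0.5 for ordinary heterozygotes).

**What the generator does not model:** missing-data patterns (genotypes
are complete; the missingness filters are exercised on constructed
matrices in the tests), sequencing error, within-tag recombination,
selection, linked drift along chromosomes (loci are independent given
population frequencies — which is why the LD-N_e estimator correctly
reports "Infinite" on it, and a separate forward Wright–Fisher generator
provides finite-N_e ground truth), and overlapping generations.  Passing
tests therefore demonstrate correctness of the estimators under the
stated sampling models, not robustness to every artifact of real data.

**Determinism.** All randomness flows from one integer seed through a
single `numpy` Generator with a documented draw order (tag layout,
genealogies, frequency chains, per-population codes, admixture, hidden
paralog copies, coordinates).  Identical seeds give byte-identical
datasets.

## Filtering

Order: individuals (genotype rate > 0.8) → SNPs (rate > 0.8, MAC ≥ 3,
recomputed once after the individual pass — a SNP whose MAC drops below
threshold when an individual leaves is dropped) → HDplot → branch A
(one SNP per tag by highest MAF, ties to the lowest within-tag index;
then per-SNP F_IS ≤ 0.5) and branch B (microhaplotypes from the
pre-selection whitelist; tags with > 10 alleles or F_IS > 0.5 dropped).
Filters are idempotent on their own output; rates are always computed
over non-missing genotypes, with a missing sentinel distinct from dose 0.

HDplot: H = n_het/n_genotyped per SNP; D = (ΣA − ΣB)/√(ΣA + ΣB) over the
reads of heterozygous individuals, a z-score against Binomial(n, 0.5).
A tag is removed whole when any of its SNPs has H > 0.5 or |D| > 7 —
duplication is a tag-level artifact.  Loci are *retained* when
−7 ≤ D ≤ 7: discarding the balanced middle would invert the screen's
purpose, so the package keeps the standard HDplot convention.  SNPs with
no heterozygotes have undefined D and pass that criterion (logged).
F_IS filters use the global (all-individuals) per-locus
F_IS = 1 − H_O/H_E; monomorphic loci pass.

A loose caller-style pre-filter (presence > 5%, MAF > 0.005) exists
behind a flag and is off by default — synthetic data does not need it.

## Diversity and N_e

Per-locus H_E uses the unbiased (2n/(2n−1)) correction.  A_r is
rarefaction to g gene copies, A_r = Σ_alleles [1 − C(N−N_i, g)/C(N, g)],
computed in log-gamma space; g defaults to the smallest per-locus copy
count so every locus supports the draw, and the identity A_r(g = N) =
observed allele count holds exactly.  Multilocus F_IS is the
ratio-of-means 1 − mean(H_O)/mean(H_E) over polymorphic loci, which is
robust to near-monomorphic loci; headline H_O/H_E average over all
retained loci, with polymorphic-only variants also reported.

LD-N_e uses Burrows' composite Δ with the standard S/(S−1) correction,
r̂² = Δ²/(p(1−p)q(1−q)), restricted to pairs of SNPs on different
chromosomes (free recombination ⇒ the only LD is drift plus sampling)
with per-population MAF ≥ p_crit (default 0.05).  r̄² is the S-weighted
mean over pairs; the sampling expectation 1/S + 3.19/S² (S ≥ 30; the
matching small-S polynomial otherwise) is subtracted pairwise, and the
closed form N̂_e = (1/3 + √(1/9 − 2.76 r²_drift))/(2 r²_drift) inverts
the result.  r²_drift ≤ 0 reports "Infinite" — the data carry no more LD
than sampling explains.  The parametric CI treats n' = number of pairs
as the effective chi-square df (a delete-one-individual jackknife is
available behind a flag).  No mixed-cohort bias correction is applied.
The r² matrices are dense (L × L); at the package's operating scale
(≈ 1–5 k SNPs) this is a few hundred MB at most.

## Structure

Weir–Cockerham variance components a (among populations), b (among
individuals within), c (within individuals) are computed per locus with
the unequal-sample-size formulas; multilocus θ is the ratio of sums,
with zero-variance loci skipped.  An independent sums-of-squares route
(`theta_from_nested_anova`) computes the same estimator as the nested
gene-copy ANOVA over strata population/individual/gamete — the tests
assert agreement at 1e−9, a real two-path consistency check since the
closed-form and SS codepaths share nothing.

Permutation tests permute individuals between the two labels preserving
sizes; p = (1 + #{θ* ≥ θ})/(1 + n_perm).  With equal sizes the exact
complement permutation reproduces θ, so the smallest attainable p can be
2/(n_perm+1) when a draw hits it.

AMOVA operates at the gene-copy level with allele-mismatch distance
summed over loci (pairwise-complete per locus).  Degrees of freedom are
G−1, P−G, 2N−P (summing to 2N−1); variance components come from mean
squares with the standard unequal-size coefficients on gene-copy counts;
negative components are reported as-is, and single-population groups are
allowed (flagged, zero df contribution).  With missing data the SSQs use
the called copies while the coefficients use full sample sizes — exact
for complete data, a documented approximation otherwise.

Nei's D_A and Edwards' distance share the per-locus Bhattacharyya
affinity Σ_u √(x_u y_u); D_A = 1 − mean affinity, Edwards =
√(1 − mean affinity).  D_A is symmetric and zero on the diagonal but not
a metric (no triangle inequality) — documented, not asserted.  The NJ
dendrogram bootstraps loci (tags for microhaplotype data — resampling
SNPs within a tag would pseudo-replicate), reports bipartition support
as the share of replicate trees containing each split, and breaks Q ties
deterministically.  An all-zero distance matrix yields a star tree with
no supported bipartitions.

## Boundaries

Edwards distances are denoised by classical PCoA (double-centring,
`eigh`), keeping only the first axis; the scaled distance is the
absolute axis-1 score difference.  A non-positive leading eigenvalue is
an error (degenerate configuration).  The Monmonier traversal runs on
the Delaunay triangulation: each run seeds at the largest uncrossed edge
above the threshold and extends through the Voronoi dual in both
directions, crossing at each triangle the admissible (uncrossed,
above-threshold) edge of maximal distance, stopping at the hull, a
previously crossed edge, a visited triangle, or when nothing is
admissible.  Ties break on the lowest edge index.  The default threshold
is the third quartile of the network's edge distances (the reference
implementation's default is not printed anywhere; ours is documented,
not claimed identical), and a relax pass re-runs with the threshold
lowered by 5% to probe shallow structure.  Convergence is recorded when
a run finds no admissible seed.

## Co-ancestry

Painting: per tag, each of a recipient's two haplotype alleles donates
one unit, split equally among the other individuals attaining the
minimal Hamming distance to either of their alleles; self never
receives; tags where the recipient is missing are skipped.  Each row
therefore sums to exactly 2 × (tags used) — asserted to 1e−6 — and the
matrix is not symmetric.  Tag order does not matter (sums commute);
tags are nevertheless arranged by genomic position first, matching how
such matrices are built downstream of alignment.  No per-tag allele-count
weighting is applied, so absolute scores are not on the scale of
published RADpainter matrices (whose extra normalisations are out of
scope); all consumers of the matrix here use contrasts, which are
invariant to that scale.

Tukey's HSD uses the pooled one-way MSE and the studentized range
distribution with the Tukey–Kramer adjustment for unequal group sizes
(intra/inter-basin sets are unbalanced by construction); with two groups
q = |t|·√2 recovers the pooled t-test exactly.  Zero within-group
variance everywhere degrades gracefully to exact mean comparison
(p ∈ {0, 1}).

Clustering is average-linkage on the symmetrised similarity converted to
dissimilarity by max-minus.

The supervised ancestry EM models each of an individual's 2L allele
copies as drawn from source k with probability q_k, emitting its allele
at the panel frequency.  Panel frequencies are clipped to
[10⁻³, 1−10⁻³] so fixed panels cannot produce −∞ log-likelihoods.
Closely related panels create a nearly flat likelihood ridge on which
plain EM crawls, so each iteration takes a SQUAREM extrapolation (two EM
sub-steps, a per-individual step length capped at 64, a stabilising EM
sub-step) with a per-individual monotonicity safeguard that falls back
to the plain update — the recorded log-likelihood trace is therefore
non-decreasing, and converged individuals leave the active set.
Convergence: max |Δq| < 10⁻⁶ or 500 iterations.

## Genome scan

Windows tile from coordinate 1 per chromosome (half-open
[start, start+window), so a locus on an end coordinate belongs to the
lower window only), 500 kb wide with a 100 kb step, out to the last
locus.  Kernel weights use σ = window/4 (±2σ spans the window; σ is a
flag).  The significance test uses the *plain* window mean — the null
draws are plain means of n loci sampled from the genome-wide pool
without replacement (with-replacement fallback, with a warning, if a
window somehow exceeds the pool) — while the weighted mean is reported
per window for plotting.  Stage 1 is 1,000 draws; windows above the 90th
percentile graduate to a fresh 10,000-draw stage 2; significance
requires exceeding the 99th percentile with at least two loci.  Null
distributions depend only on n, so they are cached per locus count.
Overlapping or adjacent significant windows merge into regions per
chromosome.  At the default densities (≈ 10 loci per occupied window,
the level the window size was chosen to hit) the null significant
fraction is ≈ 1%, and an implanted +0.15 θ region of 1 Mb is recovered
in ≥ 90% of seeded runs.

## Problem sizes

The default scenario is a deliberately scaled-down replica of a
state-wide survey: 8 populations × 30 individuals, 1,200 tags
(≈ 6,600 SNPs) on 24 chromosomes of 2.5 Mb, chosen so that the filtered
single-SNP dataset lands near 10 loci per 500-kb scan window — the same
occupancy a real ~20,000-tag, ~900-Mb dataset produces.  The test suite
and acceptance script use these sizes (with 2,000-SNP Wright–Fisher
populations and 5,000-locus scan landscapes where a statistic needs its
own geometry); all complete in a few minutes on one CPU.

## Known limitations

* AMOVA's unequal-size coefficients assume complete genotyping (exact on
  filtered synthetic data); heavily missing data shifts the coefficients
  slightly.
* The painting's absolute scale is implementation-specific (see above);
  only contrasts and clusterings are comparable across implementations.
* LD-N_e assumes a closed, unstructured, discrete-generation population;
  admixed or structured samples bias r² upward (N_e downward), which is
  why it is estimated per population after filtering.
* The genome scan's loci are treated as exchangeable under the null;
  recombination-rate variation and local LD are not modelled.
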