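"""Synthetic stocked-metapopulation generator.

Emulates the study design the rest of the package analyses: two (or
more) deeply diverged postglacial lineages, each split into drainages
holding several populations, genotyped at RAD tags of 1-10 phased SNPs
on 24 chromosomes, with a minority of tags behaving as collapsed
paralogs and optional hatchery-style admixture pulses (a fraction of a
recipient population replaced by hybrids carrying source-population
haplotypes).

Each RAD tag is a small haplotype system: a tag with k SNPs carries
k + 1 haplotype alleles, built by placing each SNP as a single mutation
on a uniformly chosen existing haplotype (infinite-sites style), so
within-tag SNPs are in strong linkage disequilibrium as they are in
real short-read tags.  Ancestral haplotype frequencies are Dirichlet
with the root (all-reference) haplotype up-weighted (alpha 14 versus
0.3 per derived haplotype), which produces the low-minor-allele-
frequency folded spectrum and per-population expected heterozygosity
around 0.16 that RAD surveys of wild midwestern fish report.

Drift is hierarchical Dirichlet Balding-Nichols on haplotype
frequencies: a lineage-level draw with precision (1 - F)/F, then a
population-level draw; SNP-level frequencies inherit exactly the same
F because sums of Dirichlet components are Beta with the same
precision.  ``F_between`` and ``F_within`` are calibrated as the
*target realized pairwise* F_ST between populations of different
lineages and of the same lineage, respectively: the internal
lineage-level parameter is ``(F_between - F_within) / (1 - F_within)``
so that the two layers of drift compose to the requested
between-lineage differentiation.

Collapsed paralogs are modelled as two independent loci (each with its
own hierarchical frequencies) whose reads merge: an individual carries
four gene copies, appears heterozygous whenever the copies disagree, and
its heterozygote allele balance sits near 1/4 or 3/4 rather than 1/2 -
reproducing both axes of the HDplot screen with one mechanism.

All randomness flows from ``ScenarioConfig.seed`` through a single
``numpy`` generator; the draw order is: tag layout, haplotype
genealogies, ancestral/lineage/population frequencies (visible then
hidden paralog copy), per-population haplotype codes, admixture origins
and redraws, paralog hidden copies, coordinates jitter.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset, ReadCountTable
from . import io as sio


class AdmixtureEvent(NamedTuple):
    """A stocking pulse: hybrids appear in ``recipient`` carrying ``source`` ancestry.

    ``fraction_pure_native`` of the recipient stays untouched; the rest
    become hybrids whose haplotypes, per RAD tag, descend from the source
    population with probability ``p_adm``.
    """

    recipient: str
    source: str
    p_adm: float
    fraction_pure_native: float


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic stocked metapopulation.

    Defaults describe a two-lineage, eight-population system at the
    differentiation scale of the walleye study region (between-lineage
    F_ST ~= 0.07, within ~= 0.04) with one Red-Lake-style stocking pulse:
    one third of the recipient population pure native, the rest hybrids
    at 46% source ancestry, for an expected population-mean source
    ancestry of ~0.31.
    """

    n_lineages: int = 2
    pops_per_lineage: int = 4
    n_tags: int = 1200
    snps_per_tag: tuple[int, int] = (1, 10)
    n_chromosomes: int = 24
    chrom_length: int = 2_500_000
    F_between: float = 0.07
    F_within: float = 0.04
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)
    sample_sizes: int | dict[str, int] = 30
    mean_depth: float = 40.0
    paralog_fraction: float = 0.0
    seed: int = 0
    lineage_names: list[str] | None = None
    drainages_per_lineage: int = 2
    drainage_of_pop: dict[str, str] | None = None
    lineage_of_pop: dict[str, str] | None = None
    pop_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_lineages < 1 or self.pops_per_lineage < 1:
            raise ValueError("need at least one lineage and one population per lineage")
        lo, hi = self.snps_per_tag
        if lo < 1 or hi > 10 or lo > hi:
            raise ValueError("snps_per_tag must be a sub-range of 1-10")
        if not (0.0 <= self.F_within <= self.F_between < 1.0):
            raise ValueError("require 0 <= F_within <= F_between < 1")
        if self.F_between > 0 and not (self.F_within < self.F_between or self.F_within == 0):
            # equality only allowed at zero (the no-drift scenario)
            raise ValueError("require F_within < F_between when drift is present")
        for ev in self.admixture_events:
            if not (0.0 <= ev.p_adm <= 1.0 and 0.0 <= ev.fraction_pure_native <= 1.0):
                raise ValueError("admixture proportions must lie in [0, 1]")
        if self.lineage_names is None:
            base = ["wisconsin", "minnesota"]
            self.lineage_names = [base[i] if i < 2 else f"lineage{i + 1}"
                                  for i in range(self.n_lineages)]
        if self.pop_names is None:
            self.pop_names, self.drainage_of_pop, self.lineage_of_pop = \
                self._default_layout()
        if self.drainage_of_pop is None or self.lineage_of_pop is None:
            raise ValueError("custom pop_names need drainage_of_pop and lineage_of_pop")
        for p in self.pop_names:
            if p not in self.drainage_of_pop or p not in self.lineage_of_pop:
                raise ValueError(f"population {p!r} missing a drainage or lineage")
        for p in self.pop_names:
            if self.sample_size_of(p) < 2:
                raise ValueError(f"population {p!r} needs at least 2 individuals")
        for ev in self.admixture_events:
            if ev.recipient not in self.pop_names or ev.source not in self.pop_names:
                raise ValueError(f"admixture event names unknown population: {ev}")

    def _default_layout(self) -> tuple[list[str], dict[str, str], dict[str, str]]:
        pops, drainage_of, lineage_of = [], {}, {}
        for li, lname in enumerate(self.lineage_names):
            for k in range(self.pops_per_lineage):
                d = k % max(self.drainages_per_lineage, 1)
                pop = f"{lname}_pop{k + 1}"
                drain = f"{lname}_drainage{d + 1}"
                pops.append(pop)
                drainage_of[pop] = drain
                lineage_of[pop] = lname
        return pops, drainage_of, lineage_of

    def sample_size_of(self, pop: str) -> int:
        if isinstance(self.sample_sizes, dict):
            return int(self.sample_sizes[pop])
        return int(self.sample_sizes)


@dataclass
class TruthRecord:
    """Ground truth recorded by :func:`simulate_metapopulation`.

    ``ancestry`` is individuals x source populations (rows sum to 1);
    ``pop_freqs`` maps each population to its native per-SNP allele
    frequencies (before any admixture pulse); ``alt_fraction`` is each
    individual's true alternate-allele dosage fraction per SNP (dose/2
    for ordinary loci, copies/4 for collapsed paralogs), the quantity
    read sampling conditions on.
    """

    ancestry: pd.DataFrame
    pop_freqs: dict[str, np.ndarray]
    paralog_flags: np.ndarray
    alt_fraction: np.ndarray
    coords: pd.DataFrame
    lineage_of_pop: dict[str, str]
    seed: int

    def lineage_ancestry(self) -> pd.DataFrame:
        """Ancestry aggregated from source populations to source lineages."""
        out = {}
        for lineage in dict.fromkeys(self.lineage_of_pop.values()):
            cols = [p for p in self.ancestry.columns if self.lineage_of_pop[p] == lineage]
            out[lineage] = self.ancestry[cols].sum(axis=1)
        return pd.DataFrame(out)


#: ancestral Dirichlet weights: root haplotype vs each derived haplotype.
#: Calibrated so the default scenario's filtered single-SNP dataset shows
#: per-population expected heterozygosity ~0.16, the level published RAD
#: surveys of midwestern walleye report.
_ALPHA_ROOT = 14.0
_ALPHA_DERIVED = 0.3


def _dirichlet_draw(rng: np.random.Generator, f: np.ndarray, F: float) -> np.ndarray:
    """One Balding-Nichols drift step on haplotype frequencies:
    Dirichlet(f * (1-F)/F), whose components have variance F f (1-f)."""
    if F <= 0.0:
        return f.copy()
    alpha = np.maximum(f * (1.0 - F) / F, 1e-6)
    return rng.dirichlet(alpha)


def _tag_genealogy(rng: np.random.Generator, k: int) -> np.ndarray:
    """Haplotype matrix (k+1, k): row 0 all-reference, each SNP a single
    mutation placed on a uniformly chosen existing haplotype."""
    H = np.zeros((k + 1, k), dtype=np.int8)
    for j in range(k):
        parent = int(rng.integers(0, j + 1))
        H[j + 1] = H[parent]
        H[j + 1, j] = 1
    return H


def _draw_codes(rng: np.random.Generator, freq: np.ndarray, shape: tuple) -> np.ndarray:
    """Sample haplotype codes from a frequency vector."""
    cum = np.cumsum(freq)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(shape), side="right").astype(np.int16)


def simulate_metapopulation(config: ScenarioConfig
                            ) -> tuple[GenotypeDataset, TruthRecord]:
    """Draw a phased genotype dataset and its ground truth from ``config``.

    Returns the dataset sorted by (chromosome, position); identical seeds
    give identical output.
    """
    rng = np.random.default_rng(config.seed)

    # --- tag layout ----------------------------------------------------
    n_tags = config.n_tags
    lo, hi = config.snps_per_tag
    snps_per_tag = rng.integers(lo, hi + 1, size=n_tags)
    tag_chrom = rng.integers(0, config.n_chromosomes, size=n_tags)
    tag_pos = rng.integers(1, max(config.chrom_length - 150, 2), size=n_tags)
    order = np.lexsort((tag_pos, tag_chrom))
    snps_per_tag, tag_chrom, tag_pos = (snps_per_tag[order], tag_chrom[order],
                                        tag_pos[order])
    rows = []
    for t in range(n_tags):
        k = int(snps_per_tag[t])
        offsets = np.sort(rng.choice(140, size=k, replace=False))
        for j, off in enumerate(offsets):
            rows.append((f"chr{tag_chrom[t] + 1}", int(tag_pos[t] + off), t, j, "A", "T"))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "tag", "tag_index", "ref", "alt"])
    n_snps = len(snps)
    snp_slices = []
    start = 0
    for t in range(n_tags):
        k = int(snps_per_tag[t])
        snp_slices.append(slice(start, start + k))
        start += k

    # --- haplotype genealogies and hierarchical frequencies ------------
    genealogies = [_tag_genealogy(rng, int(k)) for k in snps_per_tag]
    Fw = config.F_within
    Fb_eff = 0.0
    if config.F_between > 0:
        Fb_eff = (config.F_between - Fw) / (1.0 - Fw)
    pop_list = config.pop_names
    lineages = config.lineage_names

    def drift_chain() -> list[dict[str, np.ndarray]]:
        """Per-tag {pop: haplotype freqs} through the two drift layers."""
        out = []
        for t in range(n_tags):
            k = int(snps_per_tag[t])
            alpha0 = np.full(k + 1, _ALPHA_DERIVED)
            alpha0[0] = _ALPHA_ROOT
            f0 = rng.dirichlet(alpha0)
            f_lin = {ln: _dirichlet_draw(rng, f0, Fb_eff) for ln in lineages}
            out.append({pop: _dirichlet_draw(rng, f_lin[config.lineage_of_pop[pop]], Fw)
                        for pop in pop_list})
        return out

    hap_freqs = drift_chain()

    # --- paralogs: a hidden second locus per flagged tag ----------------
    n_par = int(round(config.paralog_fraction * n_tags))
    paralog_flags = np.zeros(n_tags, dtype=bool)
    if n_par:
        paralog_flags[rng.choice(n_tags, size=n_par, replace=False)] = True
    hap_freqs_copy2 = drift_chain() if n_par else None

    # --- individuals: haplotype codes per tag ---------------------------
    sizes = [config.sample_size_of(pop) for pop in pop_list]
    N = sum(sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    codes = np.empty((N, n_tags, 2), dtype=np.int16)
    for pi, pop in enumerate(pop_list):
        sl = slice(offsets[pi], offsets[pi + 1])
        for t in range(n_tags):
            codes[sl, t, :] = _draw_codes(rng, hap_freqs[t][pop], (sizes[pi], 2))

    ancestry_mat = np.zeros((N, len(pop_list)))
    for pi, pop in enumerate(pop_list):
        ancestry_mat[offsets[pi]:offsets[pi + 1], pi] = 1.0
    for ev in config.admixture_events:
        pi = pop_list.index(ev.recipient)
        n = sizes[pi]
        n_hyb = int(round((1.0 - ev.fraction_pure_native) * n))
        if n_hyb == 0:
            continue
        hyb = np.arange(offsets[pi + 1] - n_hyb, offsets[pi + 1])
        origin = rng.random((n_hyb, n_tags, 2)) < ev.p_adm
        for t in range(n_tags):
            redraw = _draw_codes(rng, hap_freqs[t][ev.source], (n_hyb, 2))
            codes[hyb, t, :] = np.where(origin[:, t, :], redraw, codes[hyb, t, :])
        frac = origin.reshape(n_hyb, -1).mean(axis=1)
        ancestry_mat[hyb, pop_list.index(ev.source)] = frac
        ancestry_mat[hyb, pi] = 1.0 - frac

    # --- expand haplotype codes to per-SNP alleles ----------------------
    hap = np.empty((N, n_snps, 2), dtype=np.int8)
    for t in range(n_tags):
        H = genealogies[t]
        hap[:, snp_slices[t], :] = H[codes[:, t, :]].transpose(0, 2, 1)
    genotypes = hap.sum(axis=2, dtype=np.int8)
    alt_fraction = (genotypes / 2.0).astype(np.float32)

    if n_par:
        for t in np.flatnonzero(paralog_flags):
            H = genealogies[t]
            hidden = np.empty((N, 2), dtype=np.int16)
            for pi, pop in enumerate(pop_list):
                sl = slice(offsets[pi], offsets[pi + 1])
                hidden[sl] = _draw_codes(rng, hap_freqs_copy2[t][pop], (sizes[pi], 2))
            sl_snp = snp_slices[t]
            copies = (hap[:, sl_snp, :].sum(axis=2)
                      + H[hidden].transpose(0, 2, 1).sum(axis=2))  # 0..4
            obs = np.where(copies == 0, 0, np.where(copies == 4, 2, 1)).astype(np.int8)
            genotypes[:, sl_snp] = obs
            # phase of a collapsed tag is arbitrary but consistent with dose
            hap[:, sl_snp, 0] = np.where(obs == 2, 1, 0)
            hap[:, sl_snp, 1] = np.where(obs >= 1, 1, 0)
            alt_fraction[:, sl_snp] = (copies / 4.0).astype(np.float32)

    # --- truth: SNP-level native frequencies per population -------------
    pop_freqs = {}
    for pop in pop_list:
        p = np.empty(n_snps)
        for t in range(n_tags):
            p[snp_slices[t]] = hap_freqs[t][pop] @ genealogies[t]
        pop_freqs[pop] = p

    ind_rows = []
    for pi, pop in enumerate(pop_list):
        for i in range(sizes[pi]):
            ind_rows.append((f"{pop}_{i:03d}", pop, config.drainage_of_pop[pop],
                             config.lineage_of_pop[pop]))
    individuals = pd.DataFrame(ind_rows, columns=["id", "population", "drainage", "group"])
    ds = GenotypeDataset(genotypes=genotypes, snps=snps, individuals=individuals,
                         haplotypes=hap)
    ancestry = pd.DataFrame(ancestry_mat, columns=pop_list,
                            index=individuals["id"])

    coords = _population_coordinates(config, rng)
    truth = TruthRecord(ancestry=ancestry, pop_freqs=pop_freqs,
                        paralog_flags=paralog_flags, alt_fraction=alt_fraction,
                        coords=coords, lineage_of_pop=dict(config.lineage_of_pop),
                        seed=config.seed)
    return ds, truth


def _population_coordinates(config: ScenarioConfig, rng: np.random.Generator
                            ) -> pd.DataFrame:
    """Planar coordinates: lineages as well-separated blocks along x,
    drainages as bands along y, populations jittered inside their band."""
    rows = []
    lineages = config.lineage_names
    for pop in config.pop_names:
        li = lineages.index(config.lineage_of_pop[pop])
        drains = sorted({d for p, d in config.drainage_of_pop.items()
                         if config.lineage_of_pop[p] == config.lineage_of_pop[pop]})
        di = drains.index(config.drainage_of_pop[pop])
        x = 3.0 * li + rng.uniform(0.0, 1.0)
        y = 2.0 * di + rng.uniform(0.0, 1.0)
        rows.append((pop, x, y))
    return pd.DataFrame(rows, columns=["population", "x", "y"])


def simulate_read_counts(dataset: GenotypeDataset, truth: TruthRecord,
                         mean_depth: float | None = None,
                         seed: int | None = None) -> ReadCountTable:
    """Sample per-SNP reference/alternate read depths.

    Depth is Poisson(``mean_depth``); alternate reads are binomial with
    the individual's true allele dosage fraction, so ordinary
    heterozygotes are balanced (p = 0.5) and collapsed paralogs are
    skewed (p in {1/4, 1/2, 3/4}).
    """
    if mean_depth is None:
        mean_depth = 40.0
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    depth = rng.poisson(mean_depth, size=dataset.genotypes.shape)
    alt = rng.binomial(depth, truth.alt_fraction)
    return ReadCountTable(ref=depth - alt, alt=alt)


def export_dataset(dataset: GenotypeDataset, truth: TruthRecord,
                   outdir: str | os.PathLike,
                   counts: ReadCountTable | None = None) -> dict[str, str]:
    """Write VCF + popmap + coordinates + truth tables; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "popmap": os.path.join(outdir, "popmap.tsv"),
        "coords": os.path.join(outdir, "coordinates.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    sio.write_vcf(paths["vcf"], dataset, counts=counts)
    sio.write_popmap(paths["popmap"], dataset.individuals)
    sio.write_coordinates(paths["coords"], truth.coords)
    with open(paths["truth"], "w") as fh:
        json.dump({
            "seed": truth.seed,
            "lineage_of_pop": truth.lineage_of_pop,
            "ancestry": {ind: {p: round(float(v), 6)
                               for p, v in row.items() if v > 0}
                         for ind, row in truth.ancestry.iterrows()},
            "paralog_tags": [int(t) for t in np.flatnonzero(truth.paralog_flags)],
            "pop_freqs": {p: np.round(f, 5).tolist()
                          for p, f in truth.pop_freqs.items()},
        }, fh)
    return paths


def wright_fisher_population(n_e: int = 100, sample_size: int = 50,
                             n_snps: int = 2000, n_chromosomes: int = 24,
                             generations: int = 8, seed: int = 0
                             ) -> GenotypeDataset:
    """Forward Wright-Fisher simulation of one ideal population.

    ``n_e`` diploids mate randomly for ``generations`` generations
    (chromosomes assort freely; within-chromosome recombination is
    irrelevant because only inter-chromosomal pairs are analysed
    downstream), after which ``sample_size`` individuals are sampled.
    Drift builds inter-chromosomal linkage disequilibrium of expectation
    ~1/(3 N_e), the signal the LD N_e estimator inverts - this generator
    is the ground-truth check for it.
    """
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.1, 0.9, n_snps)
    chrom = rng.integers(0, n_chromosomes, n_snps)
    H = (rng.random((2 * n_e, n_snps)) < p0).astype(np.int8)
    for _ in range(generations):
        H2 = np.empty_like(H)
        for i in range(n_e):
            for c, parent in enumerate(rng.integers(0, n_e, 2)):
                pick = rng.integers(0, 2, n_chromosomes)
                H2[2 * i + c] = np.where(pick[chrom] == 0, H[2 * parent],
                                         H[2 * parent + 1])
        H = H2
    idx = rng.choice(n_e, sample_size, replace=False)
    hap = np.stack([H[2 * idx], H[2 * idx + 1]], axis=2)
    snps = pd.DataFrame({"chrom": [f"chr{c + 1}" for c in chrom],
                         "pos": np.arange(1, n_snps + 1),
                         "tag": np.arange(n_snps), "tag_index": 0,
                         "ref": "A", "alt": "T"})
    individuals = pd.DataFrame({"id": [f"wf_{i:03d}" for i in range(sample_size)],
                                "population": "wf", "drainage": "wf",
                                "group": "wf"})
    return GenotypeDataset(genotypes=hap.sum(axis=2, dtype=np.int8), snps=snps,
                           individuals=individuals, haplotypes=hap)


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The default two-lineage study scenario with a Red-Lake-style pulse.

    The recipient ("minnesota_pop4") keeps one third of its individuals
    pure native; the remaining two thirds are hybrids at 46% source
    ("minnesota_pop1") ancestry, so the expected population-mean source
    ancestry is 2/3 * 0.46 ~= 0.31.
    """
    events = [AdmixtureEvent(recipient="minnesota_pop4", source="minnesota_pop1",
                             p_adm=0.46, fraction_pure_native=1.0 / 3.0)]
    params = dict(admixture_events=events, seed=seed)
    params.update(overrides)
    return ScenarioConfig(**params)
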