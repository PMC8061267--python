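"""Core in-memory containers for RAD-seq genotype data.

The package operates on three datasets:

``GenotypeDataset``
    Diploid genotypes at biallelic SNPs (alternate-allele dose 0/1/2,
    ``-1`` for missing) with per-SNP metadata (chromosome, 1-based
    position, RAD-tag id) and a population map.  An optional phase array
    carries the two haplotype alleles per SNP, as produced by haplotype-
    aware genotype callers.

``ReadCountTable``
    Per individual x SNP reference/alternate read depths, the input to
    HDplot paralog screening.

``MicrohapDataset``
    Per RAD tag, the phased multi-SNP haplotypes of each individual
    recoded as integer alleles of one multiallelic marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: columns required in the individual table
IND_COLUMNS = ("id", "population", "drainage", "group")
#: columns required in the SNP table
SNP_COLUMNS = ("chrom", "pos", "tag", "tag_index", "ref", "alt")


@dataclass
class GenotypeDataset:
    """Individuals x SNPs diploid genotype matrix with metadata.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_snps)`` int8 array of alternate-allele doses
        (0, 1, 2) with ``-1`` marking missing genotypes.
    snps
        Per-SNP metadata frame with columns ``chrom``, ``pos`` (1-based),
        ``tag`` (RAD-tag id), ``tag_index`` (within-tag SNP index),
        ``ref``, ``alt``.
    individuals
        Per-individual frame with columns ``id``, ``population``,
        ``drainage``, ``group`` (state-level grouping).
    haplotypes
        Optional ``(n_individuals, n_snps, 2)`` int8 phase array of
        haplotype alleles (0 = ref, 1 = alt, -1 = missing).
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    individuals: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (individuals x SNPs) array")
        n_ind, n_snp = self.genotypes.shape
        if len(self.individuals) != n_ind:
            raise ValueError(
                f"individual table has {len(self.individuals)} rows for {n_ind} genotype rows"
            )
        if len(self.snps) != n_snp:
            raise ValueError(f"SNP table has {len(self.snps)} rows for {n_snp} genotype columns")
        for col in IND_COLUMNS:
            if col not in self.individuals.columns:
                raise ValueError(f"individual table missing column {col!r}")
        for col in SNP_COLUMNS:
            if col not in self.snps.columns:
                raise ValueError(f"SNP table missing column {col!r}")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (n_ind, n_snp, 2):
                raise ValueError("haplotypes must have shape (n_individuals, n_snps, 2)")
        self.snps = self.snps.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.individuals["population"]))

    def pop_mask(self, population: str) -> np.ndarray:
        mask = (self.individuals["population"] == population).to_numpy()
        if not mask.any():
            raise KeyError(f"no individuals in population {population!r}")
        return mask

    # -- summaries ------------------------------------------------------
    def called_mask(self) -> np.ndarray:
        """Boolean (individuals x SNPs) mask of non-missing genotypes."""
        return self.genotypes != MISSING

    def allele_counts(self, ind_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (alt allele count, called gene-copy count) over ``ind_mask``."""
        g = self.genotypes if ind_mask is None else self.genotypes[ind_mask]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def allele_freq(self, ind_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP alternate-allele frequency (NaN where nothing called)."""
        alt, copies = self.allele_counts(ind_mask)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)

    def minor_allele_count(self) -> np.ndarray:
        alt, copies = self.allele_counts()
        return np.minimum(alt, copies - alt)

    def minor_allele_freq(self, ind_mask: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_freq(ind_mask)
        return np.minimum(p, 1.0 - p)

    # -- subsetting -----------------------------------------------------
    def take(self, ind_idx: np.ndarray | None = None, snp_idx: np.ndarray | None = None
             ) -> "GenotypeDataset":
        """Return a new dataset restricted to the given individual / SNP indices.

        Index arrays may be boolean masks or integer indices; ``None``
        keeps the axis untouched.
        """
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        if ind_idx.dtype == bool:
            ind_idx = np.flatnonzero(ind_idx)
        if snp_idx.dtype == bool:
            snp_idx = np.flatnonzero(snp_idx)
        hap = None
        if self.haplotypes is not None:
            hap = self.haplotypes[np.ix_(ind_idx, snp_idx)]
        return GenotypeDataset(
            genotypes=self.genotypes[np.ix_(ind_idx, snp_idx)],
            snps=self.snps.iloc[snp_idx],
            individuals=self.individuals.iloc[ind_idx],
            haplotypes=hap,
        )

    def sorted_by_position(self) -> "GenotypeDataset":
        """SNPs sorted by (chromosome, position); stable for ties."""
        order = self.snps.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        return self.take(snp_idx=order)

    def copy(self) -> "GenotypeDataset":
        return replace(
            self,
            genotypes=self.genotypes.copy(),
            snps=self.snps.copy(),
            individuals=self.individuals.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes.copy(),
        )


@dataclass
class ReadCountTable:
    """Reference / alternate read depths per individual x SNP."""

    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref and alt read matrices must share a shape")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt


@dataclass
class MicrohapTag:
    """One RAD tag as a multiallelic microhaplotype marker.

    ``alleles`` holds the observed haplotype strings over the tag's SNP
    alleles ("0"/"1" per SNP, in within-tag order); the integer allele
    code of a haplotype is its index in this list (dense ``0..k-1``, in
    order of first observation).  ``genos`` is ``(n_individuals, 2)``
    with ``-1`` for missing.
    """

    tag: int
    chrom: str
    pos: int
    alleles: list[str]
    genos: np.ndarray

    def __post_init__(self) -> None:
        self.genos = np.asarray(self.genos, dtype=np.int16)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def allele_length(self) -> int:
        return len(self.alleles[0]) if self.alleles else 0

    def code_distances(self) -> np.ndarray:
        """Hamming distance matrix between the tag's haplotype alleles."""
        k = self.n_alleles
        arr = np.array([[int(c) for c in a] for a in self.alleles], dtype=np.int8)
        return (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(np.int32)

    def allele_freqs(self, ind_mask: np.ndarray | None = None) -> np.ndarray:
        g = self.genos if ind_mask is None else self.genos[ind_mask]
        flat = g[g != MISSING]
        counts = np.bincount(flat, minlength=self.n_alleles).astype(float)
        total = counts.sum()
        return counts / total if total > 0 else counts


@dataclass
class MicrohapDataset:
    """Microhaplotype genotypes for a set of tags over shared individuals."""

    tags: list[MicrohapTag]
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        for col in IND_COLUMNS:
            if col not in self.individuals.columns:
                raise ValueError(f"individual table missing column {col!r}")
        n = len(self.individuals)
        for t in self.tags:
            if t.genos.shape != (n, 2):
                raise ValueError(f"tag {t.tag}: genotype block shape {t.genos.shape} != ({n}, 2)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.individuals["population"]))

    def pop_mask(self, population: str) -> np.ndarray:
        mask = (self.individuals["population"] == population).to_numpy()
        if not mask.any():
            raise KeyError(f"no individuals in population {population!r}")
        return mask

    def sorted_by_position(self) -> "MicrohapDataset":
        order = sorted(range(len(self.tags)), key=lambda i: (self.tags[i].chrom, self.tags[i].pos))
        return MicrohapDataset(tags=[self.tags[i] for i in order], individuals=self.individuals)

    def take_tags(self, keep: list[int] | np.ndarray) -> "MicrohapDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MicrohapDataset(tags=[self.tags[i] for i in keep], individuals=self.individuals)
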