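"""Genotype, individual, and locus quality filters.

The filter chain mirrors standard RAD-seq practice for population-level
datasets: drop poorly genotyped individuals, then poorly genotyped or
near-monomorphic SNPs (minor-allele count), screen collapsed paralogs
with HDplot, and branch into (A) a single-SNP dataset (highest-MAF SNP
per tag, F_IS filter) and (B) a microhaplotype dataset (phased multi-SNP
alleles per tag, allele-count and F_IS filters).

HDplot statistics per SNP:

* ``H`` - proportion of genotyped individuals that are heterozygous;
* ``D`` - heterozygote read-ratio deviation, ``(sum_ref - sum_alt) /
  sqrt(sum_ref + sum_alt)`` over reads of heterozygous individuals, a
  z-score against balanced binomial sampling.

A tag is flagged as a putative collapsed duplicate when any of its SNPs
has ``H > 0.5`` or ``|D| > 7``; flags lift to whole tags because
duplication is a tag-level artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import (MISSING, GenotypeDataset, MicrohapDataset, MicrohapTag,
                       ReadCountTable)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# missingness / MAC
# ---------------------------------------------------------------------------

def filter_missingness(ds: GenotypeDataset, ind_rate: float = 0.8,
                       snp_rate: float = 0.8, mac: int = 3
                       ) -> tuple[GenotypeDataset, dict]:
    """Drop individuals genotyped at <= ``ind_rate`` of SNPs, then SNPs
    genotyped in <= ``snp_rate`` of the remaining individuals or with
    minor-allele count below ``mac``.

    One recompute pass, individuals first: a SNP whose minor-allele
    count drops below ``mac`` after an individual is removed is dropped.
    Returns the filtered dataset and a report of the counts removed.
    """
    if ds.n_individuals == 0 or ds.n_snps == 0:
        raise ValueError("empty dataset")
    called = ds.called_mask()
    ind_ok = called.mean(axis=1) > ind_rate
    if not ind_ok.any():
        raise ValueError("all individuals removed by the genotype-rate filter")
    ds2 = ds.take(ind_idx=ind_ok)
    called2 = ds2.called_mask()
    snp_ok = called2.mean(axis=0) > snp_rate
    mac_ok = ds2.minor_allele_count() >= mac
    keep = snp_ok & mac_ok
    report = {
        "individuals_in": ds.n_individuals,
        "individuals_dropped": int((~ind_ok).sum()),
        "snps_in": ds.n_snps,
        "snps_dropped_rate": int((~snp_ok).sum()),
        "snps_dropped_mac": int((snp_ok & ~mac_ok).sum()),
        "snps_out": int(keep.sum()),
    }
    logger.info("missingness filter: %(individuals_dropped)d individuals, "
                "%(snps_dropped_rate)d low-rate + %(snps_dropped_mac)d low-MAC SNPs "
                "removed", report)
    return ds2.take(snp_idx=keep), report


def loose_prefilter(ds: GenotypeDataset, presence: float = 0.05,
                    maf: float = 0.005) -> GenotypeDataset:
    """Optional caller-style loose pre-filter: SNPs present in more than
    ``presence`` of individuals and with MAF above ``maf``.  Off by
    default in the pipeline; synthetic data does not need it."""
    called = ds.called_mask().mean(axis=0) > presence
    freq_ok = ds.minor_allele_freq() > maf
    return ds.take(snp_idx=called & np.nan_to_num(freq_ok, nan=0.0).astype(bool))


# ---------------------------------------------------------------------------
# HDplot
# ---------------------------------------------------------------------------

@dataclass
class HDplotStat:
    """Per-SNP HDplot table plus tag-level duplicate flags."""

    per_snp: pd.DataFrame        # columns: tag, H, D, n_het, flagged
    flagged_tags: np.ndarray     # tag ids flagged as putative duplicates

    def tag_flag_mask(self, tags: np.ndarray) -> np.ndarray:
        return np.isin(tags, self.flagged_tags)


def hdplot(counts: ReadCountTable, ds: GenotypeDataset,
           max_h: float = 0.5, max_abs_d: float = 7.0) -> HDplotStat:
    """HDplot paralog screen.

    ``H`` and ``D`` are computed per SNP; a tag is flagged when any of
    its SNPs exceeds either bound.  SNPs with no heterozygotes (D
    undefined) pass the D criterion by convention and are logged.
    """
    if counts.ref.shape != ds.genotypes.shape:
        raise ValueError("read-count table does not match the genotype matrix")
    g = ds.genotypes
    called = g != MISSING
    het = g == 1
    n_called = called.sum(axis=0)
    n_het = het.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    sum_ref = np.where(het, counts.ref, 0).sum(axis=0).astype(float)
    sum_alt = np.where(het, counts.alt, 0).sum(axis=0).astype(float)
    total = sum_ref + sum_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(total > 0, (sum_ref - sum_alt) / np.sqrt(np.maximum(total, 1)), 0.0)
    undefined = n_het == 0
    if undefined.any():
        logger.info("hdplot: %d SNPs without heterozygotes; D undefined, "
                    "passing by convention", int(undefined.sum()))
    snp_flag = (H > max_h) | (np.abs(D) > max_abs_d)
    per_snp = pd.DataFrame({
        "tag": ds.snps["tag"].to_numpy(),
        "H": H, "D": D, "n_het": n_het, "flagged": snp_flag,
    })
    flagged_tags = np.unique(per_snp.loc[per_snp["flagged"], "tag"].to_numpy())
    return HDplotStat(per_snp=per_snp, flagged_tags=flagged_tags)


def drop_flagged_tags(ds: GenotypeDataset, stat: HDplotStat) -> GenotypeDataset:
    """Remove every SNP of each HDplot-flagged tag."""
    keep = ~stat.tag_flag_mask(ds.snps["tag"].to_numpy())
    return ds.take(snp_idx=keep)


# ---------------------------------------------------------------------------
# one SNP per tag, F_IS
# ---------------------------------------------------------------------------

def select_one_snp_per_tag(ds: GenotypeDataset) -> GenotypeDataset:
    """Keep, per tag, the SNP with the highest minor allele frequency;
    on ties, the SNP with the lowest within-tag index."""
    maf = np.nan_to_num(ds.minor_allele_freq(), nan=-1.0)
    snps = ds.snps
    keep = []
    for _, grp in snps.groupby("tag", sort=False):
        idx = grp.sort_values("tag_index", kind="stable").index.to_numpy()
        keep.append(idx[np.argmax(maf[idx])])  # argmax takes the first max
    keep = np.sort(np.asarray(keep))
    return ds.take(snp_idx=keep)


def snp_fis(ds: GenotypeDataset) -> np.ndarray:
    """Per-SNP global F_IS = 1 - Ho/He (unbiased He); NaN where monomorphic."""
    g = ds.genotypes
    called = g != MISSING
    n = called.sum(axis=0).astype(float)
    het = (g == 1).sum(axis=0)
    p = ds.allele_freq()
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        he = np.where(n > 0, (2 * n / np.maximum(2 * n - 1, 1)) * 2 * p * (1 - p), np.nan)
        return np.where(he > 0, 1.0 - ho / he, np.nan)


def filter_fis(ds: GenotypeDataset, max_fis: float = 0.5) -> GenotypeDataset:
    """Drop SNPs with global F_IS above ``max_fis`` (monomorphic loci pass)."""
    fis = snp_fis(ds)
    keep = ~(fis > max_fis)
    return ds.take(snp_idx=keep)


def microhap_fis(mh: MicrohapDataset) -> np.ndarray:
    """Per-tag global F_IS from multiallelic haplotype genotypes."""
    out = np.full(mh.n_tags, np.nan)
    for t, tag in enumerate(mh.tags):
        genos = tag.genos
        called = (genos != MISSING).all(axis=1)
        n = int(called.sum())
        if n == 0:
            continue
        g = genos[called]
        ho = float((g[:, 0] != g[:, 1]).mean())
        freqs = np.bincount(g.ravel(), minlength=tag.n_alleles) / (2 * n)
        he = (2 * n / (2 * n - 1)) * (1.0 - np.sum(freqs ** 2)) if n > 1 else 0.0
        if he > 0:
            out[t] = 1.0 - ho / he
    return out


def filter_microhap(mh: MicrohapDataset, max_fis: float = 0.5,
                    max_alleles: int = 10) -> MicrohapDataset:
    """Drop tags with more than ``max_alleles`` haplotype alleles or with
    F_IS above ``max_fis``."""
    fis = microhap_fis(mh)
    keep = [t for t in range(mh.n_tags)
            if mh.tags[t].n_alleles <= max_alleles and not (fis[t] > max_fis)]
    return mh.take_tags(keep)


# ---------------------------------------------------------------------------
# microhaplotypes
# ---------------------------------------------------------------------------

def build_microhaplotypes(ds: GenotypeDataset,
                          tag_whitelist: np.ndarray | None = None
                          ) -> MicrohapDataset:
    """Assemble per-tag microhaplotypes from the phased dataset.

    ``ds`` should hold the individuals and SNPs that survived the
    missingness and HDplot filters (before one-SNP-per-tag selection).
    Each individual's two haplotypes at a tag are the concatenation of
    its phased alleles at the tag's SNPs; a haplotype containing any
    missing genotype is missing.  Alleles are coded by order of first
    observation (individual order, haplotype 0 before haplotype 1).
    """
    if ds.haplotypes is None:
        raise ValueError("phase information required to build microhaplotypes")
    snps = ds.snps
    tags_out: list[MicrohapTag] = []
    for tag_id, grp in snps.groupby("tag", sort=False):
        if tag_whitelist is not None and tag_id not in tag_whitelist:
            continue
        idx = grp.sort_values("tag_index", kind="stable").index.to_numpy()
        block = ds.haplotypes[:, idx, :]            # (n, k, 2)
        codes: dict[str, int] = {}
        alleles: list[str] = []
        genos = np.full((ds.n_individuals, 2), MISSING, dtype=np.int16)
        for i in range(ds.n_individuals):
            for h in (0, 1):
                alleles_h = block[i, :, h]
                if (alleles_h == MISSING).any():
                    continue
                key = "".join(str(int(a)) for a in alleles_h)
                if key not in codes:
                    codes[key] = len(alleles)
                    alleles.append(key)
                genos[i, h] = codes[key]
        # a haplotype pair is only usable if both sides are called
        half = (genos == MISSING).any(axis=1)
        genos[half] = MISSING
        tags_out.append(MicrohapTag(tag=int(tag_id), chrom=str(grp["chrom"].iloc[0]),
                                    pos=int(grp["pos"].min()), alleles=alleles,
                                    genos=genos))
    return MicrohapDataset(tags=tags_out, individuals=ds.individuals.copy())


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    """Everything the downstream stages need from the filter chain."""

    single_snp: GenotypeDataset
    microhaps: MicrohapDataset | None
    hdplot: HDplotStat | None
    report: dict


def run_filter_chain(ds: GenotypeDataset, counts: ReadCountTable | None = None,
                     ind_rate: float = 0.8, snp_rate: float = 0.8, mac: int = 3,
                     max_h: float = 0.5, max_abs_d: float = 7.0,
                     max_fis: float = 0.5, max_alleles: int = 10,
                     build_haps: bool = True) -> FilterResult:
    """Missingness -> MAC -> HDplot -> (one-SNP + F_IS | microhaps + filters)."""
    filtered, report = filter_missingness(ds, ind_rate=ind_rate,
                                          snp_rate=snp_rate, mac=mac)
    stat = None
    if counts is not None:
        kept_ids = set(filtered.individuals["id"])
        ind_keep = ds.individuals["id"].isin(kept_ids).to_numpy()
        snp_keep = _index_of(ds.snps, filtered.snps)
        sub_counts = ReadCountTable(ref=counts.ref[np.ix_(np.flatnonzero(ind_keep), snp_keep)],
                                    alt=counts.alt[np.ix_(np.flatnonzero(ind_keep), snp_keep)])
        stat = hdplot(sub_counts, filtered, max_h=max_h, max_abs_d=max_abs_d)
        filtered = drop_flagged_tags(filtered, stat)
        report["tags_flagged_hdplot"] = len(stat.flagged_tags)
    single = filter_fis(select_one_snp_per_tag(filtered), max_fis=max_fis)
    report["snps_single"] = single.n_snps
    mh = None
    if build_haps and filtered.haplotypes is not None:
        mh = filter_microhap(build_microhaplotypes(filtered),
                             max_fis=max_fis, max_alleles=max_alleles)
        report["tags_microhap"] = mh.n_tags
    logger.info("filter chain: %d individuals, %d single SNPs, %s microhap tags",
                single.n_individuals, single.n_snps,
                mh.n_tags if mh is not None else "no")
    return FilterResult(single_snp=single, microhaps=mh, hdplot=stat, report=report)


def _index_of(full: pd.DataFrame, subset: pd.DataFrame) -> np.ndarray:
    """Positions of ``subset`` SNP rows inside ``full`` (by chrom/pos/tag_index)."""
    key_full = pd.MultiIndex.from_frame(full[["chrom", "pos", "tag", "tag_index"]])
    key_sub = pd.MultiIndex.from_frame(subset[["chrom", "pos", "tag", "tag_index"]])
    locs = key_full.get_indexer(key_sub)
    if (locs < 0).any():
        raise ValueError("subset SNPs not found in the original table")
    return locs
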