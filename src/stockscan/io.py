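"""Reading and writing the on-disk formats: VCF 4.2, popmap, coordinates.

Genotypes travel as VCF 4.2 with phased GT, optional AD (per-allele read
depth) and a ``TID`` INFO key carrying the RAD-tag id, so that tag
membership survives the round trip.  The population map is a four-column
TSV (individual, population, drainage, state-level group) and the
coordinates file a three-column TSV (population, x, y).

VCF parsing goes through :mod:`cyvcf2`; the writer is a small text
emitter (one record per SNP) because the package controls the full
header and needs nothing beyond GT/AD/TID.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datasets import MISSING, GenotypeDataset, ReadCountTable


def write_vcf(path: str | os.PathLike, ds: GenotypeDataset,
              counts: ReadCountTable | None = None,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a phased VCF 4.2 with GT (+ AD when read counts are given)."""
    snps = ds.snps
    chroms = list(dict.fromkeys(snps["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stockscan\n")
        for c in chroms:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=TID,Number=1,Type=Integer,Description="RAD tag id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if counts is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
                     '"Read depth per allele">\n')
        sample_ids = list(ds.individuals["id"])
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        fmt = "GT:AD" if counts is not None else "GT"
        hap = ds.haplotypes
        for j in range(ds.n_snps):
            row = snps.iloc[j]
            fields = [str(row["chrom"]), str(int(row["pos"])),
                      f"tag{int(row['tag'])}_{int(row['tag_index'])}",
                      str(row["ref"]), str(row["alt"]), ".", "PASS",
                      f"TID={int(row['tag'])}", fmt]
            for i in range(ds.n_individuals):
                if hap is not None:
                    a, b = hap[i, j]
                    gt = "." if a == MISSING else f"{a}|{b}"
                    if a == MISSING:
                        gt = ".|."
                else:
                    dose = ds.genotypes[i, j]
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(dose), "./.")
                if counts is not None:
                    gt = f"{gt}:{counts.ref[i, j]},{counts.alt[i, j]}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | os.PathLike, popmap: pd.DataFrame
             ) -> tuple[GenotypeDataset, ReadCountTable | None]:
    """Read a VCF into a :class:`GenotypeDataset` (+ read counts when AD present).

    ``popmap`` must cover every sample in the VCF; samples absent from the
    popmap raise, since a silent drop would skew every downstream rate.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pm = popmap.set_index("id")
    missing_samples = [s for s in samples if s not in pm.index]
    if missing_samples:
        raise ValueError(f"samples missing from popmap: {missing_samples[:5]}")

    doses, haps, meta = [], [], []
    ref_counts, alt_counts = [], []
    has_ad = False
    any_unphased = False
    for var in vcf:
        gts = np.asarray(var.genotypes, dtype=np.int16)  # (n, 3): a0, a1, phased
        a = gts[:, 0].astype(np.int8)
        b = gts[:, 1].astype(np.int8)
        called = (a >= 0) & (b >= 0)
        if not np.all(gts[called, 2] == 1):
            any_unphased = True
        dose = np.where(called, a + b, MISSING).astype(np.int8)
        doses.append(dose)
        haps.append(np.stack([np.where(called, a, MISSING),
                              np.where(called, b, MISSING)], axis=1).astype(np.int8))
        tid = var.INFO.get("TID")
        tag_index = 0
        if var.ID and "_" in str(var.ID):
            try:
                tag_index = int(str(var.ID).rsplit("_", 1)[1])
            except ValueError:
                tag_index = 0
        meta.append((var.CHROM, var.POS, int(tid) if tid is not None else len(meta),
                     tag_index, var.REF, var.ALT[0] if var.ALT else "N"))
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            has_ad = True
            ad = np.asarray(ad)
            ref_counts.append(np.maximum(ad[:, 0], 0))
            alt_counts.append(np.maximum(ad[:, 1], 0))
    if not doses:
        raise ValueError(f"no variant records in {path}")

    snps = pd.DataFrame(meta, columns=["chrom", "pos", "tag", "tag_index", "ref", "alt"])
    individuals = pd.DataFrame({
        "id": samples,
        "population": [pm.loc[s, "population"] for s in samples],
        "drainage": [pm.loc[s, "drainage"] for s in samples],
        "group": [pm.loc[s, "group"] for s in samples],
    })
    ds = GenotypeDataset(
        genotypes=np.stack(doses, axis=1),
        snps=snps,
        individuals=individuals,
        haplotypes=None if any_unphased else np.stack(haps, axis=1),
    )
    counts = None
    if has_ad:
        counts = ReadCountTable(ref=np.stack(ref_counts, axis=1),
                                alt=np.stack(alt_counts, axis=1))
    return ds, counts


def write_popmap(path: str | os.PathLike, individuals: pd.DataFrame) -> None:
    individuals[["id", "population", "drainage", "group"]].to_csv(
        path, sep="\t", index=False)


def read_popmap(path: str | os.PathLike) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "population", "drainage", "group"}
    if not required.issubset(pm.columns):
        raise ValueError(f"popmap must have columns {sorted(required)}")
    return pm


def write_coordinates(path: str | os.PathLike, coords: pd.DataFrame) -> None:
    coords[["population", "x", "y"]].to_csv(path, sep="\t", index=False)


def read_coordinates(path: str | os.PathLike) -> pd.DataFrame:
    coords = pd.read_csv(path, sep="\t")
    if not {"population", "x", "y"}.issubset(coords.columns):
        raise ValueError("coordinates file must have columns population, x, y")
    return coords
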