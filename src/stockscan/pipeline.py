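"""End-to-end pipeline: simulate -> filter -> diversity -> structure ->
boundaries -> coancestry -> scan, from one configuration.

Each stage writes its artifact into the output directory and logs one
structured line with input/output dimensions; a manifest JSON records
the package version, seed, every parameter value and a checksum per
artifact, so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__, boundaries, coancestry, diversity, genomescan
from . import io as sio
from . import qcfilter, simdata, structure

logger = logging.getLogger("stockscan.pipeline")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's printed values."""

    outdir: str = "stockscan_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    filter: bool = True
    diversity: bool = True
    structure: bool = True
    boundaries: bool = True
    coancestry: bool = True
    scan: bool = True
    # inputs when not simulating
    vcf: str | None = None
    popmap: str | None = None
    coordinates: str | None = None
    # scenario (used when simulate=True); None -> package default scenario
    scenario: dict = field(default_factory=dict)
    # filter parameters
    ind_rate: float = 0.8
    snp_rate: float = 0.8
    mac: int = 3
    hdplot_max_h: float = 0.5
    hdplot_max_abs_d: float = 7.0
    max_fis: float = 0.5
    max_alleles: int = 10
    loose_prefilter: bool = False
    # diversity / Ne
    pcrit: float = 0.05
    # structure
    n_permutations: int = 10_000
    n_bootstraps: int = 10_000
    # boundaries
    monmonier_runs: int = 3
    monmonier_relax: float = 0.05
    # coancestry
    tukey_alpha: float = 0.001
    # scan
    window: int = 500_000
    step: int = 100_000
    scan_reps1: int = 1000
    scan_reps2: int = 10_000
    scan_gate: float = 90.0
    scan_call: float = 99.0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in dependency order; returns the manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, path: str) -> str:
        artifacts[name] = path
        return path

    truth = None
    counts = None
    if config.simulate:
        scen = simdata.default_scenario(seed=config.seed, **config.scenario)
        ds, truth = simdata.simulate_metapopulation(scen)
        counts = simdata.simulate_read_counts(ds, truth, mean_depth=scen.mean_depth)
        paths = simdata.export_dataset(ds, truth, config.outdir, counts=counts)
        for k, p in paths.items():
            save(f"sim_{k}", p)
        coords = truth.coords
        logger.info("simulate: %d individuals x %d SNPs (%d tags)",
                    ds.n_individuals, ds.n_snps, ds.snps["tag"].nunique())
    else:
        if not (config.vcf and config.popmap):
            raise FileNotFoundError("vcf and popmap inputs required when "
                                    "the simulate stage is disabled")
        pm = sio.read_popmap(config.popmap)
        ds, counts = sio.read_vcf(config.vcf, pm)
        coords = sio.read_coordinates(config.coordinates) if config.coordinates else None
        logger.info("load: %d individuals x %d SNPs", ds.n_individuals, ds.n_snps)

    if config.filter:
        if config.loose_prefilter:
            ds = qcfilter.loose_prefilter(ds)
        res = qcfilter.run_filter_chain(
            ds, counts, ind_rate=config.ind_rate, snp_rate=config.snp_rate,
            mac=config.mac, max_h=config.hdplot_max_h,
            max_abs_d=config.hdplot_max_abs_d, max_fis=config.max_fis,
            max_alleles=config.max_alleles)
        single, mh = res.single_snp, res.microhaps
        with open(save("filter_report", os.path.join(config.outdir, "filter_report.json")), "w") as fh:
            json.dump(res.report, fh, indent=1)
        sio.write_vcf(save("filtered_vcf", os.path.join(config.outdir, "filtered.vcf")), single)
    else:
        missing_rate = float((ds.genotypes < 0).mean())
        if missing_rate > 0:
            logger.warning("filtering disabled with %.1f%% missing genotypes; "
                           "downstream statistics use pairwise-complete data",
                           100 * missing_rate)
        single = qcfilter.select_one_snp_per_tag(ds)
        mh = (qcfilter.build_microhaplotypes(ds) if ds.haplotypes is not None else None)

    if config.diversity:
        table = diversity.diversity_table(single)
        ne = diversity.ne_table(single, pcrit=config.pcrit)
        table = table.merge(ne, on="population")
        table.to_csv(save("diversity", os.path.join(config.outdir, "diversity.tsv")),
                     sep="\t", index=False)
        logger.info("diversity: %d populations", len(table))

    if config.structure:
        theta, pvals = structure.pairwise_fst(single, n_perm=0)
        theta.to_csv(save("fst_matrix", os.path.join(config.outdir, "pairwise_fst.tsv")),
                     sep="\t")
        grouping = {pop: single.individuals.loc[single.pop_mask(pop), "group"].iloc[0]
                    for pop in single.populations()}
        am = structure.amova(single, grouping)
        am.table.to_csv(save("amova", os.path.join(config.outdir, "amova.tsv")),
                        sep="\t", index=False)
        tree = structure.nj_bootstrap(mh if mh is not None else single,
                                      n_boot=config.n_bootstraps, seed=config.seed)
        with open(save("nj_tree", os.path.join(config.outdir, "nj_tree.nwk")), "w") as fh:
            fh.write(tree.newick + "\n")
        logger.info("structure: %d pops, AMOVA percents %s",
                    len(theta), np.round(am.table["percent"].to_numpy(), 2))

    if config.boundaries and coords is not None:
        D = boundaries.edwards_matrix(single)
        scaled = boundaries.pcoa_first_axis(D)
        net = boundaries.delaunay_network(coords, scaled)
        net = boundaries.monmonier(net, n_runs=config.monmonier_runs,
                                   threshold_relax=config.monmonier_relax)
        net.boundary_frame().to_csv(
            save("boundaries", os.path.join(config.outdir, "boundaries.tsv")),
            sep="\t", index=False)
        with open(save("boundary_report", os.path.join(config.outdir, "boundaries.json")), "w") as fh:
            json.dump({"threshold": net.threshold,
                       "converged_at_run": net.converged_at_run,
                       "n_boundaries": len(net.boundaries)}, fh, indent=1)
        logger.info("boundaries: %d traced, threshold %.4f",
                    len(net.boundaries), net.threshold)

    if config.coancestry and mh is not None:
        cm = coancestry.paint_coancestry(mh)
        cm.to_frame().to_csv(save("coancestry", os.path.join(config.outdir, "coancestry.csv")))
        stats = coancestry.coancestry_group_stats(cm)
        stats.per_population.rename("mean_intra_coancestry").to_csv(
            save("coancestry_stats", os.path.join(config.outdir, "coancestry_stats.tsv")),
            sep="\t")
        hsd = coancestry.tukey_hsd({"intra_basin": stats.intra_basin,
                                    "inter_basin": stats.inter_basin},
                                   alpha=config.tukey_alpha)
        hsd.to_csv(save("coancestry_hsd", os.path.join(config.outdir, "coancestry_hsd.tsv")),
                   sep="\t", index=False)
        _, newick = coancestry.cluster_coancestry(cm)
        with open(save("coancestry_tree", os.path.join(config.outdir, "coancestry_tree.nwk")), "w") as fh:
            fh.write(newick + "\n")
        logger.info("coancestry: %d individuals painted at %d tags (median)",
                    cm.n, int(np.median(cm.loci_used)))

    if config.scan:
        cfg = genomescan.ScanConfig(window=config.window, step=config.step,
                                    reps1=config.scan_reps1, reps2=config.scan_reps2,
                                    gate=config.scan_gate, call=config.scan_call)
        records, windows, regions = genomescan.genome_scan(single, config=cfg,
                                                           seed=config.seed)
        windows.to_csv(save("scan_windows", os.path.join(config.outdir, "scan_windows.tsv")),
                       sep="\t", index=False)
        genomescan.regions_to_bed(regions).to_csv(
            save("scan_regions", os.path.join(config.outdir, "scan_regions.bed")),
            sep="\t", index=False, header=False)
        logger.info("scan: %d windows, %d significant, %d regions",
                    len(windows), int(windows["significant"].sum()), len(regions))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "artifacts": {k: {"path": p, "sha256": _checksum(p)}
                      for k, p in artifacts.items()},
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
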