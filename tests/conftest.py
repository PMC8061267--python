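"""Shared fixtures: toy dataset builders and one mid-sized simulated run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import stockscan as ss
from stockscan.datasets import GenotypeDataset


def make_dataset(genotypes, populations, chrom=None, tag=None, pos=None,
                 haplotypes=None, drainage=None, group=None) -> GenotypeDataset:
    """Build a GenotypeDataset from plain lists (missing = -1)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, L = g.shape
    populations = list(populations)
    snps = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * L,
        "pos": pos if pos is not None else np.arange(1, L + 1),
        "tag": tag if tag is not None else np.arange(L),
        "tag_index": _tag_indices(tag, L),
        "ref": "A", "alt": "T",
    })
    individuals = pd.DataFrame({
        "id": [f"ind{i}" for i in range(n)],
        "population": populations,
        "drainage": drainage if drainage is not None else populations,
        "group": group if group is not None else populations,
    })
    hap = None
    if haplotypes is not None:
        hap = np.asarray(haplotypes, dtype=np.int8)
    return GenotypeDataset(genotypes=g, snps=snps, individuals=individuals,
                           haplotypes=hap)


def _tag_indices(tag, L):
    if tag is None:
        return [0] * L
    idx, seen = [], {}
    for t in tag:
        idx.append(seen.get(t, 0))
        seen[t] = idx[-1] + 1
    return idx


@pytest.fixture(scope="session")
def default_sim():
    """The default two-lineage stocked scenario (one shared realisation)."""
    cfg = ss.default_scenario(seed=11)
    ds, truth = ss.simulate_metapopulation(cfg)
    counts = ss.simulate_read_counts(ds, truth)
    return cfg, ds, truth, counts


@pytest.fixture(scope="session")
def filtered_sim(default_sim):
    cfg, ds, truth, counts = default_sim
    res = ss.run_filter_chain(ds, counts)
    return cfg, truth, res
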