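"""Published 23-population walleye survey tables and their summary arithmetic.

The package ships, as plain TSV data, the headline tables of a published
RAD-seq survey of walleye across Wisconsin and Minnesota: per-population
diversity/N_e/co-ancestry summaries, the pairwise F_ST matrix, and the
three hierarchical AMOVA component tables.  The functions here exercise
the package's reporting code paths on those real inputs - state-level
means of intra-population co-ancestry and pairwise F_ST,
percent-of-variation reconstruction from AMOVA components, and column
means - which serve as fixed reference points for the test suite and
the acceptance script.

Population 15 (St. Louis River) is a border water: it groups with
Wisconsin in pairwise-F_ST summaries but belongs to neither state for
state-level column means, mirroring how the survey reported it.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .structure import variance_percentages

_WISCONSIN_IDS = list(range(1, 15))          # state == Wisconsin
_WISCONSIN_FST_IDS = list(range(1, 16))      # border water grouped with WI
_MINNESOTA_IDS = list(range(16, 24))


def _data_path(name: str):
    return resources.files("stockscan").joinpath("data", name)


def population_summary() -> pd.DataFrame:
    """Per-population survey summary (diversity, N_e, co-ancestry)."""
    with resources.as_file(_data_path("walleye_population_summary.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    for col in ("ne", "ne_ci_low", "ne_ci_high"):
        df[col] = df[col].replace("Infinite", np.inf).astype(float)
    return df


def pairwise_fst_matrix() -> pd.DataFrame:
    """Symmetric 23 x 23 pairwise F_ST matrix (diagonal zero)."""
    with resources.as_file(_data_path("walleye_pairwise_fst.tsv")) as p:
        long = pd.read_csv(p, sep="\t")
    ids = sorted(set(long["pop_i"]) | set(long["pop_j"]))
    M = pd.DataFrame(0.0, index=ids, columns=ids)
    for row in long.itertuples(index=False):
        M.loc[row.pop_i, row.pop_j] = row.fst
        M.loc[row.pop_j, row.pop_i] = row.fst
    return M


def amova_components(analysis: str = "all") -> pd.DataFrame:
    """AMOVA table (df, SSQ, variance component) for one analysis:
    ``all``, ``wisconsin`` or ``minnesota``."""
    with resources.as_file(_data_path("walleye_amova.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    sub = df[df["analysis"] == analysis].reset_index(drop=True)
    if sub.empty:
        raise KeyError(f"unknown AMOVA analysis {analysis!r}")
    return sub


def amova_percentages(analysis: str = "all") -> np.ndarray:
    """Percent of variation per stratum reconstructed from the published
    variance components."""
    comp = amova_components(analysis)["variance"].to_numpy()
    return variance_percentages(comp)


def state_mean_intra_coancestry() -> dict[str, float]:
    """Mean intra-population co-ancestry score per state."""
    df = population_summary()
    return {
        "wisconsin": float(df.loc[df["id"].isin(_WISCONSIN_IDS), "coancestry"].mean()),
        "minnesota": float(df.loc[df["id"].isin(_MINNESOTA_IDS), "coancestry"].mean()),
    }


def _within_state_values(M: pd.DataFrame, ids: list[int]) -> np.ndarray:
    vals = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            vals.append(float(M.loc[ids[a], ids[b]]))
    return np.asarray(vals)


def within_state_fst_summary() -> dict[str, dict[str, float]]:
    """Mean / min / max pairwise F_ST within each state (border water
    grouped with Wisconsin)."""
    M = pairwise_fst_matrix()
    out = {}
    for state, ids in (("wisconsin", _WISCONSIN_FST_IDS), ("minnesota", _MINNESOTA_IDS)):
        v = _within_state_values(M, ids)
        out[state] = {"mean": float(v.mean()), "min": float(v.min()),
                      "max": float(v.max()), "n_pairs": len(v)}
    return out


def between_state_fst_mean() -> float:
    """Mean pairwise F_ST for Wisconsin-vs-Minnesota comparisons."""
    M = pairwise_fst_matrix()
    vals = [float(M.loc[i, j]) for i in _WISCONSIN_FST_IDS for j in _MINNESOTA_IDS]
    return float(np.mean(vals))


def column_means() -> dict[str, float]:
    """Survey-wide means of the headline diversity columns and sample size."""
    df = population_summary()
    return {
        "he": float(df["he"].mean()),
        "ho": float(df["ho"].mean()),
        "ar": float(df["ar"].mean()),
        "n_sampled": float(df["n_sampled"].mean()),
    }
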