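"""Kernel-smoothed windowed differentiation scan with a bootstrap null.

Per-locus multi-population theta values are smoothed in sliding windows
(default 500 kb, step 100 kb, tiled from coordinate 1 per chromosome)
with Gaussian kernel weights w_i = exp(-d_i^2 / (2 sigma^2)) on the
distance d_i from the window centre (sigma defaults to a quarter of the
window, so +-2 sigma spans it).

Significance is a two-stage empirical bootstrap: for a window holding n
loci, n loci are drawn from the genome-wide pool without replacement
and their *plain* mean theta recorded; 1,000 such draws form the stage-1
null, and windows above its 90th percentile graduate to a fresh
10,000-draw stage.  A window is significant when its plain mean exceeds
the stage-2 99th percentile and it holds at least two loci.  Contiguous
significant windows merge into regions.

The null depends only on n, so draw distributions are cached per locus
count and reused across windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset
from .structure import per_locus_theta


@dataclass
class ScanConfig:
    window: int = 500_000
    step: int = 100_000
    sigma: float | None = None          # default window / 4
    reps1: int = 1000
    reps2: int = 10_000
    gate: float = 90.0
    call: float = 99.0
    min_loci: int = 2


def kernel_windows(records: pd.DataFrame, window: int = 500_000,
                   step: int = 100_000, sigma: float | None = None
                   ) -> pd.DataFrame:
    """Tile windows and compute kernel-weighted and plain mean theta.

    ``records`` needs columns chrom/pos/theta sorted by (chrom, pos).
    Windows are half-open [start, start+window) from coordinate 1 per
    chromosome; empty windows are emitted with ``n_loci = 0`` and NaN
    statistics.
    """
    if window < step:
        raise ValueError("window must be >= step (otherwise the tiling has gaps)")
    if sigma is None:
        sigma = window / 4.0
    out = []
    for chrom, grp in records.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        theta = grp["theta"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            order = np.argsort(pos, kind="stable")
            pos, theta = pos[order], theta[order]
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window
            center = start + window / 2.0
            lo, hi = np.searchsorted(pos, [start, end])
            n = hi - lo
            if n > 0:
                d = pos[lo:hi] - center
                w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
                weighted = float((w * theta[lo:hi]).sum() / w.sum())
                plain = float(theta[lo:hi].mean())
            else:
                weighted = plain = np.nan
            out.append({"chrom": chrom, "start": start, "end": end,
                        "center": center, "n_loci": int(n),
                        "weighted_theta": weighted, "mean_theta": plain})
            start += step
    cols = ["chrom", "start", "end", "center", "n_loci",
            "weighted_theta", "mean_theta"]
    return pd.DataFrame(out, columns=cols)


def bootstrap_significance(windows: pd.DataFrame, records: pd.DataFrame,
                           reps1: int = 1000, reps2: int = 10_000,
                           gate: float = 90.0, call: float = 99.0,
                           min_loci: int = 2, seed: int = 0) -> pd.DataFrame:
    """Attach bootstrap percentile, stage, and significance flags.

    The percentile is the share of null draws strictly below the
    window's plain mean theta, on a 0-100 scale; ``stage`` records the
    number of draws behind it (reps1 or reps2).
    """
    pool = records["theta"].to_numpy()
    L = len(pool)
    rng = np.random.default_rng(seed)
    null_cache: dict[tuple[int, int], np.ndarray] = {}

    def null_means(n: int, reps: int) -> np.ndarray:
        key = (n, reps)
        if key not in null_cache:
            if n > L:
                # pool smaller than the window: fall back to replacement
                import logging
                logging.getLogger(__name__).warning(
                    "window holds %d loci but the pool only %d; sampling "
                    "with replacement", n, L)
                draws = rng.integers(0, L, size=(reps, n))
                null_cache[key] = pool[draws].mean(axis=1)
            else:
                means = np.empty(reps)
                for rep in range(reps):
                    means[rep] = pool[rng.choice(L, size=n, replace=False)].mean()
                null_cache[key] = means
        return null_cache[key]

    win = windows.copy()
    pct = np.full(len(win), np.nan)
    stage = np.zeros(len(win), dtype=int)
    sig = np.zeros(len(win), dtype=bool)
    for k, row in enumerate(win.itertuples(index=False)):
        n = int(row.n_loci)
        if n < 1 or not np.isfinite(row.mean_theta):
            continue
        null1 = null_means(n, reps1)
        stage[k] = reps1
        pct[k] = 100.0 * float((null1 < row.mean_theta).mean())
        if row.mean_theta > np.percentile(null1, gate):
            null2 = null_means(n, reps2)
            stage[k] = reps2
            pct[k] = 100.0 * float((null2 < row.mean_theta).mean())
            if row.mean_theta > np.percentile(null2, call) and n >= min_loci:
                sig[k] = True
    win["percentile"] = pct
    win["stage"] = stage
    win["significant"] = sig
    return win


def merge_regions(windows: pd.DataFrame, records: pd.DataFrame | None = None
                  ) -> pd.DataFrame:
    """Merge overlapping/adjacent significant windows into regions.

    Regions never span chromosomes.  ``records`` (chrom/pos/theta), when
    given, fills ``n_distinct_loci`` per region.
    """
    sig = windows[windows["significant"]].sort_values(["chrom", "start"])
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        cur_start = cur_end = None
        n_win = 0
        for w in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, n_win = w.start, w.end, 1
            elif w.start <= cur_end:          # overlap or adjacency
                cur_end = max(cur_end, w.end)
                n_win += 1
            else:
                rows.append((chrom, cur_start, cur_end, n_win))
                cur_start, cur_end, n_win = w.start, w.end, 1
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end, n_win))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])
    if records is not None and len(regions):
        counts = []
        for r in regions.itertuples(index=False):
            m = ((records["chrom"] == r.chrom) & (records["pos"] >= r.start)
                 & (records["pos"] < r.end))
            counts.append(int(m.sum()))
        regions["n_distinct_loci"] = counts
    elif len(regions):
        regions["n_distinct_loci"] = np.nan
    else:
        regions["n_distinct_loci"] = pd.Series(dtype=float)
    return regions


def genome_scan(ds: GenotypeDataset, populations: list[str] | None = None,
                config: ScanConfig | None = None, seed: int = 0
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full scan: per-locus theta -> kernel windows -> bootstrap -> regions.

    Returns (records, windows, regions).
    """
    cfg = config or ScanConfig()
    records, _dropped = per_locus_theta(ds, populations)
    windows = kernel_windows(records, window=cfg.window, step=cfg.step,
                             sigma=cfg.sigma)
    windows = bootstrap_significance(windows, records, reps1=cfg.reps1,
                                     reps2=cfg.reps2, gate=cfg.gate,
                                     call=cfg.call, min_loci=cfg.min_loci,
                                     seed=seed)
    regions = merge_regions(windows, records)
    return records, windows, regions


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """Regions as BED (0-based half-open) columns chrom/start/end/name."""
    bed = regions.copy()
    bed["start"] = bed["start"] - 1        # 1-based inclusive -> 0-based
    bed["end"] = bed["end"] - 1
    bed["name"] = [f"region_{i + 1}" for i in range(len(bed))]
    return bed[["chrom", "start", "end", "name"]]


def manhattan_plot(records: pd.DataFrame, windows: pd.DataFrame, path: str) -> None:
    """Manhattan-style figure: per-locus theta with significant windows marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(records["chrom"]))
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += int(records.loc[records["chrom"] == c, "pos"].max()) + 1
    x = records["pos"].to_numpy() + np.array([offsets[c] for c in records["chrom"]])
    fig, ax = plt.subplots(figsize=(12, 3.5))
    ax.scatter(x, records["theta"], s=4, c="black", alpha=0.5)
    sig = windows[windows["significant"]]
    for w in sig.itertuples(index=False):
        x0 = offsets[w.chrom] + w.start
        ax.plot([x0, x0 + (w.end - w.start)], [w.mean_theta] * 2, c="red", lw=2)
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"per-locus $\theta$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
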