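"""Kernel-smoothed windowed F_ST scan with the two-stage bootstrap null.

Implants a divergent 1-Mb region into an otherwise exchangeable per-locus
theta landscape and shows the scan recovering it.
"""

import numpy as np
import pandas as pd

from stockscan.genomescan import (bootstrap_significance, kernel_windows,
                                  merge_regions)

rng = np.random.default_rng(5)
n_chrom, L = 24, 5000
chrom = np.sort(rng.integers(0, n_chrom, L))
pos = np.concatenate([np.sort(rng.integers(1, 10_000_000, (chrom == c).sum()))
                      for c in range(n_chrom)])
theta = rng.exponential(0.02, L)
implant = (chrom == 7) & (pos >= 4_000_000) & (pos < 5_000_000)
theta[implant] += 0.15
records = pd.DataFrame({"chrom": [f"chr{c + 1}" for c in chrom],
                        "pos": pos, "theta": theta})

windows = kernel_windows(records)                       # 500 kb / 100 kb step
windows = bootstrap_significance(windows, records, seed=5)
regions = merge_regions(windows, records)

occupied = windows[windows["n_loci"] > 0]
print(f"{len(windows)} windows, mean {occupied['n_loci'].mean():.1f} loci per "
      f"occupied window, {int(windows['significant'].sum())} significant")
print("\nmerged significant regions:")
print(regions.to_string(index=False))
# The implanted chr8:4.0-5.0 Mb stretch appears as a merged region; the
# few additional single-window regions are the ~1% false-positive rate the
# 99th-percentile bootstrap call implies.
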