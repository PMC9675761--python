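"""The statistical toolbox: exact tests, TE density controls, copy number.

Shows the tests used in TEMR enrichment analyses on small worked inputs:
the exact two-tailed binomial, Fisher's exact test by hypergeometric
enumeration, Welch's unequal-variance t-test, TE density with random-window
controls, and read-depth copy-number estimation for a multi-copy CNV.
"""

import numpy as np
import pandas as pd

from temrkit import (DepthProfile, binom_two_tailed, depth_copy_number,
                     fisher_exact_2x2, sample_control_windows, te_density, welch_t)

# 1 single-monomer vs 9 three-monomer chimeric Alus: is the imbalance real?
p = binom_two_tailed(1, 10, 0.5)
print(f"binomial(1 of 10 | p0=0.5), two-tailed: p = {p:.3f}")

# a strongly unbalanced 2x2 association table
print(f"Fisher (1,9 / 9,1): p = {fisher_exact_2x2(1, 9, 9, 1):.7f} "
      f"(= 202/184756 by enumeration)")

# TE density around events vs random control windows
rng = np.random.default_rng(1)
starts = np.sort(rng.choice(np.arange(0, 990_000, 400), 900, replace=False))
ann = pd.DataFrame([{"chrom": "chr1", "start": int(s), "end": int(s) + 300,
                     "family": "Alu"} for s in starts])
events = [("chr1", int(s) - 2000, int(s) + 2000) for s in starts[100:140]]
dens = [te_density(ev, ann, "Alu") for ev in events]
controls = sample_control_windows(100, {"chr1": 1_000_000}, ann, "Alu", seed=2)
res = welch_t(dens, controls)
print(f"Alu density, events vs controls: {np.mean(dens):.1f}% vs "
      f"{np.mean(controls):.1f}% (Welch t = {res['t']:.2f}, p = {res['p']:.3g})")

# read-depth copy number of a triplicated segment (diploid baseline CN = 2)
depth = np.full(3000, 30.0) + rng.normal(0, 1.0, 3000)
depth[1000:1200] *= 2.0                     # segment present in 4 copies
profile = DepthProfile(100, depth, genome_mean=30.0)
cn = depth_copy_number(profile, (100_000, 120_000))
print(f"mCNV locus: depth ratio {cn['ratio']:.2f} -> copy number {cn['copy_number']}")

# The event windows sit on TE positions, so their density matches the
# genome-wide Alu fraction here (~27%); with no planted enrichment the
# Welch test should be non-significant.  The depth ratio 2.0 doubles the
# diploid baseline: CN = 4.
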