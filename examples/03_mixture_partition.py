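"""Fit the two-Gaussian model to a log2-ratio distribution and partition
segments into three groups (loss / limited gain / strong gain).

Run:  python examples/03_mixture_partition.py
"""

import numpy as np

from k27domains import fit_bimodal, partition_groups, simulate_log2_mixture

# a bimodal log2-ratio distribution: 60% of segments centered at 0 (no
# change), 40% centered at +1 (strong gain), widths w = 0.3 (sd = w/sqrt(2))
A_true = (0.6, 0.0, 0.3, 0.4, 1.0, 0.3)
values = simulate_log2_mixture(A_true, n=10_000, seed=11)

fit = fit_bimodal(values, n_bins=60)
print("fitted y = A0*exp(-((x-A1)/A2)^2) + A3*exp(-((x-A4)/A5)^2):")
print(f"  component 1: amplitude {fit.A0:.3f}, mean {fit.A1:+.3f}, width {fit.A2:.3f}")
print(f"  component 2: amplitude {fit.A3:.3f}, mean {fit.A4:+.3f}, width {fit.A5:.3f}")
print(f"  residual sum of squares: {fit.rss:.5f}")
print(f"group boundaries: cut_low = A1 - A2 = {fit.cut_low:+.3f}, "
      f"cut_high = component crossing = {fit.cut_high:+.3f}")

labels = partition_groups(values, fit)
for g, meaning in (("CL1", "loss"), ("CL2", "limited gain"), ("CL3", "strong gain")):
    n = int((labels == g).sum())
    print(f"  {g} ({meaning:12s}): {n:5d} segments ({100 * n / len(values):.1f}%)")
print("true means were 0 and 1; the crossing separates the two modes")
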