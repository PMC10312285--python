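"""Locate the Hopf bifurcation of the E-I mean-field model and cross it.

The exact mean-field (firing rate) equations of coupled excitatory and
inhibitory QIF populations undergo a Hopf bifurcation as the rescaled
Lorentzian half-widths (d_e, d_i) vary.  This script traces the
bifurcation curve by bisection on the Jacobian eigenvalues, then
simulates one population pair just below and just above the curve: the
subcritical side relaxes to a fixed point, the supercritical side
settles into sustained E-I rate oscillations.
"""

import numpy as np

import oscibrain as ob
from oscibrain.meanfield import simulate_fre_network

curve = ob.locate_hopf_curve(np.array([0.8, 1.0, 1.2]))
print("Hopf curve (d_e -> critical d_i):")
for de, di in curve:
    print(f"  d_e = {de:.2f}: d_i* = {di:.4f}")

de, di_crit = curve[1]
bundle = ob.ConnectomeBundle(C=np.array([[0.0, 0.01], [0.01, 0.0]]))
for tag, d_i in (("subcritical", di_crit + 0.4), ("supercritical", di_crit - 0.3)):
    p = ob.FREParams(d_e=de, d_i=d_i, G=0.0, dt=0.002, duration=100,
                     transient=100)
    r = simulate_fre_network(p, bundle, seed=0)
    print(f"{tag} (d_i = {d_i:.3f}): excitatory-rate range = "
          f"{r[0].max() - r[0].min():.4f}")
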