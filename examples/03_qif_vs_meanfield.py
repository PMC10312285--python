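"""Check the mean-field reduction against a microscopic QIF population.

Integrates 10,000 quadratic integrate-and-fire neurons with Lorentzian-
distributed input currents and recurrent coupling, and compares the
stationary population firing rate with the fixed point of the exact
firing-rate equations.  The two should agree within a few percent —
the mean-field model is exact in the large-population limit.
"""

from oscibrain import QIFParams, simulate_qif_population
from oscibrain.meanfield import fre_single_fixed_point

eta, delta, J = 1.0, 1.0, 0.5
qif = QIFParams(n_neurons=10_000, eta_center=eta, delta=delta, J=J,
                duration=40.0, dt=2e-4)
out = simulate_qif_population(qif, seed=7)
r_qif = out["rate"][int(20 / qif.dt):].mean()          # rate per tau_m
r_fre, v_fre = fre_single_fixed_point(d=delta, eta=eta, j=J)

print(f"QIF population rate (10^4 neurons): {r_qif:.4f} per tau_m")
print(f"FRE fixed-point rate:               {r_fre:.4f} per tau_m")
print(f"relative discrepancy:               {abs(r_qif - r_fre) / r_fre:.2%}")
print(f"(in Hz with tau_m = 10 ms: {r_qif / qif.tau_m:.1f} vs {r_fre / 0.01:.1f})")
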