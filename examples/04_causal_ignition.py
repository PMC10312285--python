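"""Causal ignition: transfer entropy from a region's amplitude to global
synchronization.

Constructs a toy system in which a hidden driver's amplitude linearly
determines the next step of a global synchronization series, computes
the Gaussian transfer entropy and its normalized causal-ignition score,
and tests significance with circular-shift surrogates.  An independent
amplitude stream serves as the negative control: its transfer entropy
is near zero and its surrogate p value large.  (The normalized CI of
the control is a ratio of two near-zero quantities — the surrogate
test, not the CI magnitude, carries the significance.)
"""

import numpy as np

from oscibrain import surrogate_pvalue, transfer_entropy_ci

rng = np.random.default_rng(0)
n = 2000
amp_driver = rng.standard_normal(n)
amp_bystander = rng.standard_normal(n)
kop = np.empty(n)
kop[0] = 0.0
kop[1:] = 0.6 * amp_driver[:-1] + 0.4 * rng.standard_normal(n - 1)

for name, amp in (("driver", amp_driver), ("bystander", amp_bystander)):
    ci, i_n, total = transfer_entropy_ci(kop, amp, T=10)
    p = surrogate_pvalue(kop, amp, T=10, n_surrogates=99, seed=1)
    print(f"{name:9s}: TE = {i_n:.4f} nats, CI = {ci:.3f}, "
          f"surrogate p = {p:.3f}")
print("The driver's amplitude genuinely predicts next-step synchronization;")
print("the bystander's does not (TE ~ 0 nats, p > 0.05).")
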