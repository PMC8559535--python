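"""Fit one sequence's kinetics and bootstrap its uncertainty.

Simulates noisy reacted fractions for a ribozyme with known k and A over
the extended substrate series (2-1250 uM in triplicate), fits the
pseudo-first-order model, and reports bootstrap CI-95s plus the
identifiability score gamma.
"""

import numpy as np

from kseqtools import (
    KineticModelConfig,
    bootstrap_fit,
    condition_layout,
    fit_sequence,
    model_predict,
)

cfg = KineticModelConfig()  # alpha = 0.479, t = 90 min
conc = condition_layout("extended").conc.to_numpy()

k_true, A_true = 40.0, 0.65
rng = np.random.default_rng(7)
f0 = model_predict(k_true, A_true, conc, cfg)
fractions = np.clip(f0 * (1.0 + 0.2 * rng.standard_normal(f0.size)), 0.0, None)

fit = fit_sequence(conc, fractions, cfg)
summary = bootstrap_fit(conc, fractions, fit, cfg, n_boot=100, seed=1)

print(f"truth:     k = {k_true:.1f} /min/M   A = {A_true:.2f}   kA = {k_true * A_true:.1f}")
print(f"estimate:  k = {fit.k_hat:.1f}        A = {fit.A_hat:.2f}   kA = {fit.kA_hat:.1f}")
lo, hi = summary.ci95_pctl.loc["kA"]
print(f"kA CI-95 (percentile bootstrap): [{lo:.1f}, {hi:.1f}]")
print(f"gamma = {summary.gamma:.2f}  (near 0: k and A separable)")
print(f"fold-range = {summary.fold_range:.2f}  (CI spans {summary.fold_range:.1f}x)")
# With 20% relative noise and saturation visible at 250-1250 uM, k and A
# separate cleanly; remove the highest concentration and gamma rises.
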