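"""Type-I error and power of the tests across many simulated trials.

Draws a maximin Latin hypercube over the benchmark parameter ranges,
simulates one trial per design point, and reports rejection fractions.
Scaled to 300 datasets per study for a quick demonstration; the
benchmark-scale studies (2,000+ datasets) run the same code.
"""

import placeboiv as piv

common = dict(setting="blinded", confounded=True, n_datasets=300, B=400, seed=5,
              alphas=(0.01, 0.05, 0.1, 0.2), methods=("iv_placebo", "regression_psi"))

print("blinded confounded trials, H0: psi = 0 true (type-I error):")
curves = piv.run_error_power_experiment(piv.ExperimentConfig(**common))
for method, curve in curves.items():
    cells = "  ".join(f"{a}:{r:.3f}" for a, r in zip(curve.alphas, curve.rejection))
    print(f"  {method:>15}  {cells}")

print("\nsame setting, psi in [-2, 2] (power):")
curves = piv.run_error_power_experiment(
    piv.ExperimentConfig(psi_hypothesis="alt", **common)
)
for method, curve in curves.items():
    cells = "  ".join(f"{a}:{r:.3f}" for a, r in zip(curve.alphas, curve.rejection))
    print(f"  {method:>15}  {cells}")

print()
print("Under the null the IV randomization test rejects at the nominal rate")
print("while the regression t-test is grossly inflated by confounding (its")
print("rejections are false positives, so its apparent power is meaningless).")
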