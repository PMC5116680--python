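"""Robustness demonstrations: noisy emotion recordings and a second mediator.

First contaminates the emotion level with additive Gaussian noise and
compares the IV and regression placebo estimates; then simulates a trial
whose placebo channel runs through two mediators (M and A, each with its
own randomized instrument) and applies the doubly-adjusted two-step
estimator.
"""

import numpy as np

import placeboiv as piv

# -- measurement error -------------------------------------------------------
params = piv.ReducedModelParameters.with_constant_loadings(
    1.0, n=2000, psi=1.0, beta=1.0, theta_DQ=2.0, theta_MD=2.0, theta_ME=2.0
)
iv_err, reg_err = [], []
for seed in range(200):
    noisy = piv.add_measurement_error(piv.simulate_trial(params, seed=seed), 1.0, seed=seed)
    iv_err.append(piv.placebo_effect_iv(noisy).value - 1.0)
    reg_err.append(piv.regression_comparator(noisy).psi_hat - 1.0)
print("placebo estimation with measurement error sd = 1 on M (200 replicates):")
print(f"  IV bias         {np.mean(iv_err):+.3f}")
print(f"  regression bias {np.mean(reg_err):+.3f}")

# -- second placebo mediator -------------------------------------------------
multi_params = piv.ReducedModelParameters.with_constant_loadings(
    1.0, n=5000, psi=1.0, beta=1.0, theta_EX=1.0, blinded=False, kappa=1.0,
    theta_XZ=2.0, theta_DQ=2.0, theta_MD=2.0, theta_ME=2.0,
)
data = piv.simulate_trial(multi_params, seed=4)
est = piv.multi_mediator_two_step(data)
print("\ntwo-mediator trial (true psi = kappa = beta = 1):")
print(f"  psi_hat   = {est.diagnostics['psi_hat']:.3f}   (M channel, instrument Q)")
print(f"  kappa_hat = {est.diagnostics['kappa_hat']:.3f}   (A channel, instrument W)")
print(f"  beta_hat  = {est.value:.3f}   (treatment effect after removing both)")
print()
print("The IV placebo estimate tolerates noise on M that attenuates and")
print("biases the regression estimate, and extra placebo pathways are")
print("handled by adding one randomized instrument per mediator.")
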