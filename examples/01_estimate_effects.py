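"""Estimate placebo and treatment effects in a simulated unblinded trial.

Builds one unblinded encouragement-design trial (n = 2,000) in which the
true treatment effect is beta = 1 and the true net placebo effect is
psi = 1, with unmeasured confounders on every endogenous pair, then
compares the IV estimators with the naive OLS regression of Y on (X, M).
"""

import placeboiv as piv

params = piv.ReducedModelParameters.with_constant_loadings(
    1.0, n=2000, beta=1.0, psi=1.0, theta_EX=1.0, blinded=False,
    theta_XZ=2.0, theta_DQ=2.0, theta_MD=2.0, theta_ME=2.0,
)
data = piv.simulate_trial(params, seed=1)

placebo = piv.placebo_effect_iv(data)
two_step = piv.treatment_effect_two_step(data, placebo.value)
unadjusted = piv.treatment_effect_unadjusted(data)
regression = piv.regression_comparator(data)
diag = piv.instrument_diagnostics(data)

print(f"generating effects:      psi = {params.psi:.2f}, beta = {params.beta:.2f}")
print(f"IV placebo effect        psi_hat  = {placebo.value:6.3f}   (Cov(Q,Y)/Cov(Q,M))")
print(f"IV two-step treatment    beta_hat = {two_step.value:6.3f}   (Cov(Z,R)/Cov(Z,X), R = Y - psi_hat*M)")
print(f"IV unadjusted treatment  beta_hat = {unadjusted.value:6.3f}   (ignores the placebo channel)")
print(f"OLS regression           psi_hat  = {regression.psi_hat:6.3f}, beta_hat = {regression.beta_hat:6.3f}")
print(f"instrument strength:     corr(Q,M) = {diag['corr_QM']:.3f}, corr(Z,X) = {diag['corr_ZX']:.3f}")
print()
print("The IV estimates scatter around the generating effects despite the")
print("unmeasured confounding (they are consistent, with sampling noise set")
print("by the instrument strength shown above); the regression coefficients")
print("absorb the confounder associations and are biased away from the truth.")
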