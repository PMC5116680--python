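"""Replicate-level simulation studies: error, power, consistency, coverage.

Each study draws a maximin Latin hypercube over the benchmark parameter
ranges, simulates one trial per design point, applies the configured
tests or estimators, and summarizes rejection fractions (empirical
type-I error on null data, power on alternative data), estimator bias
and spread by sample size, or confidence-interval coverage.  Per-dataset
seeds are spawned from the master seed, so serial and parallel runs
agree and any run is reproducible from its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dataset import TrialDataset
from .estimators import (
    DegenerateInstrumentError,
    placebo_effect_iv,
    regression_comparator,
    treatment_effect_two_step,
    treatment_effect_unadjusted,
)
from .randomization import (
    confidence_interval,
    placebo_randomization_test,
    pvalue_profile,
    treatment_randomization_test,
)
from .simulate import (
    default_parameter_ranges,
    latin_hypercube_design,
    params_from_point,
    simulate_trial,
    ReducedModelParameters,
)

__all__ = [
    "ExperimentConfig",
    "RejectionCurve",
    "CoverageResult",
    "TestThenEstimateResult",
    "run_error_power_experiment",
    "run_consistency_experiment",
    "run_coverage_experiment",
    "test_then_estimate",
]

DEFAULT_ALPHAS = (0.01, 0.025, 0.05, 0.1, 0.15, 0.2, 0.25)

#: method label -> (effect tested, needs generating psi)
METHODS = {
    "iv_placebo": "psi",
    "iv_two_step": "beta",
    "iv_unadjusted": "beta",
    "iv_true_psi": "beta",
    "regression_psi": "psi",
    "regression_beta": "beta",
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration of the replicate-level studies."""

    setting: str = "blinded"  # 'blinded' | 'unblinded'
    confounded: bool = True
    beta_hypothesis: str = "null"  # 'null' | 'alt'
    psi_hypothesis: str = "null"
    n_datasets: int = 2000
    B: int = 500  # permutations per randomization test
    alphas: tuple = DEFAULT_ALPHAS
    methods: tuple = ("iv_placebo", "iv_two_step", "iv_unadjusted", "regression_psi", "regression_beta")
    seed: int = 0
    n_jobs: int = 1
    lhs_restarts: int = 5

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be at least 1")
        if not all(0 < a < 1 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass(frozen=True)
class RejectionCurve:
    """Empirical rejection fraction of one test across the alpha grid."""

    method: str
    effect_kind: str
    alphas: tuple
    rejection: np.ndarray  # fraction of p-values below each alpha
    standard_errors: np.ndarray  # binomial Monte-Carlo SEs
    n_datasets: int
    n_failures: int  # datasets where the estimator was degenerate
    p_values: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class CoverageResult:
    effect_kind: str
    nominal_level: float
    n_replicates: int
    coverage: float  # fraction of intervals containing the generating value
    mean_width: float
    standard_error: float


@dataclass(frozen=True)
class TestThenEstimateResult:
    placebo_test: object
    placebo_detected: bool
    chosen_estimator: str  # 'two_step' | 'unadjusted'
    treatment_estimate: object
    placebo_estimate: object


def _spawn_seeds(master: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master).spawn(n)


def _dataset_pvalues(params: ReducedModelParameters, methods, B, child_seed):
    rng = np.random.default_rng(child_seed)
    data = simulate_trial(params, rng)
    out = {}
    reg = None
    for method in methods:
        try:
            if method == "iv_placebo":
                out[method] = placebo_randomization_test(data, B=B, seed=rng).p_value
            elif method == "iv_two_step":
                out[method] = treatment_randomization_test(data, B=B, seed=rng).p_value
            elif method == "iv_unadjusted":
                out[method] = treatment_randomization_test(
                    data, B=B, seed=rng, psi=0.0
                ).p_value
            elif method == "iv_true_psi":
                out[method] = treatment_randomization_test(
                    data, B=B, seed=rng, psi=params.psi
                ).p_value
            elif method in ("regression_psi", "regression_beta"):
                if reg is None:
                    reg = regression_comparator(data)
                out[method] = (
                    reg.psi_pvalue if method == "regression_psi" else reg.beta_pvalue
                )
        except DegenerateInstrumentError:
            out[method] = np.nan
    return out


def _design_params(config: ExperimentConfig):
    ranges = default_parameter_ranges(
        config.setting, config.confounded, config.beta_hypothesis, config.psi_hypothesis
    )
    design = latin_hypercube_design(
        ranges, config.n_datasets, seed=config.seed, restarts=config.lhs_restarts
    )
    return [
        params_from_point(row, config.setting, config.confounded)
        for row in design.matrix.to_dict("records")
    ]


def run_error_power_experiment(config: ExperimentConfig) -> dict[str, RejectionCurve]:
    """Empirical type-I error (null data) or power (alternative data) curves.

    One trial is simulated per Latin-hypercube design point; every
    configured test runs on every trial.  Datasets on which an estimator
    is degenerate (weak instrument draw) are counted as failures for that
    method and excluded from its rejection fractions.
    """
    params_list = _design_params(config)
    seeds = _spawn_seeds(config.seed, config.n_datasets)
    worker = delayed(_dataset_pvalues)
    results = Parallel(n_jobs=config.n_jobs)(
        worker(p, config.methods, config.B, s) for p, s in zip(params_list, seeds)
    )
    curves = {}
    alphas = np.asarray(config.alphas)
    for method in config.methods:
        pvals = np.array([r[method] for r in results])
        ok = ~np.isnan(pvals)
        frac = np.array([(pvals[ok] < a).mean() for a in alphas])
        se = np.sqrt(frac * (1 - frac) / max(ok.sum(), 1))
        curves[method] = RejectionCurve(
            method=method,
            effect_kind=METHODS[method],
            alphas=config.alphas,
            rejection=frac,
            standard_errors=se,
            n_datasets=int(ok.sum()),
            n_failures=int((~ok).sum()),
            p_values=pvals,
        )
    return curves


def run_consistency_experiment(
    config: ExperimentConfig,
    sample_size_bins: tuple = ((100, 280), (280, 460), (460, 640), (640, 820), (820, 1000)),
    replicates_per_bin: int = 500,
) -> pd.DataFrame:
    """Bias and spread of the psi and beta estimates by sample-size bin.

    Replicates are drawn from Latin hypercubes restricted to each bin's
    sample sizes; generating beta and psi vary over their declared ranges,
    so bias and spread are measured on the estimate-minus-truth scale.
    """
    rows = []
    for b, (lo, hi) in enumerate(sample_size_bins):
        ranges = default_parameter_ranges(
            config.setting, config.confounded, config.beta_hypothesis, config.psi_hypothesis
        )
        ranges["n"] = range(int(lo), int(hi) + 1)
        design = latin_hypercube_design(
            ranges, replicates_per_bin, seed=config.seed + b, restarts=config.lhs_restarts
        )
        seeds = _spawn_seeds(config.seed + b, replicates_per_bin)
        psi_err, beta_err = [], []
        failures = 0
        for row, child in zip(design.matrix.to_dict("records"), seeds):
            params = params_from_point(row, config.setting, config.confounded)
            data = simulate_trial(params, np.random.default_rng(child))
            try:
                psi_hat = placebo_effect_iv(data).value
                beta_hat = treatment_effect_two_step(data, psi_hat).value
            except DegenerateInstrumentError:
                failures += 1
                continue
            psi_err.append(psi_hat - params.psi)
            beta_err.append(beta_hat - params.beta)
        psi_err = np.asarray(psi_err)
        beta_err = np.asarray(beta_err)
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n_replicates": psi_err.size,
                "n_failures": failures,
                "psi_bias": psi_err.mean(),
                "psi_spread": psi_err.std(ddof=1),
                "beta_bias": beta_err.mean(),
                "beta_spread": beta_err.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def _one_coverage_replicate(params, child_seed, B, alpha, step):
    rng = np.random.default_rng(child_seed)
    data = simulate_trial(params, rng)
    try:
        profile = pvalue_profile(data, "psi", step=step, B=B, seed=rng)
        ci = confidence_interval(profile, alpha)
    except (DegenerateInstrumentError, ValueError, RuntimeError):
        return None
    return ci.lower, ci.upper


def run_coverage_experiment(
    config: ExperimentConfig,
    params: ReducedModelParameters | None = None,
    n_replicates: int = 200,
    alpha: float = 0.025,
    B: int = 1000,
    step: float | None = None,
) -> CoverageResult:
    """Empirical coverage of the placebo-effect randomization CI.

    Default generating process: all structural coefficients 1 at the
    configured setting/confounding, n = 300.  Reports the fraction of
    nominal 100(1-2*alpha)% intervals containing the generating psi.
    """
    if params is None:
        params = ReducedModelParameters.with_constant_loadings(
            1.0 if config.confounded else 0.0,
            n=300,
            theta_EX=0.0 if config.setting == "blinded" else 1.0,
            blinded=(config.setting == "blinded"),
            beta=1.0,
            psi=1.0,
        )
    seeds = _spawn_seeds(config.seed, n_replicates)
    worker = delayed(_one_coverage_replicate)
    intervals = Parallel(n_jobs=config.n_jobs)(
        worker(params, s, B, alpha, step) for s in seeds
    )
    intervals = [iv for iv in intervals if iv is not None]
    lo = np.array([iv[0] for iv in intervals])
    hi = np.array([iv[1] for iv in intervals])
    covered = (lo <= params.psi) & (params.psi <= hi)
    coverage = float(covered.mean())
    return CoverageResult(
        effect_kind="placebo",
        nominal_level=1 - 2 * alpha,
        n_replicates=len(intervals),
        coverage=coverage,
        mean_width=float((hi - lo).mean()),
        standard_error=float(np.sqrt(coverage * (1 - coverage) / len(intervals))),
    )


def test_then_estimate(
    data: TrialDataset, B: int = 1000, seed=None, alpha: float = 0.05
) -> TestThenEstimateResult:
    """Pragmatic unblinded-analysis strategy: test for a placebo effect first.

    If H0: psi = 0 is rejected at ``alpha`` the treatment effect is
    estimated with the two-step (placebo-adjusted) estimator; otherwise
    with the unadjusted IV estimator.
    """
    test = placebo_randomization_test(data, B=B, seed=seed)
    detected = test.p_value < alpha
    placebo = placebo_effect_iv(data)
    if detected:
        estimate = treatment_effect_two_step(data, placebo.value)
        chosen = "two_step"
    else:
        estimate = treatment_effect_unadjusted(data)
        chosen = "unadjusted"
    return TestThenEstimateResult(
        placebo_test=test,
        placebo_detected=detected,
        chosen_estimator=chosen,
        treatment_estimate=estimate,
        placebo_estimate=placebo,
    )
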