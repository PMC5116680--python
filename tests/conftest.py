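import numpy as np
import pytest

from placeboiv import ReducedModelParameters, TrialDataset, simulate_trial


@pytest.fixture
def fixed_dataset() -> TrialDataset:
    """Small deterministic trial with every optional column populated."""
    return TrialDataset(
        Z=np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0]),
        Q=np.array([1, 0, 1, 0, 1, 0, 1, 0, 0, 1]),
        X=np.array([0, 1, 0, 1, 1, 1, 1, 0, 1, 0]),
        M=np.array([1.2, -0.3, 2.1, 0.4, 1.8, 0.1, 2.5, -0.6, 0.2, 1.1]),
        Y=np.array([2.0, 0.5, 3.1, 1.4, 3.9, 0.8, 4.2, -0.2, 1.0, 2.2]),
        E=np.array([1, 0, 1, 0, 1, 0, 1, 0, 0, 1]),
        D=np.array([1, 1, 1, 0, 1, 0, 1, 0, 1, 1]),
    )


@pytest.fixture(scope="module")
def simulated_alt() -> TrialDataset:
    """Unblinded confounded trial with nonzero placebo and treatment effects."""
    params = ReducedModelParameters.with_constant_loadings(
        1.0, n=400, beta=1.0, psi=1.0, theta_EX=1.0, blinded=False
    )
    return simulate_trial(params, seed=42)


def null_blinded_params(n: int = 300) -> ReducedModelParameters:
    """Blinded confounded model with beta = psi = 0."""
    return ReducedModelParameters.with_constant_loadings(1.0, n=n)
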