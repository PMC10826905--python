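import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import betaimpute as bi

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> bi.BetaMatrix:
    """4 samples x 5 probes, one missing entry in the last probe."""
    values = np.array(
        [
            [0.10, 0.20, 0.30, 0.40, 0.50],
            [0.15, 0.25, 0.35, 0.45, 0.55],
            [0.12, 0.22, 0.32, 0.42, 0.52],
            [0.18, 0.28, 0.38, 0.48, np.nan],
        ]
    )
    return bi.BetaMatrix(
        values=values,
        sample_ids=[f"S{i}" for i in range(1, 5)],
        probe_ids=[f"cg{j:02d}" for j in range(1, 6)],
    )


@pytest.fixture
def masked_fixture() -> bi.MaskedDataset:
    """Correlated 40 x 300 matrix with 3% of probes artificially masked."""
    X, _ = bi.generate_beta_matrix(40, 300, latent_rank=3, noise_sd=0.05, seed=11)
    return bi.inject_missing(X, bi.NAGenerationConfig(probe_fraction=0.03, lam=3.0, seed=12))


def exact_logit_linear_matrix(
    n: int, m: int, rank: int, seed: int
) -> bi.BetaMatrix:
    """Matrix whose logit lies exactly in a rank-`rank` subspace (no noise)."""
    X, _ = bi.generate_beta_matrix(n, m, latent_rank=rank, noise_sd=0.0, seed=seed)
    return X
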