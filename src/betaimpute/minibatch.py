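"""Row-subsampling (mini-batch) regression for large sample sizes.

For datasets with hundreds of samples, each regression can be solved on a
random fraction P of the observation rows of A and B, repeated R times with
independent subsets, and the imputed blocks averaged. C (the predictor rows
at the missing samples) is never subsampled. At P = 100 the procedure is
exactly the full algorithm for any R.
"""

from __future__ import annotations

import math

import numpy as np

from .core import ImputationConfig, MiniBatchConfig, RegressionSystem, _solve_block

__all__ = ["MiniBatchConfig", "sample_row_subset", "minibatch_impute_group"]


def sample_row_subset(
    n_rows: int, percent: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ceil(n_rows * percent / 100) distinct row indices, sorted.

    If the target size reaches ``n_rows`` (always at percent = 100), all rows
    are returned unchanged and the random stream is not consumed — matrices
    already smaller than the batch size are not subsampled.
    """
    if n_rows < 1:
        raise ValueError(f"n_rows must be >= 1, got {n_rows}")
    if not 0.0 < percent <= 100.0:
        raise ValueError(f"percent must be in (0, 100], got {percent}")
    size = max(1, math.ceil(n_rows * percent / 100.0))
    if size >= n_rows:
        return np.arange(n_rows)
    idx = rng.choice(n_rows, size=size, replace=False)
    return np.sort(idx)


def minibatch_impute_group(
    system: RegressionSystem, config: ImputationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Impute one group's r x l block with subsampled regressions.

    Per repetition one row subset is drawn and applied jointly to A and B
    (they index the same observations); the R imputed blocks are averaged
    elementwise. Subsets are drawn independently per repetition and, through
    the shared ``rng``, per pattern group.
    """
    mb = config.minibatch
    if mb is None:
        raise ValueError("config.minibatch is not set")
    n_obs = system.A.shape[0]
    blocks = []
    for _ in range(mb.repetitions):
        rows = sample_row_subset(n_obs, mb.percent, rng)
        if len(rows) == n_obs:
            # no subsampling happens: every repetition is the identical full
            # solve, so compute it once (keeps P=100 bit-equal to the full
            # algorithm for any R)
            return _solve_block(system.A, system.B, system.C, config)
        blocks.append(_solve_block(system.A[rows], system.B[rows], system.C, config))
    if len(blocks) == 1:
        return blocks[0]
    return np.mean(blocks, axis=0)
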