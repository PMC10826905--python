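"""Synthetic correlated beta-matrices and artificial missing-value injection.

The generator emulates the one property the regression relies on: strong
cross-probe linear structure on the logit (M-value) scale. A latent-factor
matrix Z = U.V' + E is drawn with standard-normal factors and Gaussian noise,
mapped through the logistic function to (0, 1), and probes are assigned to
chromosomes in consecutive blocks of configurable, unequal sizes. At
noise_sd = 0 every column of Z lies exactly in a rank-k subspace, which makes
exact-recovery tests possible.

Missing values are injected by the evaluation protocol used for methylation
arrays: a fraction of probes (3% by default) is chosen uniformly, each
chosen probe receives k ~ Poisson(lambda) missing entries (truncated to
[1, n]), placed uniformly among the samples, and the masked positions are
recorded so that accuracy can later be scored on them alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import inverse_logit
from .io import BetaMatrix, ProbeAnnotation

__all__ = [
    "NAGenerationConfig",
    "MaskedDataset",
    "generate_beta_matrix",
    "draw_na_mask",
    "inject_missing",
]


@dataclass(frozen=True)
class NAGenerationConfig:
    """Parameters of the artificial-NA protocol.

    ``probe_fraction`` of the m probes receive missing values; each receives
    a Poisson(``lam``)-distributed number of them, truncated to [1, n].
    """

    probe_fraction: float = 0.03
    lam: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.probe_fraction <= 1.0:
            raise ValueError(f"probe_fraction must be in (0, 1], got {self.probe_fraction}")
        if self.lam <= 0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")


@dataclass
class MaskedDataset:
    """Ground truth, its masked copy, and the artificial mask positions."""

    complete: BetaMatrix
    observed: BetaMatrix
    artificial_mask: list[tuple[int, int]]
    preexisting_mask: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_masked(self) -> int:
        return len(self.artificial_mask)


def generate_beta_matrix(
    n: int,
    m: int,
    latent_rank: int = 3,
    noise_sd: float = 0.1,
    chromosome_sizes: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[BetaMatrix, ProbeAnnotation]:
    """Draw a fully observed n x m beta-matrix with low-rank logit structure.

    Z = U.V' + E with U (n x rank), V (m x rank) standard normal and E
    Gaussian with sd ``noise_sd``; beta = logistic(Z). Probes are assigned to
    the given chromosomes in consecutive blocks; by default two chromosomes
    of unequal size (2/3 and 1/3 of m).
    """
    if n < 1 or m < 1:
        raise ValueError(f"need n >= 1 and m >= 1, got n={n}, m={m}")
    if not 0 < latent_rank < min(n, m):
        raise ValueError(f"latent_rank must be in (0, min(n, m)), got {latent_rank}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if chromosome_sizes is None:
        chromosome_sizes = {"chr1": m - m // 3, "chr2": m // 3}
    if sum(chromosome_sizes.values()) != m:
        raise ValueError(
            f"chromosome sizes sum to {sum(chromosome_sizes.values())}, expected m={m}"
        )
    rng = np.random.default_rng(seed)
    U = rng.standard_normal((n, latent_rank))
    V = rng.standard_normal((m, latent_rank))
    Z = U @ V.T
    if noise_sd > 0:
        Z += rng.normal(scale=noise_sd, size=(n, m))
    beta = inverse_logit(Z)

    width = len(str(m))
    probe_ids = [f"cg{j:0{width}d}" for j in range(m)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    entries: dict[str, str] = {}
    j = 0
    for chrom, size in chromosome_sizes.items():
        for _ in range(size):
            entries[probe_ids[j]] = chrom
            j += 1
    X = BetaMatrix(values=beta, sample_ids=sample_ids, probe_ids=probe_ids)
    return X, ProbeAnnotation(entries=entries)


def draw_na_mask(
    n: int, m: int, config: NAGenerationConfig, rng: np.random.Generator | None = None
) -> list[tuple[int, int]]:
    """Draw artificial-NA positions for an n x m matrix, without the matrix.

    round(probe_fraction * m) probes are chosen uniformly without
    replacement; each receives k ~ Poisson(lambda) missing rows, k truncated
    to [1, n], rows chosen uniformly without replacement. Positions are
    returned sorted by (column, row) for determinism.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_probes = int(round(config.probe_fraction * m))
    if n_probes < 1:
        raise ValueError(
            f"probe_fraction*m = {config.probe_fraction * m:.3g} selects no probe"
        )
    probes = np.sort(rng.choice(m, size=n_probes, replace=False))
    counts = np.clip(rng.poisson(config.lam, size=n_probes), 1, n)
    positions: list[tuple[int, int]] = []
    for j, k in zip(probes, counts):
        rows = np.sort(rng.choice(n, size=int(k), replace=False))
        positions.extend((int(i), int(j)) for i in rows)
    return positions


def inject_missing(X: BetaMatrix, config: NAGenerationConfig) -> MaskedDataset:
    """Mask artificial NAs into a copy of X, recording their positions.

    Pre-existing missing entries of X are tracked separately and never
    selected as artificial positions (a masked position must have known
    ground truth).
    """
    rng = np.random.default_rng(config.seed)
    n, m = X.shape
    preexisting = [tuple(map(int, ij)) for ij in np.argwhere(X.missing_mask())]
    pre_set = set(preexisting)
    positions = [ij for ij in draw_na_mask(n, m, config, rng) if ij not in pre_set]
    observed = X.copy()
    if positions:
        rows, cols = zip(*positions)
        observed.values[list(rows), list(cols)] = np.nan
    return MaskedDataset(
        complete=X.copy(),
        observed=observed,
        artificial_mask=positions,
        preexisting_mask=preexisting,
    )
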