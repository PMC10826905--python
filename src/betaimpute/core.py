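"""Logit-space multiple linear regression imputation.

The method exploits the strong inter-sample correlation of methylation
levels. Probes (columns) sharing the same pattern of missing samples are
imputed jointly: with RNA the set of r samples at which the group is missing
and CNA its l probe columns, the fully observed probes form the predictor
block and the system

    logit(A) . x = logit(B)        =>        Imp = logit^-1(logit(C) . x)

is solved on the logit scale by a minimum-norm least-squares fit
(Moore-Penrose pseudo-inverse via SVD), where

* A  is the (n-r) x (m-L) block of fully observed probes at observed samples,
* B  is the (n-r) x l block of the group's probes at observed samples,
* C  is the r x (m-L) block of fully observed probes at the missing samples,

and L is the total number of probes with any missing value. The logit
transform moves the bounded beta-values onto an unbounded scale where a
linear model is appropriate (the M-value scale); the inverse logistic maps
predictions back into (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import BetaMatrix

__all__ = [
    "MissingnessGroup",
    "RegressionSystem",
    "ImputationConfig",
    "GroupRecord",
    "ImputationReport",
    "UnimputableGroupError",
    "logit_transform",
    "inverse_logit",
    "find_missingness_groups",
    "build_regression_system",
    "min_norm_least_squares",
    "impute_group",
    "impute_matrix",
]


class UnimputableGroupError(ValueError):
    """A pattern group for which no regression system can be formed."""


@dataclass(frozen=True)
class MissingnessGroup:
    """One unique missingness pattern.

    ``na_rows`` (size r) are the sample indices at which every column in
    ``na_cols`` (size l) is missing; each of those columns is observed at all
    other samples.
    """

    na_rows: tuple[int, ...]
    na_cols: tuple[int, ...]

    @property
    def r(self) -> int:
        return len(self.na_rows)

    @property
    def l(self) -> int:  # noqa: E741 - field notation
        return len(self.na_cols)


@dataclass
class RegressionSystem:
    """The A/B/C blocks for one missingness group."""

    A: np.ndarray  # (n-r) x (m-L)
    B: np.ndarray  # (n-r) x l
    C: np.ndarray  # r x (m-L)
    predictor_cols: tuple[int, ...]  # the m-L fully observed columns


@dataclass(frozen=True)
class MiniBatchConfig:
    """Row-subsampling settings for large-n regressions.

    ``percent`` (P) of the observation rows of A and B are retained per
    repetition; ``repetitions`` (R) independent subsets are drawn and the
    imputed blocks averaged.
    """

    percent: float = 100.0
    repetitions: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.percent <= 100.0:
            raise ValueError(f"minibatch percent must be in (0, 100], got {self.percent}")
        if self.repetitions < 1:
            raise ValueError(f"minibatch repetitions must be >= 1, got {self.repetitions}")


@dataclass
class ImputationConfig:
    """Numerical settings for the imputation.

    Parameters
    ----------
    logit_eps
        Beta-values are clamped to [eps, 1-eps] before the logit so that 0
        and 1 stay finite. 1e-6 keeps the transform monotone and far outside
        the biologically meaningful range.
    svd_rtol
        Relative singular-value cutoff for the pseudo-inverse; ``None``
        selects ``1e-10 * max(p, q)`` for a p x q system.
    minibatch
        Optional row-subsampling of A and B; ``None`` uses all samples.
    seed
        Master seed for all randomness (mini-batch subsets).
    skip_logit
        Solve on the raw scale (identity transform) for unbounded inputs.
    add_intercept
        Append a constant predictor column to A and C. Off by default: the
        system is the intercept-free A.x = logit(B).
    """

    logit_eps: float = 1e-6
    svd_rtol: float | None = None
    minibatch: MiniBatchConfig | None = None
    seed: int = 0
    skip_logit: bool = False
    add_intercept: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.logit_eps < 0.5:
            raise ValueError(f"logit_eps must be in (0, 0.5), got {self.logit_eps}")
        if self.svd_rtol is not None and self.svd_rtol < 0:
            raise ValueError(f"svd_rtol must be >= 0, got {self.svd_rtol}")

    def with_seed(self, seed: int) -> "ImputationConfig":
        return replace(self, seed=int(seed))


@dataclass
class GroupRecord:
    """Per-group entry of an :class:`ImputationReport`."""

    na_rows: tuple[int, ...]
    na_cols: tuple[int, ...]
    r: int
    l: int  # noqa: E741
    imputed: bool
    reason: str | None = None  # set when not imputed


@dataclass
class ImputationReport:
    """What :func:`impute_matrix` did: group sizes and unimputable columns."""

    n_groups: int = 0
    groups: list[GroupRecord] = field(default_factory=list)
    n_imputed_entries: int = 0
    unimputable_cols: dict[int, str] = field(default_factory=dict)

    @property
    def n_unimputable_groups(self) -> int:
        return sum(1 for g in self.groups if not g.imputed)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def logit_transform(p, eps: float = 1e-6):
    """log(p' / (1 - p')) with p' = clamp(p, eps, 1-eps); accepts arrays."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore"):
        if bool(np.any((p < 0.0) | (p > 1.0))):
            raise ValueError("logit_transform requires values in [0, 1]")
    p = np.clip(p, eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return out if out.ndim else float(out)


def inverse_logit(q):
    """The logistic function 1 / (1 + exp(-q)), mapping R -> (0, 1)."""
    q = np.asarray(q, dtype=float)
    # evaluate on the negative side only to avoid overflow in exp
    out = np.empty_like(q)
    pos = q >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-q[pos]))
    eq = np.exp(q[~pos])
    out[~pos] = eq / (1.0 + eq)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# grouping and system construction
# ---------------------------------------------------------------------------


def find_missingness_groups(X: BetaMatrix) -> list[MissingnessGroup]:
    """Group probe columns by their exact set of missing sample rows.

    Every column with at least one missing entry belongs to exactly one
    group; complete columns belong to none. Groups are ordered by their
    smallest member column index, and index tuples are ascending, so the
    result is deterministic.
    """
    mask = X.missing_mask()
    cols_with_na = np.flatnonzero(mask.any(axis=0))
    if cols_with_na.size == 0:
        return []
    patterns: dict[bytes, list[int]] = {}
    for j in cols_with_na:
        patterns.setdefault(mask[:, j].tobytes(), []).append(int(j))
    groups = []
    for key, cols in patterns.items():
        rows = np.flatnonzero(np.frombuffer(key, dtype=bool))
        groups.append(
            MissingnessGroup(na_rows=tuple(int(i) for i in rows), na_cols=tuple(cols))
        )
    groups.sort(key=lambda g: g.na_cols[0])
    return groups


def build_regression_system(X: BetaMatrix, group: MissingnessGroup) -> RegressionSystem:
    """Extract the A, B, C blocks for one missingness group.

    The predictor set is the same for every group of a matrix: all columns
    with zero missing entries (the m-L fully observed probes).

    Raises
    ------
    UnimputableGroupError
        If no column is fully observed (m-L = 0) or the group is missing in
        every sample (n-r = 0).
    """
    mask = X.missing_mask()
    predictor_cols = np.flatnonzero(~mask.any(axis=0))
    if predictor_cols.size == 0:
        raise UnimputableGroupError("no fully observed predictor column (m-L = 0)")
    n = X.n_samples
    obs_rows = np.setdiff1d(np.arange(n), np.asarray(group.na_rows, dtype=int))
    if obs_rows.size == 0:
        raise UnimputableGroupError("columns missing in every sample (n-r = 0)")
    na_rows = np.asarray(group.na_rows, dtype=int)
    na_cols = np.asarray(group.na_cols, dtype=int)
    A = X.values[np.ix_(obs_rows, predictor_cols)]
    B = X.values[np.ix_(obs_rows, na_cols)]
    C = X.values[np.ix_(na_rows, predictor_cols)]
    return RegressionSystem(
        A=A, B=B, C=C, predictor_cols=tuple(int(j) for j in predictor_cols)
    )


# ---------------------------------------------------------------------------
# minimum-norm least squares via SVD
# ---------------------------------------------------------------------------

#: aspect ratio above which the pseudo-inverse is computed from the smaller
#: Gram matrix instead of a direct thin SVD
_GRAM_ASPECT = 10


def min_norm_least_squares(
    M: np.ndarray, Y: np.ndarray, rtol: float | None = None
) -> np.ndarray:
    """Minimum-Frobenius-norm least-squares solution x of M.x ~ Y.

    Equivalent to ``pinv(M) @ Y`` with singular values below
    ``rtol * sigma_max`` treated as zero. When the p x q system is strongly
    rectangular (aspect ratio above 10) the SVD is obtained from the
    eigendecomposition of the smaller Gram matrix (M.M' or M'.M), which is
    much cheaper when min(p, q) << max(p, q); otherwise a direct thin SVD is
    used. Both paths return the same solution to numerical accuracy.
    """
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if M.ndim != 2 or Y.ndim != 2:
        raise ValueError("M and Y must be 2-D")
    p, q = M.shape
    if Y.shape[0] != p:
        raise ValueError(f"row mismatch: M is {M.shape}, Y is {Y.shape}")
    if rtol is None:
        rtol = 1e-10 * max(p, q)
    if not np.any(M):
        return np.zeros((q, Y.shape[1]))

    if max(p, q) > _GRAM_ASPECT * min(p, q):
        if p <= q:
            # x = M' U S^-2 U' Y with M M' = U S^2 U'
            G = M @ M.T
            w, U = np.linalg.eigh(G)
            w = np.clip(w, 0.0, None)
            s = np.sqrt(w)
            keep = s > rtol * s.max()
            U = U[:, keep]
            inv_s2 = 1.0 / w[keep]
            return M.T @ (U @ (inv_s2[:, None] * (U.T @ Y)))
        # x = V S^-2 V' M' Y with M' M = V S^2 V'
        G = M.T @ M
        w, V = np.linalg.eigh(G)
        w = np.clip(w, 0.0, None)
        s = np.sqrt(w)
        keep = s > rtol * s.max()
        V = V[:, keep]
        inv_s2 = 1.0 / w[keep]
        return V @ (inv_s2[:, None] * (V.T @ (M.T @ Y)))

    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    keep = s > rtol * s[0]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    return Vt.T @ ((U.T @ Y) / s[:, None])


# ---------------------------------------------------------------------------
# group imputation
# ---------------------------------------------------------------------------


def _solve_block(
    A: np.ndarray, B: np.ndarray, C: np.ndarray, config: ImputationConfig
) -> np.ndarray:
    """Solve one regression system and map predictions back to beta scale.

    The whole system is solved on the logit (M-value) scale: predictors and
    targets are transformed, the min-norm coefficients fitted there, and the
    predictions for the missing rows mapped back through the logistic. A
    linear model is only coherent on the unbounded scale; transforming the
    response alone would leave the fit tied to the bounded predictor scale
    and break exactness on logit-linear data.
    """
    if not config.skip_logit:
        A = logit_transform(A, config.logit_eps)
        B = logit_transform(B, config.logit_eps)
        C = logit_transform(C, config.logit_eps)
    if config.add_intercept:
        A = np.hstack([A, np.ones((A.shape[0], 1))])
        C = np.hstack([C, np.ones((C.shape[0], 1))])
    x = min_norm_least_squares(A, B, rtol=config.svd_rtol)
    pred = C @ x
    return pred if config.skip_logit else inverse_logit(pred)


def impute_group(
    X: BetaMatrix,
    group: MissingnessGroup,
    config: ImputationConfig | None = None,
    rng: np.random.Generator | None = None,
    system: RegressionSystem | None = None,
) -> np.ndarray:
    """Impute one missingness group, returning the r x l block ``Imp``.

    With ``config.minibatch`` set, the observation rows of A and B are
    jointly subsampled ``repetitions`` times and the imputed blocks averaged
    (C is never subsampled). ``rng`` carries the random stream across groups;
    if omitted, one is seeded from ``config.seed``.
    """
    from .minibatch import minibatch_impute_group  # local import to avoid cycle

    config = config or ImputationConfig()
    if system is None:
        system = build_regression_system(X, group)
    if config.minibatch is not None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        return minibatch_impute_group(system, config, rng)
    return _solve_block(system.A, system.B, system.C, config)


def impute_matrix(
    X: BetaMatrix, config: ImputationConfig | None = None
) -> tuple[BetaMatrix, ImputationReport]:
    """Impute every missingness group of X.

    Observed entries are passed through bit-identically; entries of groups
    that cannot be imputed (no complete predictor column, or missing in every
    sample) are left missing and flagged in the report rather than raising,
    so one pathological probe cannot abort a run.
    """
    config = config or ImputationConfig()
    groups = find_missingness_groups(X)
    out = X.values.copy()
    report = ImputationReport(n_groups=len(groups))
    rng = np.random.default_rng(config.seed)
    # the predictor set is identical for all groups; compute its mask once
    mask = X.missing_mask()
    predictor_cols = np.flatnonzero(~mask.any(axis=0))
    for group in groups:
        record = GroupRecord(
            na_rows=group.na_rows, na_cols=group.na_cols,
            r=group.r, l=group.l, imputed=False,
        )
        try:
            if predictor_cols.size == 0:
                raise UnimputableGroupError("no fully observed predictor column (m-L = 0)")
            system = build_regression_system(X, group)
            imp = impute_group(X, group, config, rng=rng, system=system)
        except UnimputableGroupError as exc:
            record.reason = str(exc)
            for j in group.na_cols:
                report.unimputable_cols[int(j)] = str(exc)
        else:
            out[np.ix_(group.na_rows, group.na_cols)] = imp
            record.imputed = True
            report.n_imputed_entries += group.r * group.l
        report.groups.append(record)
    result = BetaMatrix(
        values=out, sample_ids=list(X.sample_ids), probe_ids=list(X.probe_ids)
    )
    return result, report
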