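"""Estimation for the misrecorded Poisson model.

Two estimators of ``theta = (lambda, phi)``:

* the closed-form maximum-likelihood estimator.  The score equations
  collapse to a quadratic in ``lambda`` whose positive root is

  ``lam_hat = [(xbar - 1 + n0/N) + sqrt((xbar - 1 + n0/N)^2
              + 4 (xbar - n1/N))] / 2``

  followed by ``phi_hat = (n0 - n1 / lam_hat) / (n0 + n1)``, where
  ``n0`` and ``n1`` count observed zeros and ones;

* a linear Bayes estimator ``theta_hat = B T + b`` built on the
  statistic ``T = (t1, t2) = (2 lam_hat, n0 - n1 / lam_hat)`` with the
  diagonal design matrix ``A = diag(1/2, 1/(n0 + n1))`` satisfying
  ``A T = theta_hat_MLE``.  Among linear functions of ``T`` that are
  unbiased under the joint (prior x sampling) model, it minimises Bayes
  risk under squared loss; only the prior mean and covariance enter.
  The shrinkage weight depends on ``W``, the sampling dispersion of
  ``T``, estimated here by bootstrap resampling.

The module also provides the mean-squared-error and MSE-matrix
evaluation used to compare the two estimators.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "EstimationError",
    "FrequencyTable",
    "SampleSummary",
    "StatisticT",
    "DesignMatrix",
    "PriorSpec",
    "LBComponents",
    "Estimate",
    "EvalResult",
    "summarize",
    "mle",
    "loglik",
    "statistic_and_design",
    "bootstrap_w",
    "linear_bayes",
    "evaluate",
    "msem_ordering_check",
]


class EstimationError(RuntimeError):
    """Estimation failed on a degenerate sample.

    Carries ``lambda_hat`` when the intensity estimate exists but the
    misclassification component is undefined.
    """

    def __init__(self, message: str, lambda_hat: float | None = None):
        super().__init__(message)
        self.lambda_hat = lambda_hat


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class FrequencyTable:
    """Observed counts as (value, count) pairs.

    Values are unique, sorted, nonnegative integers; counts are
    nonnegative with a positive total.  Zero-count rows are preserved
    (they document the observed support but contribute nothing).
    """

    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.int64)
        vals_in = np.asarray(self.values, dtype=float)
        cnts_in = np.asarray(self.counts, dtype=float)
        if values.ndim != 1 or counts.shape != values.shape:
            raise ValueError("values and counts must be 1-d arrays of equal length")
        if np.any(vals_in != values) or np.any(cnts_in != counts):
            raise ValueError("values and counts must be integers")
        if values.size == 0:
            raise ValueError("frequency table is empty")
        if np.any(values < 0) or np.any(counts < 0):
            raise ValueError("values and counts must be nonnegative")
        if np.any(np.diff(values) <= 0):
            raise ValueError("values must be strictly increasing")
        if counts.sum() < 1:
            raise ValueError("total count must be at least 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_pairs(cls, entries) -> "FrequencyTable":
        """Build from an iterable of (value, count) pairs or a dict."""
        if isinstance(entries, dict):
            entries = sorted(entries.items())
        else:
            entries = sorted(entries)
        values = [v for v, _ in entries]
        counts = [c for _, c in entries]
        return cls(np.asarray(values), np.asarray(counts))

    @classmethod
    def from_observations(cls, obs) -> "FrequencyTable":
        """Tabulate a raw observation vector."""
        obs = np.asarray(obs)
        values, counts = np.unique(obs, return_counts=True)
        return cls(values, counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_observations(self) -> np.ndarray:
        return np.repeat(self.values, self.counts)


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient summary (N, n0, n1, xbar) of a sample."""

    n: int
    n0: int
    n1: int
    sample_mean: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("sample size must be at least 1")
        if not 0 <= self.n0 + self.n1 <= self.n:
            raise ValueError("n0 + n1 must lie in [0, N]")
        # Any integer sample satisfies xbar >= n1/N; this guards against
        # summaries not arising from real data (they would break the MLE root).
        if self.sample_mean < self.n1 / self.n - 1e-12:
            raise ValueError("sample_mean below n1/N is impossible for count data")


@dataclass(frozen=True)
class StatisticT:
    """The statistic ``T = (t1, t2)`` with ``A T = theta_hat_MLE``."""

    t1: float
    t2: float

    def asarray(self) -> np.ndarray:
        return np.array([self.t1, self.t2])


@dataclass(frozen=True)
class DesignMatrix:
    """Diagonal design matrix ``A = diag(1/2, 1/(n0 + n1))``."""

    n01: int

    def __post_init__(self) -> None:
        if self.n01 < 1:
            raise ValueError("design matrix is singular: no zeros or ones observed")

    @property
    def matrix(self) -> np.ndarray:
        return np.diag([0.5, 1.0 / self.n01])

    @property
    def inverse(self) -> np.ndarray:
        return np.diag([2.0, float(self.n01)])


@dataclass(frozen=True)
class PriorSpec:
    """Prior mean and covariance of ``theta = (lambda, phi)``.

    Any prior with finite second moment is admissible; only these two
    summaries enter the linear Bayes estimator.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mean.shape != (2,) or cov.shape != (2, 2):
            raise ValueError("prior mean must be length 2, covariance 2x2")
        if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(cov))):
            raise ValueError("prior moments must be finite")
        if not np.allclose(cov, cov.T):
            raise ValueError("prior covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("prior covariance must be positive semi-definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


@dataclass(frozen=True)
class LBComponents:
    """Building blocks of the linear Bayes estimate.

    ``w`` is the sampling dispersion of ``T``; ``m`` the inner inverse
    ``[W + A^-1 Cov(theta) (A^-1)']^-1``; ``b_mat`` and ``b_vec`` the
    coefficients of ``theta_hat = B T + b`` with ``B = A - A W M`` and
    ``b = E(theta) - B A^-1 E(theta)``.
    """

    w: np.ndarray
    m: np.ndarray
    b_mat: np.ndarray
    b_vec: np.ndarray


@dataclass(frozen=True)
class Estimate:
    """A fitted parameter pair with provenance tag and warnings."""

    method: str
    theta_hat: np.ndarray
    warnings: list = field(default_factory=list)

    @property
    def lambda_hat(self) -> float:
        return float(self.theta_hat[0])

    @property
    def phi_hat(self) -> float:
        return float(self.theta_hat[1])


@dataclass(frozen=True)
class EvalResult:
    """Mean squared error of an estimate (or set of replicates).

    ``mse_sum`` is the summed quadratic ``E[(th - t)'(th - t)]``;
    ``mse_avg`` averages over the two components (``mse_sum / 2``);
    ``msem`` is the full matrix ``E[(th - t)(th - t)']``.
    """

    mse_avg: float
    mse_sum: float
    msem: np.ndarray


# ---------------------------------------------------------------------------
# fitting


def summarize(table: FrequencyTable) -> SampleSummary:
    """Reduce a frequency table to its sufficient summary."""
    n = table.n
    n0 = int(table.counts[table.values == 0].sum())
    n1 = int(table.counts[table.values == 1].sum())
    total = int(np.dot(table.values, table.counts))
    return SampleSummary(n=n, n0=n0, n1=n1, sample_mean=total / n)


def _lambda_root(b, c):
    """Positive root of ``lam^2 - b lam - c = 0`` with ``c >= 0``.

    When ``c == 0`` (sample mean equals n1/N) the nonnegative root is
    ``max(b, 0)``; callers treat a zero root as failure. Vectorised.
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    root = 0.5 * (b + np.sqrt(b * b + 4.0 * np.maximum(c, 0.0)))
    root = np.where(c <= 0.0, np.maximum(b, 0.0), root)
    return root if root.ndim else float(root)


def _mle_arrays(n, n0, n1, xbar):
    """Vectorised MLE from summary arrays; returns (lam, phi).

    Entries with an undefined component come back as NaN rather than
    raising, for use in bootstrap / simulation loops.
    """
    n = np.asarray(n, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    xbar = np.asarray(xbar, dtype=float)
    lam = _lambda_root(xbar - 1.0 + n0 / n, xbar - n1 / n)
    lam = np.where(lam > 0.0, lam, np.nan)
    n01 = n0 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(n01 >= 1.0, (n0 - n1 / lam) / np.where(n01 >= 1, n01, 1.0), np.nan)
    return lam, phi


def mle(summary: SampleSummary, clamp: bool = False) -> Estimate:
    """Closed-form maximum-likelihood estimate of ``(lambda, phi)``.

    Parameters
    ----------
    summary : SampleSummary
    clamp : bool
        If true, a ``phi_hat`` outside ``[0, 1]`` (possible for
        one-inflated data) is truncated to the boundary; the raw value
        is kept in the warning either way.

    Raises
    ------
    EstimationError
        If the sample is all zeros (``lam_hat = 0`` degenerate) or
        contains no zeros or ones (``phi_hat`` undefined; the exception
        carries ``lambda_hat``).
    """
    n, n0, n1, xbar = summary.n, summary.n0, summary.n1, summary.sample_mean
    if xbar == 0.0:
        raise EstimationError("all observations are zero: lambda MLE degenerates to 0")
    lam = _lambda_root(xbar - 1.0 + n0 / n, xbar - n1 / n)
    if lam <= 0.0:
        raise EstimationError("likelihood maximised at lambda = 0: sample is degenerate")
    n01 = n0 + n1
    if n01 == 0:
        raise EstimationError(
            "no zeros or ones observed: phi is not identified", lambda_hat=lam
        )
    phi = (n0 - n1 / lam) / n01
    warn: list = []
    if not 0.0 <= phi <= 1.0:
        warn.append(f"phi MLE {phi:.6g} outside [0, 1]")
        if clamp:
            phi = min(max(phi, 0.0), 1.0)
            warn.append("phi clamped to [0, 1]")
    return Estimate(method="mle", theta_hat=np.array([lam, phi]), warnings=warn)


def loglik(data, params) -> float:
    """Log-likelihood of the misrecorded Poisson model.

    ``-N lam + n0 log(1 + phi lam) + n1 log(1 - phi) + (sum x) log lam
    - sum log(x_i!)``.  The factorial constant is included when ``data``
    is a :class:`FrequencyTable` and omitted (it does not affect
    maximisation) when only a :class:`SampleSummary` is given.

    Invalid parameters (``lam <= 0``, ``phi`` outside ``[0, 1]``, or
    ``phi = 1`` with ones observed) return ``-inf`` rather than raising.
    """
    if hasattr(params, "lambda_rate"):
        lam, phi = params.lambda_rate, params.misclass_prob
    else:
        lam, phi = float(params[0]), float(params[1])
    if isinstance(data, FrequencyTable):
        summary = summarize(data)
        const = -float(np.dot(gammaln(data.values + 1.0), data.counts))
    else:
        summary = data
        const = 0.0
    n, n0, n1, xbar = summary.n, summary.n0, summary.n1, summary.sample_mean
    if not np.isfinite(lam) or lam <= 0.0 or not 0.0 <= phi <= 1.0:
        return -np.inf
    if phi == 1.0 and n1 > 0:
        return -np.inf
    total = xbar * n
    ll = -n * lam + n0 * np.log1p(phi * lam) + total * np.log(lam) + const
    if n1 > 0:
        ll += n1 * np.log1p(-phi)
    return float(ll)


def statistic_and_design(summary: SampleSummary):
    """The statistic ``T`` and design matrix ``A`` with ``A T = theta_hat``.

    ``t1 = 2 lam_hat`` and ``t2 = n0 - n1 / lam_hat = (n0 + n1) phi_hat``,
    so the identity holds by construction on the same arithmetic path as
    :func:`mle`.
    """
    est = mle(summary)
    n01 = summary.n0 + summary.n1
    t = StatisticT(t1=2.0 * est.lambda_hat, t2=n01 * est.phi_hat)
    return t, DesignMatrix(n01=n01)


# ---------------------------------------------------------------------------
# bootstrap dispersion of T


def bootstrap_w(table: FrequencyTable, n_boot: int = 1000, seed=None) -> np.ndarray:
    """Bootstrap estimate of ``W = diag(Var t1, Var t2)``.

    The ``N`` observations are resampled with replacement ``n_boot``
    times (equivalently, multinomial draws over the observed support);
    ``(t1*, t2*)`` is computed from each resample's own summary and the
    diagonal of sample variances is returned.  Resamples on which the
    statistic is undefined (no zeros or ones, or an all-zero sample) are
    dropped with a warning.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = table.n
    probs = table.counts / n
    counts = rng.multinomial(n, probs, size=n_boot)  # (n_boot, k)
    values = table.values.astype(float)
    n0 = counts[:, table.values == 0].sum(axis=1)
    n1 = counts[:, table.values == 1].sum(axis=1)
    xbar = counts @ values / n
    lam, _ = _mle_arrays(np.full(n_boot, n), n0, n1, xbar)
    valid = np.isfinite(lam) & (n0 + n1 >= 1)
    n_bad = int(n_boot - valid.sum())
    if n_bad:
        _warnings.warn(
            f"dropped {n_bad} bootstrap resamples with undefined statistic",
            RuntimeWarning,
            stacklevel=2,
        )
    if valid.sum() < 2:
        raise EstimationError("fewer than 2 valid bootstrap resamples")
    t1 = 2.0 * lam[valid]
    t2 = n0[valid] - n1[valid] / lam[valid]
    return np.diag([float(np.var(t1, ddof=1)), float(np.var(t2, ddof=1))])


# ---------------------------------------------------------------------------
# linear Bayes


def _inv2(mat: np.ndarray, name: str) -> np.ndarray:
    """Closed-form 2x2 inverse with an explicit singularity diagnostic."""
    a, b = mat[0, 0], mat[0, 1]
    c, d = mat[1, 0], mat[1, 1]
    det = a * d - b * c
    if not np.isfinite(det) or abs(det) < 1e-300:
        raise EstimationError(f"matrix {name} is singular (det = {det:.3g})")
    return np.array([[d, -b], [-c, a]]) / det


def linear_bayes(t: StatisticT, a: DesignMatrix, w: np.ndarray, prior: PriorSpec):
    """Linear Bayes estimate ``theta_hat = B T + b``.

    ``M = [W + A^-1 Cov(theta) (A^-1)']^-1``, ``B = A - A W M`` and
    ``b = E(theta) - B A^-1 E(theta)``; equivalently the estimate is
    ``(A - A W M) T + A W M A^-1 E(theta)``, a shrinkage of the MLE
    ``A T`` toward the prior mean with weight growing in ``W`` and
    shrinking in the prior covariance.

    Returns ``(Estimate, LBComponents)``.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (2, 2):
        raise ValueError("w must be a 2x2 matrix")
    a_mat, a_inv = a.matrix, a.inverse
    inner = w + a_inv @ prior.cov @ a_inv.T
    m = _inv2(inner, "W + A^-1 Cov(theta) (A^-1)'")
    b_mat = a_mat - a_mat @ w @ m
    b_vec = prior.mean - b_mat @ (a_inv @ prior.mean)
    theta = b_mat @ t.asarray() + b_vec
    warn: list = []
    if not 0.0 <= theta[1] <= 1.0:
        warn.append(f"phi LB {theta[1]:.6g} outside [0, 1]")
    if theta[0] <= 0.0:
        warn.append(f"lambda LB {theta[0]:.6g} not positive")
    comps = LBComponents(w=w, m=m, b_mat=b_mat, b_vec=b_vec)
    return Estimate(method="linear_bayes", theta_hat=theta, warnings=warn), comps


# ---------------------------------------------------------------------------
# evaluation


def _theta_matrix(est) -> np.ndarray:
    if isinstance(est, Estimate):
        return est.theta_hat[None, :]
    if isinstance(est, (list, tuple)) and est and isinstance(est[0], Estimate):
        return np.vstack([e.theta_hat for e in est])
    arr = np.atleast_2d(np.asarray(est, dtype=float))
    if arr.shape[1] != 2:
        raise ValueError("estimates must be 2-vectors")
    return arr


def evaluate(est, truth) -> EvalResult:
    """Squared-error evaluation of one estimate or a set of replicates.

    ``msem`` is the average outer product of errors over replicates;
    ``mse_sum`` its trace (the summed quadratic form) and ``mse_avg``
    the per-component average ``mse_sum / 2``.
    """
    theta = _theta_matrix(est)
    truth = np.asarray(truth, dtype=float)
    if truth.shape != (2,):
        raise ValueError("truth must be a 2-vector")
    if not np.all(np.isfinite(theta)):
        raise ValueError("estimates must be finite")
    err = theta - truth
    msem = err.T @ err / err.shape[0]
    mse_sum = float(np.trace(msem))
    return EvalResult(mse_avg=mse_sum / 2.0, mse_sum=mse_sum, msem=msem)


def msem_ordering_check(a: DesignMatrix, w: np.ndarray, m: np.ndarray) -> float:
    """Smallest eigenvalue of the theoretical MSEM gap ``A W M W A'``.

    Under the joint model the MSE matrix of the MLE is ``A W A'`` and
    that of the linear Bayes estimate is ``A (W - W M W) A'``; their
    difference ``A W M W A'`` is positive semi-definite, so the returned
    eigenvalue is nonnegative up to roundoff.
    """
    a_mat = a.matrix
    diff = a_mat @ w @ m @ w @ a_mat.T
    return float(np.min(np.linalg.eigvalsh(0.5 * (diff + diff.T))))
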