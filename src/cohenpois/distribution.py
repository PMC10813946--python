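"""The misrecorded (Cohen) Poisson distribution.

The model describes count data in which a recorder sometimes fails to
notice a single event: a true count ``Y ~ Poisson(lambda)`` is reported
faithfully unless ``Y == 1``, in which case it is written down as ``0``
with probability ``phi``.  The resulting law is zero-inflated and
one-deflated relative to the plain Poisson with the same intensity::

    P(X = 0) = exp(-lam) * (1 + lam * phi)
    P(X = 1) = exp(-lam) * lam * (1 - phi)
    P(X = x) = exp(-lam) * lam**x / x!          for x >= 2

``phi = 0`` recovers the Poisson distribution; ``phi = 1`` is the
zero-one modified case in which every true one is reported as zero.

Because misrecording only moves probability mass ``lam * phi * exp(-lam)``
from ``x = 1`` to ``x = 0``, every raw moment equals the Poisson raw
moment minus that same mass (the unit contribution of the deleted ones).
All moment formulas here are derived from the mass function and verified
against direct series summation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln


@dataclass(frozen=True)
class ModelParams:
    """Parameter pair of the misrecorded Poisson law.

    Parameters
    ----------
    lambda_rate : float
        Poisson intensity ``lambda > 0``.
    misclass_prob : float
        Probability ``phi`` in ``[0, 1]`` that a true count of one is
        recorded as zero.  The closed endpoints are admitted so the
        Poisson (``phi = 0``) and zero-one modified (``phi = 1``)
        reductions are representable.
    """

    lambda_rate: float
    misclass_prob: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_rate) or self.lambda_rate <= 0:
            raise ValueError(f"lambda_rate must be positive, got {self.lambda_rate}")
        if not 0.0 <= self.misclass_prob <= 1.0:
            raise ValueError(f"misclass_prob must lie in [0, 1], got {self.misclass_prob}")


@dataclass(frozen=True)
class MomentSet:
    """Mean, variance and raw moments ``E[X^k]`` for ``k = 2, 3, 4``."""

    mean: float
    variance: float
    raw2: float
    raw3: float
    raw4: float


@dataclass(frozen=True)
class Perturbations:
    """Departure of the zero and one probabilities from the plain Poisson.

    ``zero_inflation`` is ``lam * phi * exp(-lam)`` (excess mass at zero)
    and ``one_deflation`` is its negative (the matching deficit at one).
    """

    zero_inflation: float
    one_deflation: float


def _check_support(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.integer):
        xf = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(xf)) or not np.all(xf == np.floor(xf)):
            raise ValueError("x must contain nonnegative integers")
        x = xf.astype(np.int64)
    if np.any(x < 0):
        raise ValueError("x must contain nonnegative integers")
    return x


def logpmf(x, params: ModelParams):
    """Log of the probability mass function, vectorised over ``x``.

    Safe for large ``lambda`` or ``x`` where the direct mass underflows.
    """
    x = _check_support(x)
    lam, phi = params.lambda_rate, params.misclass_prob
    xf = x.astype(float)
    # Poisson log-mass; overwritten at the two modified support points.
    out = -lam + xf * np.log(lam) - gammaln(xf + 1.0)
    out = np.where(x == 0, -lam + np.log1p(lam * phi), out)
    if phi == 1.0:
        one_term = -np.inf
    else:
        one_term = -lam + np.log(lam) + np.log1p(-phi)
    out = np.where(x == 1, one_term, out)
    return out if out.ndim else float(out)


def pmf(x, params: ModelParams):
    """Probability mass function ``P(X = x)``, vectorised over ``x``."""
    return np.exp(logpmf(x, params))


def support_upper(params: ModelParams, tail_mass: float = 1e-12) -> int:
    """Smallest truncation point ``X*`` leaving Poisson tail mass below
    ``tail_mass``.  Beyond ``x = 1`` the law coincides with the Poisson,
    so the Poisson survival function bounds the truncation error."""
    lam = params.lambda_rate
    hi = int(np.ceil(lam + 20.0 * np.sqrt(lam) + 20.0))
    while stats.poisson.sf(hi, lam) >= tail_mass:
        hi *= 2
    return hi


def moments(params: ModelParams) -> MomentSet:
    """Closed-form moments.

    With ``a = phi * exp(-lam)`` each raw moment is the Poisson raw
    moment minus ``lam * a``::

        E X   = lam (1 - a)
        E X^2 = lam^2 + lam (1 - a)
        E X^3 = lam^3 + 3 lam^2 + lam (1 - a)
        E X^4 = lam^4 + 6 lam^3 + 7 lam^2 + lam (1 - a)

    and ``Var X = E X^2 - (E X)^2``.
    """
    lam, phi = params.lambda_rate, params.misclass_prob
    a = phi * np.exp(-lam)
    mean = lam * (1.0 - a)
    raw2 = lam**2 + lam * (1.0 - a)
    raw3 = lam**3 + 3.0 * lam**2 + lam * (1.0 - a)
    raw4 = lam**4 + 6.0 * lam**3 + 7.0 * lam**2 + lam * (1.0 - a)
    return MomentSet(mean=mean, variance=raw2 - mean**2, raw2=raw2, raw3=raw3, raw4=raw4)


def pgf(s, params: ModelParams):
    """Probability generating function ``G(s) = E[s^X]``.

    ``G(s) = exp(lam (s - 1)) + lam phi exp(-lam) (1 - s)``: the Poisson
    generating function plus the linear correction from moving mass
    ``lam phi exp(-lam)`` from ``s^1`` to ``s^0``.  Defined for all real
    ``s`` (the series converges everywhere); the usual domain is
    ``|s| <= 1``.
    """
    lam, phi = params.lambda_rate, params.misclass_prob
    s = np.asarray(s, dtype=float)
    out = np.exp(lam * (s - 1.0)) + lam * phi * np.exp(-lam) * (1.0 - s)
    return out if out.ndim else float(out)


def perturbations(params: ModelParams) -> Perturbations:
    """Zero-inflation / one-deflation relative to ``Poisson(lambda)``."""
    lam, phi = params.lambda_rate, params.misclass_prob
    shift = lam * phi * np.exp(-lam)
    return Perturbations(zero_inflation=shift, one_deflation=-shift)


def sample(n: int, params: ModelParams, seed) -> np.ndarray:
    """Draw ``n`` observations by the misrecording mechanism.

    A Poisson(lambda) count is drawn for each observation; counts equal
    to one are independently replaced by zero with probability ``phi``.
    This mirrors the data-generating story exactly (rather than inverting
    the CDF) and is O(1) per draw.

    Parameters
    ----------
    n : int
        Number of observations, ``n >= 0``.
    params : ModelParams
    seed : int or numpy.random.Generator
        Required source of randomness; fixed seed gives identical output.
    """
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = rng.poisson(params.lambda_rate, size=n)
    if params.misclass_prob > 0 and n > 0:
        ones = y == 1
        hide = ones & (rng.random(n) < params.misclass_prob)
        y = np.where(hide, 0, y)
    return y.astype(np.int64)
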