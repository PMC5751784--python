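"""Generalized Poisson observation model and the posterior of the true count.

The observation model: sequencing draws ``S`` fragments without replacement
from a pool of ``N``, so the observed count ``x`` of a gene with true count
``k`` is hypergeometric. For large ``N`` this is well approximated by a
Generalized Poisson (GP) distribution with parameters

    lambda1 = b * k * sqrt(m),    lambda2 = 1 - sqrt(m),

where ``b = S/N`` is the sample coverage and ``m = 1/(1-b)`` is the
mean-to-variance ratio. The GP mean is ``b*k`` and its variance ``b*k/m``;
``m > 1`` gives underdispersion (variance below the mean), the signature of
sampling without replacement. At ``m = 1`` the GP reduces to Poisson(b*k).

Inverting the model under a uniform prior on the true count gives a proper
posterior P(T=k | X=x, b), computed here two ways:

* :func:`posterior_pmf_bruteforce` — term-by-term summation of the exact
  posterior over a truncated support; slow, used as the reference.
* :func:`posterior_gamma` — a closed-form gamma approximation with

      mu      ~= (x+1)/b - (1 + 1/(2b))^{-1}
      sigma^2 ~= (x+1) / (b(b+1))^2

  which is the production path: its quantiles are cheap and feed the
  differential-expression decision rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import gamma as _gamma_dist

from .errors import CoverageError, GPValidityWarning, ParameterError, TruncationError

__all__ = [
    "GPParams",
    "PosteriorGamma",
    "PosteriorPMF",
    "gp_pmf",
    "mean_variance_ratio",
    "posterior_pmf_bruteforce",
    "posterior_gamma",
    "posterior_percentile",
]

#: Coverage at which m = 1/(1-b) reaches 4, the edge of GP validity
#: (|lambda2| < 1 requires m < 4).
_GP_VALIDITY_COVERAGE = 0.75


def _check_coverage(b: float) -> None:
    if not (0.0 < b < 1.0):
        raise CoverageError(
            f"coverage b={b!r} outside (0, 1); the method is not recommended "
            "if the estimated coverage is one or more"
        )


def mean_variance_ratio(b: float) -> float:
    """Mean-to-variance ratio ``m = 1/(1-b)`` implied by coverage ``b``.

    Sampling S of N fragments without replacement yields hypergeometric
    counts whose mean/variance ratio is (N/(N-k))((N-1)/(N-S)) ~= N/(N-S)
    = 1/(1-b) for true counts k much smaller than N. For small b this is
    approximately 1 + b (near-Poisson regime).

    Warns when b >= 0.75 (m >= 4), where the GP parameterisation leaves
    its validity region.
    """
    _check_coverage(b)
    m = 1.0 / (1.0 - b)
    if m >= 4.0:
        warnings.warn(
            f"coverage b={b} implies mean-variance ratio m={m:.3f} >= 4, "
            "outside the Generalized Poisson validity region (0 < m < 4)",
            GPValidityWarning,
            stacklevel=2,
        )
    return m


@dataclass(frozen=True)
class GPParams:
    """Generalized Poisson parameters for one (coverage, true count) pair.

    ``lambda1 = b*k*sqrt(m)`` and ``lambda2 = 1 - sqrt(m)`` so that the GP
    mean is ``b*k`` and the variance ``b*k/m``.
    """

    lambda1: float
    lambda2: float
    m: float
    b: float
    k: int

    def __post_init__(self):
        if not (self.lambda1 > 0):
            raise ParameterError(f"lambda1 must be positive, got {self.lambda1}")
        if self.m <= 0:
            raise ParameterError(f"mean-variance ratio m must be positive, got {self.m}")
        if not (0.0 < self.b < 1.0):
            raise CoverageError(f"coverage b={self.b!r} outside (0, 1)")
        if self.k < 1 or int(self.k) != self.k:
            raise ParameterError(f"true count k must be a positive integer, got {self.k}")
        if abs(self.lambda2) >= 1.0:
            warnings.warn(
                f"|lambda2|={abs(self.lambda2):.3f} >= 1 (m={self.m:.3f} outside "
                "(0, 4)); GP probabilities may be unreliable",
                GPValidityWarning,
                stacklevel=3,
            )

    @classmethod
    def from_coverage(cls, b: float, k: int, m: float | None = None) -> "GPParams":
        """Build GP parameters from coverage and true count.

        ``m`` defaults to ``1/(1-b)``, the ratio implied by sampling
        without replacement; pass ``m=1`` for the Poisson special case.
        """
        if m is None:
            m = mean_variance_ratio(b)
        sm = math.sqrt(m)
        return cls(lambda1=b * k * sm, lambda2=1.0 - sm, m=m, b=b, k=int(k))

    @property
    def mean(self) -> float:
        return self.lambda1 / (1.0 - self.lambda2)

    @property
    def variance(self) -> float:
        return self.lambda1 / (1.0 - self.lambda2) ** 3


def gp_pmf(x, params: GPParams):
    """Generalized Poisson probability P(X=x | T=k).

    Evaluated in log space (counts can reach 1e5). For lambda2 < 0
    (underdispersion) the pmf is set to zero wherever
    ``lambda1 + x*lambda2 <= 0``, the standard truncated-GP convention;
    no renormalisation is applied here.

    ``x`` may be a scalar or array of non-negative integers.
    """
    x_arr = np.asarray(x)
    if np.any(x_arr < 0) or not np.issubdtype(x_arr.dtype, np.integer) and np.any(
        x_arr != np.floor(x_arr)
    ):
        raise ParameterError("x must contain non-negative integers")
    xf = x_arr.astype(float)
    l1, l2 = params.lambda1, params.lambda2
    base = l1 + xf * l2
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (
            math.log(l1)
            + (xf - 1.0) * np.log(base)
            - (l1 + xf * l2)
            - gammaln(xf + 1.0)
        )
    out = np.where(base > 0, np.exp(logp), 0.0)
    if np.ndim(x) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Exact (brute-force) posterior


@dataclass(frozen=True)
class PosteriorPMF:
    """Truncated, renormalised exact posterior of the true count.

    The support runs over integers ``support_min .. k_max``;
    ``truncation_mass_bound`` bounds the posterior mass discarded beyond
    ``k_max`` (geometric tail bound, relative to the retained mass).
    """

    x: int
    b: float
    support_min: int
    k_max: int
    probs: np.ndarray = field(repr=False)
    truncation_mass_bound: float

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.support_min, self.k_max + 1)

    def mean(self) -> float:
        return float(np.sum(self.support * self.probs))

    def var(self) -> float:
        mu = self.mean()
        return float(np.sum((self.support - mu) ** 2 * self.probs))

    def mode(self) -> int:
        return int(self.support[np.argmax(self.probs)])


def _log_posterior_terms(k: np.ndarray, x: int, b: float, sqrt_m: float) -> np.ndarray:
    """Log of the unnormalised posterior term k*(bk*sm + x(1-sm))^{x-1} e^{-bk*sm}."""
    base = b * k * sqrt_m + x * (1.0 - sqrt_m)
    with np.errstate(divide="ignore"):
        logt = np.log(k) + (x - 1.0) * np.log(base) - b * k * sqrt_m
    return np.where(base > 0, logt, -np.inf)


def posterior_pmf_bruteforce(
    x: int, b: float, tol: float = 1e-10, max_terms: int = 5_000_000
) -> PosteriorPMF:
    """Exact posterior of the true count by term-by-term summation.

    The infinite normalising sum is truncated at an initial bound
    ``ceil(mu + 12*sigma)`` taken from the gamma approximation and then
    extended until a geometric bound on the discarded tail mass falls
    below ``tol`` (relative to the retained mass). The support starts at
    ``max(x, 1)``: the prior is uniform over 1, 2, ..., so for x = 0 the
    posterior still starts at 1.

    This is the reference implementation the gamma approximation is
    validated against; it is not the production path.
    """
    if int(x) != x or x < 0:
        raise ParameterError(f"x must be a non-negative integer, got {x}")
    if tol <= 0:
        raise ParameterError(f"tol must be positive, got {tol}")
    x = int(x)
    m = mean_variance_ratio(b)
    sm = math.sqrt(m)
    k_min = max(x, 1)

    pg = posterior_gamma(x, b)
    k_max = max(k_min + 100, int(math.ceil(pg.mu + 12.0 * math.sqrt(pg.sigma2))))

    while True:
        k = np.arange(k_min, k_max + 1, dtype=float)
        logt = _log_posterior_terms(k, x, b, sm)
        log_total = logsumexp(logt)
        # geometric tail bound from the ratio of the last two terms
        ratio = math.exp(logt[-1] - logt[-2]) if logt[-2] > -np.inf else 0.0
        if ratio < 1.0:
            log_tail = logt[-1] + math.log(ratio / (1.0 - ratio)) if ratio > 0 else -np.inf
            tail_bound = math.exp(log_tail - log_total)
        else:
            tail_bound = math.inf
        if tail_bound < tol:
            break
        if k.size >= max_terms:
            raise TruncationError(
                f"posterior truncation did not reach tol={tol} within "
                f"{max_terms} terms (achieved tail-mass bound {tail_bound:.3e})",
                achieved_bound=tail_bound,
            )
        k_max = k_min + 2 * (k_max - k_min)

    probs = np.exp(logt - log_total)
    probs /= probs.sum()
    return PosteriorPMF(
        x=x,
        b=b,
        support_min=k_min,
        k_max=int(k_max),
        probs=probs,
        truncation_mass_bound=tail_bound,
    )


# ---------------------------------------------------------------------------
# Gamma approximation (production path)


@dataclass(frozen=True)
class PosteriorGamma:
    """Gamma approximation to the posterior of the true count.

    ``shape = mu^2/sigma2`` and ``scale = sigma2/mu``, so that the gamma
    has exactly the approximated mean and variance.
    """

    x: int
    b: float
    mu: float
    sigma2: float
    shape: float
    scale: float

    def percentile(self, q: float) -> float:
        return posterior_percentile(self, q)

    def cdf(self, k) -> float:
        return _gamma_dist.cdf(k, self.shape, scale=self.scale)


def _gamma_moments(x, b):
    """Vectorised (mu, sigma2) of the approximating gamma; no validation."""
    x = np.asarray(x, dtype=float)
    b = np.asarray(b, dtype=float)
    mu = (x + 1.0) / b - 1.0 / (1.0 + 1.0 / (2.0 * b))
    sigma2 = (x + 1.0) / (b * (b + 1.0)) ** 2
    return mu, sigma2


def _gamma_shape_scale(x, b):
    """Vectorised (shape, scale) of the approximating gamma; no validation."""
    mu, sigma2 = _gamma_moments(x, b)
    return mu * mu / sigma2, sigma2 / mu


def posterior_gamma(x: int, b: float) -> PosteriorGamma:
    """Gamma approximation to the posterior of the true count given (x, b).

    Defined for all x >= 0 (at x = 0 the mean is still positive: some
    copies of the gene may exist even when none were sequenced).
    """
    if int(x) != x or x < 0:
        raise ParameterError(f"x must be a non-negative integer, got {x}")
    _check_coverage(b)
    mu, sigma2 = _gamma_moments(x, b)
    mu, sigma2 = float(mu), float(sigma2)
    return PosteriorGamma(
        x=int(x), b=b, mu=mu, sigma2=sigma2, shape=mu * mu / sigma2, scale=sigma2 / mu
    )


def posterior_percentile(pg: PosteriorGamma, q: float) -> float:
    """q-quantile of the approximating gamma posterior, 0 < q < 1."""
    if not (0.0 < q < 1.0):
        raise ParameterError(f"quantile level q={q!r} outside (0, 1)")
    return float(_gamma_dist.ppf(q, pg.shape, scale=pg.scale))
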