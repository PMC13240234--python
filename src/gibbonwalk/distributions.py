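"""Step-length, turning-angle and dwell-time distributions.

Every movement model in this package is assembled from the parametric
families below: exponential and Weibull step lengths for ballistic /
area-restricted phases, the truncated Pareto for Lévy-type searches,
von Mises and wrapped Cauchy circular laws for directional persistence,
and a shifted Poisson for behavioral-phase residence times (support
starts at one step, so a phase always emits at least one observation).

Each family exposes ``logpdf``/``pdf`` (or ``logpmf``), ``cdf``,
``sample`` and, where meaningful, ``mean``.  Densities are per metre
(steps) or per radian (angles).  Log-densities are floored at
``LOG_FLOOR`` so a single outlying observation cannot poison a whole
likelihood with ``-inf``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import special, stats

__all__ = [
    "Exponential",
    "TruncatedPareto",
    "Weibull",
    "VonMises",
    "WrappedCauchy",
    "ShiftedPoisson",
    "fit_exponential",
    "fit_truncated_pareto",
    "fit_weibull",
    "LOG_FLOOR",
    "UNIFORM_ANGLE_LOGPDF",
]

#: floor for log-densities; exp(-745) is the smallest positive double
LOG_FLOOR = -745.0

#: log-density of the circular uniform law v0(h) = 1/(2*pi)
UNIFORM_ANGLE_LOGPDF = -np.log(2.0 * np.pi)

#: concentration cap keeping the wrapped Cauchy away from the rho -> 1 boundary
RHO_MAX = 1.0 - 1e-6


def _floor(logp):
    return np.maximum(logp, LOG_FLOOR)


@dataclass(frozen=True)
class Exponential:
    """Exponential step-length law with rate ``rate`` (1/m); mean = 1/rate."""

    rate: float

    def __post_init__(self):
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(invalid="ignore"):
            lp = np.where(x >= 0, np.log(self.rate) - self.rate * x, -np.inf)
        return _floor(lp)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, -np.expm1(-self.rate * np.maximum(x, 0.0)), 0.0)

    def mean(self):
        return 1.0 / self.rate

    def sample(self, n, rng):
        return rng.exponential(scale=1.0 / self.rate, size=n)


@dataclass(frozen=True)
class TruncatedPareto:
    """Truncated Pareto (power-law) step lengths on the finite support [a, b].

    Density ``w(l) = (mu-1) a^(mu-1) l^(-mu) / (1 - (a/b)^(mu-1))`` for
    exponent ``mu != 1``; the ``mu == 1`` limit is ``1 / (l log(b/a))``.
    Heavy tails (small ``mu``) put appreciable mass on rare long steps,
    the signature of a Lévy-type search bounded by the arena/home range.
    """

    mu: float
    a: float
    b: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > self.a):
            raise ValueError(f"need 0 < a < b, got a={self.a}, b={self.b}")
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")

    def _log_norm(self):
        # log of the normalizing constant C with w(l) = C * l^(-mu)
        m, a, b = self.mu, self.a, self.b
        if abs(m - 1.0) < 1e-9:
            return -np.log(np.log(b / a))
        # (mu-1) a^(mu-1) / (1-(a/b)^(mu-1)); stable for both mu<1 and mu>1
        num = np.log(abs(m - 1.0)) + (m - 1.0) * np.log(a)
        den = np.log(abs(1.0 - (a / b) ** (m - 1.0)))
        return num - den

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= self.a) & (x <= self.b)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(inside, self._log_norm() - self.mu * np.log(x), -np.inf)
        return _floor(lp)

    def pdf(self, x):
        lp = self.logpdf(np.asarray(x, dtype=float))
        out = np.exp(lp)
        # undo the floor outside the support: density is exactly zero there
        x = np.asarray(x, dtype=float)
        return np.where((x >= self.a) & (x <= self.b), out, 0.0)

    def cdf(self, x):
        x = np.clip(np.asarray(x, dtype=float), self.a, self.b)
        m, a, b = self.mu, self.a, self.b
        if abs(m - 1.0) < 1e-9:
            return np.log(x / a) / np.log(b / a)
        return (1.0 - (a / x) ** (m - 1.0)) / (1.0 - (a / b) ** (m - 1.0))

    def sample(self, n, rng):
        u = rng.uniform(size=n)
        m, a, b = self.mu, self.a, self.b
        if abs(m - 1.0) < 1e-9:
            return a * np.exp(u * np.log(b / a))
        return a * (1.0 - u * (1.0 - (a / b) ** (m - 1.0))) ** (-1.0 / (m - 1.0))


@dataclass(frozen=True)
class Weibull:
    """Weibull step lengths; ``shape == 1`` reduces to the exponential."""

    shape: float
    scale: float

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(
                f"shape and scale must be > 0, got {self.shape}, {self.scale}"
            )

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        k, lam = self.shape, self.scale
        with np.errstate(divide="ignore", invalid="ignore"):
            z = x / lam
            lp = np.where(
                x > 0,
                np.log(k / lam) + (k - 1.0) * np.log(z) - z**k,
                -np.inf,
            )
        return _floor(lp)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, -np.expm1(-((np.maximum(x, 0.0) / self.scale) ** self.shape)), 0.0)

    def mean(self):
        return self.scale * special.gamma(1.0 + 1.0 / self.shape)

    def sample(self, n, rng):
        return self.scale * rng.weibull(self.shape, size=n)


@dataclass(frozen=True)
class VonMises:
    """von Mises turning angles centered at 0; ``kappa == 0`` is circular uniform."""

    kappa: float
    mean_direction: float = 0.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")

    def logpdf(self, theta):
        theta = np.asarray(theta, dtype=float)
        k = self.kappa
        # log I0(k) = log(i0e(k)) + k is stable for large k
        log_i0 = np.log(special.i0e(k)) + k
        return _floor(k * np.cos(theta - self.mean_direction) - np.log(2 * np.pi) - log_i0)

    def pdf(self, theta):
        return np.exp(self.logpdf(theta))

    def cdf(self, theta):
        theta = np.asarray(theta, dtype=float)
        if self.kappa == 0:
            return (theta + np.pi) / (2 * np.pi)
        return stats.vonmises.cdf(theta, self.kappa, loc=self.mean_direction)

    def mean_resultant_length(self):
        if self.kappa == 0:
            return 0.0
        return float(special.i1e(self.kappa) / special.i0e(self.kappa))

    def sample(self, n, rng):
        if self.kappa == 0:
            return rng.uniform(-np.pi, np.pi, size=n)
        return np.asarray(
            stats.vonmises.rvs(
                self.kappa, loc=self.mean_direction, size=n, random_state=rng
            )
        )


@dataclass(frozen=True)
class WrappedCauchy:
    """Wrapped Cauchy turning angles centered at 0.

    ``rho`` is both the concentration parameter and the mean resultant
    length; 0 gives the circular uniform law, values near 1 a tightly
    directed walk.
    """

    rho: float
    mean_direction: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")

    def logpdf(self, theta):
        theta = np.asarray(theta, dtype=float) - self.mean_direction
        r = self.rho
        lp = (
            np.log1p(-(r**2))
            - np.log(2 * np.pi)
            - np.log1p(r**2 - 2.0 * r * np.cos(theta))
        )
        return _floor(lp)

    def pdf(self, theta):
        return np.exp(self.logpdf(theta))

    def cdf(self, theta):
        """CDF on (-pi, pi] (mean direction 0 assumed for the closed form)."""
        theta = np.asarray(theta, dtype=float) - self.mean_direction
        r = self.rho
        return 0.5 + np.arctan2((1 + r) * np.sin(theta / 2.0), (1 - r) * np.cos(theta / 2.0)) / np.pi

    def mean_resultant_length(self):
        return self.rho

    def sample(self, n, rng):
        u = rng.uniform(size=n)
        r = self.rho
        # inverse CDF of the centered wrapped Cauchy
        theta = 2.0 * np.arctan(((1 - r) / (1 + r)) * np.tan(np.pi * (u - 0.5)))
        return theta + self.mean_direction


@dataclass(frozen=True)
class ShiftedPoisson:
    """Residence-time (dwell) law: 1 + Poisson(lambda), support {1, 2, ...}.

    The shift guarantees a behavioral phase lasts at least one step;
    mean dwell = 1 + lambda.  ``lambda == 0`` collapses to a deterministic
    one-step dwell (strict phase alternation).
    """

    lam: float

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")

    def pmf(self, d):
        d = np.asarray(d)
        if np.any(d < 1):
            raise ValueError("dwell must be >= 1 step")
        return stats.poisson.pmf(d - 1, self.lam)

    def logpmf(self, d):
        d = np.asarray(d)
        if np.any(d < 1):
            raise ValueError("dwell must be >= 1 step")
        return _floor(stats.poisson.logpmf(d - 1, self.lam))

    def sf_geq(self, d):
        """P(D >= d) for integer d >= 1."""
        d = np.asarray(d)
        return stats.poisson.sf(d - 2, self.lam)

    def mean(self):
        return 1.0 + self.lam

    def quantile(self, q):
        return int(1 + stats.poisson.ppf(q, self.lam))

    def residual_pmf(self, d):
        """Equilibrium residual-life pmf: P(R = d) = P(D >= d) / E[D].

        The distribution of the remaining dwell when a stationary
        alternating process is cut at an arbitrary time.
        """
        d = np.asarray(d)
        return self.sf_geq(d) / self.mean()

    def sample_residual(self, n, rng):
        top = max(self.quantile(1.0 - 1e-12) + 2, 3)
        support = np.arange(1, top + 1)
        p = self.residual_pmf(support)
        p = p / p.sum()
        return rng.choice(support, size=n, p=p)

    def hazard(self, m):
        """Discrete hazard h(j) = P(D = j | D >= j) for j = 1..m."""
        j = np.arange(1, m + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = self.pmf(j) / self.sf_geq(j)
        return np.clip(np.nan_to_num(h, nan=1.0), 0.0, 1.0)

    def sample(self, n, rng):
        return 1 + rng.poisson(self.lam, size=n)


# ---------------------------------------------------------------------------
# maximum-likelihood fits
# ---------------------------------------------------------------------------


def fit_exponential(steps) -> Exponential:
    """Closed-form MLE: rate = 1 / mean(steps)."""
    steps = np.asarray(steps, dtype=float)
    if steps.size < 1 or not np.all(steps > 0):
        raise ValueError("need at least one strictly positive step")
    return Exponential(rate=1.0 / steps.mean())


def fit_truncated_pareto(steps, a=None, b=None, mu_max=20.0):
    """MLE of the truncated-Pareto exponent on empirical support.

    ``a``/``b`` default to the smallest/largest observed step (the
    standard empirical-support convention for truncated power laws) and
    are recorded in the returned parameter object, not counted as free
    parameters.  The exponent is found by golden-section search refined
    from a coarse grid; exact ties resolve to the smaller ``mu``.
    """
    from scipy.optimize import minimize_scalar

    steps = np.asarray(steps, dtype=float)
    if steps.size < 2:
        raise ValueError("need at least two steps")
    a = float(steps.min()) if a is None else float(a)
    b = float(steps.max()) if b is None else float(b)
    if not b > a:
        raise ValueError("degenerate sample: all steps equal")
    if np.any(steps < a) or np.any(steps > b):
        raise ValueError("steps outside the stated [a, b] support")

    sum_log = float(np.log(steps).sum())
    n = steps.size

    def nll(mu):
        return -(n * TruncatedPareto(mu, a, b)._log_norm() - mu * sum_log)

    grid = np.linspace(1.0 + 1e-6, mu_max, 400)
    vals = np.array([nll(m) for m in grid])
    i = int(np.argmin(vals))  # argmin takes the first minimum: ties -> smaller mu
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    mu_hat = float(res.x) if res.fun <= vals[i] else float(grid[i])
    return TruncatedPareto(mu=mu_hat, a=a, b=b)


def fit_weibull(steps) -> Weibull:
    """Weibull MLE via the profile (one-dimensional) shape equation."""
    from scipy.optimize import brentq

    steps = np.asarray(steps, dtype=float)
    if steps.size < 2 or not np.all(steps > 0):
        raise ValueError("need at least two strictly positive steps")
    # rescale by the max: the profile score is scale-invariant and x^k
    # would overflow for large shapes otherwise
    scaled = steps / steps.max()
    logs = np.log(scaled)

    def score(k):
        xk = scaled**k
        return xk @ logs / xk.sum() - 1.0 / k - logs.mean()

    k_hat = brentq(score, 1e-3, 1e3, xtol=1e-10)
    scale = (np.mean(steps**k_hat)) ** (1.0 / k_hat)
    return Weibull(shape=float(k_hat), scale=float(scale))


def params_to_json(params) -> str:
    """Serialize any distribution parameter object to a JSON string."""
    return json.dumps({"family": type(params).__name__, "params": asdict(params)})
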