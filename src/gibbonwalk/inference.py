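"""Maximum-likelihood fitting, AICc model selection and state summaries.

Fitting works on an unconstrained transformed scale (log for positive
parameters, logit for probabilities/concentrations) with a moment-based
start plus a fixed Latin-grid multi-start, because the CCRW likelihoods
are multimodal.  Model comparison uses the small-sample-corrected
Akaike information criterion

    AICc = -2 loglik + 2k + 2k(k+1) / (n - k - 1)

with n = total number of steps, and Akaike weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).

Confidence intervals come from profile likelihood: the interval where
the profile log-likelihood stays within chi2_1(level)/2 of its maximum.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, is_dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distributions import (
    Exponential,
    ShiftedPoisson,
    TruncatedPareto,
    VonMises,
    Weibull,
    WrappedCauchy,
    fit_exponential,
    fit_truncated_pareto,
)
from .likelihoods import (
    BwParams,
    CcrwoParams,
    CcrwpParams,
    Observations,
    TlwParams,
    loglik as _loglik,
    loglik_ccrwo,
    loglik_ccrwp,
    markov_stationary,
)

__all__ = [
    "ModelFit",
    "StateSummary",
    "FitOptions",
    "MODELS",
    "fit_model",
    "aicc",
    "akaike_weights",
    "model_comparison",
    "best_model",
    "profile_ci",
    "state_summary",
]

MODELS = ("BW", "TLW", "CCRWo", "CCRWp")

#: fixed sub-state count used while optimizing the HSMM, so the objective
#: does not jump when the dwell quantile crosses an integer; covers the
#: 0.999 dwell quantile everywhere inside the lambda box below
_FIT_DWELL_STATES = 160


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class FitOptions:
    """Optimizer engineering knobs (not study conditions).

    All starts get a short exploratory run; the most promising
    ``n_polish`` are polished to convergence.
    """

    n_grid_starts: int = 8
    pre_iter: int = 20
    n_polish: int = 2
    polish_iter: int = 400
    gtol: float = 1e-6


@dataclass
class ModelFit:
    model: str
    params: object
    loglik: float
    k: int
    n: int
    aicc: float
    akaike_weight: Optional[float] = None
    convergence: dict = field(default_factory=dict)
    profile_cis: Optional[dict] = None

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if is_dataclass(v):
                return {kk: conv(vv) for kk, vv in asdict(v).items()}
            return v

        return {
            "model": self.model,
            "params": conv(self.params),
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "akaike_weight": self.akaike_weight,
            "convergence": {k: conv(v) for k, v in self.convergence.items()},
            "profile_cis": self.profile_cis,
        }


@dataclass(frozen=True)
class StateSummary:
    """Reported behavioral-state quantities of a fitted 2-phase model.

    p_i/p_e are stationary phase proportions, s_i/s_e expected step
    lengths (m) per phase, r_e the extensive-phase turning-angle
    concentration (mean resultant length).
    """

    p_i: float
    p_e: float
    s_i: float
    s_e: float
    r_e: float


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aiccs) -> np.ndarray:
    aiccs = np.asarray(aiccs, dtype=float)
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def model_comparison(fits: list[ModelFit]) -> pd.DataFrame:
    """AICc comparison table; fills the ``akaike_weight`` of each fit."""
    w = akaike_weights([f.aicc for f in fits])
    for f, wi in zip(fits, w):
        f.akaike_weight = float(wi)
    df = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta_aicc": [f.aicc - min(x.aicc for x in fits) for f in fits],
            "weight": w,
        }
    )
    # near-ties (< 1e-6) resolve toward the simpler model
    return df.sort_values(["aicc", "k"], kind="stable").reset_index(drop=True)


def best_model(fits: list[ModelFit]) -> ModelFit:
    order = model_comparison(fits)
    name = order.loc[0, "model"]
    if len(order) > 1 and abs(order.loc[1, "aicc"] - order.loc[0, "aicc"]) < 1e-6:
        cand = order.iloc[:2].sort_values("k").iloc[0]["model"]
        name = cand
    return next(f for f in fits if f.model == name)


# ---------------------------------------------------------------------------
# transformed parameter vectors per model
# ---------------------------------------------------------------------------



class _CcrwoSpace:
    names = ("rate_i", "rate_e", "kappa_e", "p_ie", "p_ei")
    bounds = [
        (np.log(1e-8), np.log(10.0)),
        (np.log(1e-8), np.log(10.0)),
        (np.log(1e-4), np.log(100.0)),
        (_logit(1e-4), _logit(1.0 - 1e-4)),
        (_logit(1e-4), _logit(1.0 - 1e-4)),
    ]

    @staticmethod
    def pack(rate_i, rate_e, kappa_e, p_ie, p_ei):
        return np.array(
            [np.log(rate_i), np.log(rate_e), np.log(kappa_e), _logit(p_ie), _logit(p_ei)]
        )

    @staticmethod
    def unpack(z) -> CcrwoParams:
        rate_i, rate_e, kappa_e = np.exp(z[0]), np.exp(z[1]), np.exp(z[2])
        p_ie, p_ei = _expit(z[3]), _expit(z[4])
        gamma = np.array([[1.0 - p_ie, p_ie], [p_ei, 1.0 - p_ei]])
        return CcrwoParams(
            step_i=Exponential(rate_i),
            step_e=Exponential(rate_e),
            angle_e=VonMises(kappa_e),
            gamma=gamma,
        )


class _CcrwpSpace:
    names = (
        "shape_i",
        "scale_i",
        "shape_e",
        "scale_e",
        "rho_i",
        "rho_e",
        "lam_i",
        "lam_e",
    )
    bounds = [
        (np.log(0.2), np.log(10.0)),
        (np.log(1e-2), np.log(1e6)),
        (np.log(0.2), np.log(10.0)),
        (np.log(1e-2), np.log(1e6)),
        (_logit(1e-6), _logit(1.0 - 1e-6)),
        (_logit(1e-6), _logit(1.0 - 1e-6)),
        (np.log(1e-6), np.log(120.0)),
        (np.log(1e-6), np.log(120.0)),
    ]

    @staticmethod
    def pack(shape_i, scale_i, shape_e, scale_e, rho_i, rho_e, lam_i, lam_e):
        return np.array(
            [
                np.log(shape_i),
                np.log(scale_i),
                np.log(shape_e),
                np.log(scale_e),
                _logit(rho_i),
                _logit(rho_e),
                np.log(lam_i),
                np.log(lam_e),
            ]
        )

    @staticmethod
    def unpack(z) -> CcrwpParams:
        return CcrwpParams(
            step_i=Weibull(np.exp(z[0]), np.exp(z[1])),
            step_e=Weibull(np.exp(z[2]), np.exp(z[3])),
            angle_i=WrappedCauchy(_expit(z[4])),
            angle_e=WrappedCauchy(_expit(z[5])),
            dwell_i=ShiftedPoisson(np.exp(z[6])),
            dwell_e=ShiftedPoisson(np.exp(z[7])),
        )


def _relabel(params):
    """Enforce the labeling constraint: E is the larger-mean-step phase."""
    if isinstance(params, CcrwoParams):
        if params.step_i.mean() <= params.step_e.mean():
            return params
        g = params.gamma
        return CcrwoParams(
            step_i=params.step_e,
            step_e=params.step_i,
            angle_e=params.angle_e,
            gamma=np.array([[g[1, 1], g[1, 0]], [g[0, 1], g[0, 0]]]),
        )
    if isinstance(params, CcrwpParams):
        if params.step_i.mean() <= params.step_e.mean():
            return params
        return CcrwpParams(
            step_i=params.step_e,
            step_e=params.step_i,
            angle_i=params.angle_e,
            angle_e=params.angle_i,
            dwell_i=params.dwell_e,
            dwell_e=params.dwell_i,
        )
    return params


# ---------------------------------------------------------------------------
# multi-start construction
# ---------------------------------------------------------------------------


def _latin_grid(ranges, n, rng):
    """n Latin-hypercube points over natural-scale ranges (log-spaced)."""
    d = len(ranges)
    u = (np.array([rng.permutation(n) for _ in range(d)]).T + 0.5) / n
    pts = np.empty((n, d))
    for j, (lo, hi) in enumerate(ranges):
        pts[:, j] = np.exp(np.log(lo) + u[:, j] * (np.log(hi) - np.log(lo)))
    return pts


def _moment_split(obs: Observations):
    steps = obs.all_steps()
    med = np.median(steps)
    lo = steps[steps <= med]
    hi = steps[steps > med]
    m_i = float(lo.mean()) if lo.size else float(steps.mean())
    m_e = float(hi.mean()) if hi.size else float(steps.mean()) * 2
    angles = obs.all_angles()
    resultant = float(np.abs(np.mean(np.exp(1j * angles)))) if angles.size else 0.2
    return m_i, max(m_e, m_i * 1.5), resultant


def _starts_ccrwo(obs, n_grid, rng):
    m_i, m_e, resultant = _moment_split(obs)
    starts = [_CcrwoSpace.pack(1.0 / m_i, 1.0 / m_e, 1.0, 0.2, 0.3)]
    ranges = [
        (0.3 / m_i, 3.0 / m_i),
        (0.3 / m_e, 3.0 / m_e),
        (0.2, 8.0),
        (0.02, 0.6),
        (0.02, 0.6),
    ]
    for p in _latin_grid(ranges, n_grid, rng):
        starts.append(_CcrwoSpace.pack(p[0], p[1], p[2], p[3], p[4]))
    return starts


def _starts_ccrwp(obs, n_grid, rng):
    m_i, m_e, resultant = _moment_split(obs)
    starts = [
        _CcrwpSpace.pack(
            1.0,
            m_i,
            1.0,
            m_e,
            0.05,
            float(np.clip(resultant * 1.5, 0.05, 0.9)),
            4.0,
            2.0,
        )
    ]
    ranges = [
        (0.6, 2.5),
        (0.2 * m_i, 2.0 * m_i),
        (0.6, 2.5),
        (0.5 * m_e, 4.0 * m_e),
        (0.02, 0.5),
        (0.1, 0.85),
        (1.0, 20.0),
        (0.5, 8.0),
    ]
    for p in _latin_grid(ranges, n_grid, rng):
        starts.append(_CcrwpSpace.pack(*p))
    return starts


def _multistart_minimize(nll, starts, bounds, options: FitOptions):
    """Short runs from every start, polish the most promising few."""
    short = []
    for z0 in starts:
        res = optimize.minimize(
            nll,
            z0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.pre_iter, "gtol": options.gtol},
        )
        short.append(res)
    order = np.argsort([r.fun for r in short])
    best = None
    trace = []
    for idx in order[: options.n_polish]:
        res = optimize.minimize(
            nll,
            short[idx].x,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.polish_iter, "gtol": options.gtol},
        )
        trace.append(
            {"start": int(idx), "nll": float(res.fun), "nit": int(res.nit),
             "converged": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all optimizer starts failed: {trace}")
    at_bound = bool(
        np.any(np.isclose(best.x, [b[0] for b in bounds]))
        or np.any(np.isclose(best.x, [b[1] for b in bounds]))
    )
    info = {
        "converged": bool(best.success) or best.nit > 0,
        "n_starts": len(starts),
        "polish_trace": trace,
        "boundary_pinned": at_bound,
    }
    return best, info


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def fit_model(
    obs: Observations,
    model: str,
    seed: int = 0,
    options: FitOptions | None = None,
) -> ModelFit:
    """Fit one candidate model by maximum likelihood.

    ``seed`` only controls the Latin-grid multi-start layout; given the
    same data, seed and options the fit is deterministic.
    """
    if options is None:
        options = FitOptions()
    n = obs.n_steps
    if n == 0:
        raise ValueError("empty observation series")
    steps = obs.all_steps()

    if model == "BW":
        params = BwParams(step=fit_exponential(steps))
        ll = _loglik(obs, params)
        k = 1
        info = {"converged": True, "method": "closed-form"}
    elif model == "TLW":
        params = TlwParams(step=fit_truncated_pareto(steps))
        ll = _loglik(obs, params)
        k = 1
        info = {"converged": True, "method": "1-d profile search",
                "support": [params.step.a, params.step.b]}
    elif model == "CCRWo":
        rng = np.random.default_rng(seed)
        starts = _starts_ccrwo(obs, options.n_grid_starts, rng)

        def nll(z):
            return -loglik_ccrwo(obs, _CcrwoSpace.unpack(z))

        best, info = _multistart_minimize(nll, starts, _CcrwoSpace.bounds, options)
        params = _relabel(_CcrwoSpace.unpack(best.x))
        ll = loglik_ccrwo(obs, params)
        k = 5
    elif model == "CCRWp":
        rng = np.random.default_rng(seed)
        starts = _starts_ccrwp(obs, options.n_grid_starts, rng)

        def nll(z):
            return -loglik_ccrwp(obs, _CcrwpSpace.unpack(z), _FIT_DWELL_STATES)

        best, info = _multistart_minimize(nll, starts, _CcrwpSpace.bounds, options)
        params = _relabel(_CcrwpSpace.unpack(best.x))
        ll = loglik_ccrwp(obs, params)
        k = 8
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")

    if n <= k + 2:
        raise ValueError(f"too few steps (n={n}) to fit {model} with k={k}")
    return ModelFit(
        model=model, params=params, loglik=float(ll), k=k, n=n,
        aicc=aicc(float(ll), k, n), convergence=info,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

_SPACES = {"CCRWo": _CcrwoSpace, "CCRWp": _CcrwpSpace}


def _fit_vector(fit: ModelFit):
    """(names, z, bounds, nll) of the fitted model on the transformed scale."""
    p = fit.params
    if fit.model == "BW":
        names = ("rate",)
        z = np.array([np.log(p.step.rate)])
        bounds = [(np.log(1e-10), np.log(1e3))]

        def unpack(z):
            return BwParams(step=Exponential(np.exp(z[0])))

    elif fit.model == "TLW":
        names = ("mu",)
        a, b = p.step.a, p.step.b
        z = np.array([np.log(p.step.mu - 1.0)])
        bounds = [(np.log(1e-8), np.log(50.0))]

        def unpack(z, a=a, b=b):
            return TlwParams(step=TruncatedPareto(1.0 + np.exp(z[0]), a, b))

    elif fit.model == "CCRWo":
        names = _CcrwoSpace.names
        g = p.gamma
        z = _CcrwoSpace.pack(p.step_i.rate, p.step_e.rate, p.angle_e.kappa,
                             g[0, 1], g[1, 0])
        bounds = _CcrwoSpace.bounds
        unpack = _CcrwoSpace.unpack
    elif fit.model == "CCRWp":
        names = _CcrwpSpace.names
        z = _CcrwpSpace.pack(
            p.step_i.shape, p.step_i.scale, p.step_e.shape, p.step_e.scale,
            p.angle_i.rho, p.angle_e.rho, p.dwell_i.lam, p.dwell_e.lam,
        )
        bounds = _CcrwpSpace.bounds
        unpack = _CcrwpSpace.unpack
    else:
        raise ValueError(fit.model)
    return names, z, bounds, unpack


def profile_ci(
    obs: Observations,
    fit: ModelFit,
    param_name: str,
    level: float = 0.95,
    max_nuisance_iter: int = 150,
) -> tuple[float, float]:
    """Profile-likelihood interval for one natural-scale parameter.

    Returns (lo, hi); a side that runs into the feasible boundary before
    the profile drops far enough is open and reported as NaN.
    """
    if not fit.convergence.get("converged", False):
        raise ValueError("profile CI requires a converged fit")
    names, z_mle, bounds, unpack = _fit_vector(fit)
    if param_name not in names:
        raise KeyError(f"{param_name!r} not in {names}")
    j = names.index(param_name)
    drop = stats.chi2.ppf(level, df=1) / 2.0
    llmax = fit.loglik
    target = llmax - drop

    free = [i for i in range(len(names)) if i != j]

    def profile_ll(zj):
        if not free:
            return float(_loglik(obs, _params_of(unpack, np.array([zj]), fit)))
        z0 = z_mle[free]

        def nll(zf):
            z = z_mle.copy()
            z[free] = zf
            z[j] = zj
            return -_loglik(obs, _params_of(unpack, z, fit))

        res = optimize.minimize(
            nll, z0, method="L-BFGS-B",
            bounds=[bounds[i] for i in free],
            options={"maxiter": max_nuisance_iter},
        )
        return -float(res.fun)

    def _params_of(unpack, z, fit):
        if fit.model in ("BW", "TLW"):
            return unpack(z)
        return unpack(z)

    lo_b, hi_b = bounds[j]

    def side(direction):
        step = 0.1
        z_edge = z_mle[j]
        for _ in range(60):
            z_try = z_mle[j] + direction * step
            if z_try <= lo_b or z_try >= hi_b:
                # profile never dropped below target before the boundary
                z_clip = np.clip(z_try, lo_b, hi_b)
                if profile_ll(z_clip) > target:
                    return np.nan
                z_try = z_clip
            if profile_ll(z_try) < target:
                root = optimize.brentq(
                    lambda zz: profile_ll(zz) - target,
                    min(z_edge, z_try), max(z_edge, z_try), xtol=1e-6,
                )
                return root
            z_edge = z_try
            step *= 2.0
        return np.nan

    z_lo = side(-1.0)
    z_hi = side(+1.0)

    def natural(zj):
        if np.isnan(zj):
            return np.nan
        z = z_mle.copy()
        z[j] = zj
        return _natural_value(fit.model, unpack, z, param_name)

    return natural(z_lo), natural(z_hi)


def _natural_value(model, unpack, z, name):
    p = unpack(z)
    if model == "BW":
        return p.step.rate
    if model == "TLW":
        return p.step.mu
    if model == "CCRWo":
        return {
            "rate_i": p.step_i.rate,
            "rate_e": p.step_e.rate,
            "kappa_e": p.angle_e.kappa,
            "p_ie": p.gamma[0, 1],
            "p_ei": p.gamma[1, 0],
        }[name]
    return {
        "shape_i": p.step_i.shape,
        "scale_i": p.step_i.scale,
        "shape_e": p.step_e.shape,
        "scale_e": p.step_e.scale,
        "rho_i": p.angle_i.rho,
        "rho_e": p.angle_e.rho,
        "lam_i": p.dwell_i.lam,
        "lam_e": p.dwell_e.lam,
    }[name]


# ---------------------------------------------------------------------------
# derived behavioral-state summaries
# ---------------------------------------------------------------------------


def state_summary(params) -> StateSummary:
    """pI, pE, sI, sE, rE of a fitted 2-phase model."""
    if isinstance(params, CcrwpParams):
        mi, me = params.dwell_i.mean(), params.dwell_e.mean()
        p_e = me / (mi + me)
        return StateSummary(
            p_i=1.0 - p_e,
            p_e=p_e,
            s_i=float(params.step_i.mean()),
            s_e=float(params.step_e.mean()),
            r_e=float(params.angle_e.rho),
        )
    if isinstance(params, CcrwoParams):
        pi = markov_stationary(params.gamma)
        return StateSummary(
            p_i=float(pi[0]),
            p_e=float(pi[1]),
            s_i=float(params.step_i.mean()),
            s_e=float(params.step_e.mean()),
            r_e=float(params.angle_e.mean_resultant_length()),
        )
    raise TypeError("state summary applies to 2-phase models only")
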