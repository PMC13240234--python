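"""Log-likelihoods for the four candidate movement models.

Candidates
----------
BW     Brownian walk: exponential steps, circular-uniform angles.
TLW    truncated Lévy walk: truncated-Pareto steps, uniform angles.
CCRWo  composite correlated random walk as a 2-state HMM: exponential
       steps per phase, uniform angles in the intensive phase, von Mises
       angles in the extensive phase, geometric (Markov) dwell.
CCRWp  CCRW as a 2-state HSMM: Weibull steps, wrapped-Cauchy angles in
       both phases, shifted-Poisson dwell.

The observation unit is the step: each step t carries a length L_t and,
except at a segment start or after a zero-length step, a turning angle
theta_t.  Angles missing in the data are omitted from every model's
likelihood, so the observation set is constant across models and AICc
differences reflect model structure only.  BW and TLW include the
uniform-angle constant for the same reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .distributions import (
    UNIFORM_ANGLE_LOGPDF,
    Exponential,
    ShiftedPoisson,
    TruncatedPareto,
    VonMises,
    Weibull,
    WrappedCauchy,
)
from .geo import StepSeries

__all__ = [
    "SegmentObs",
    "Observations",
    "BwParams",
    "TlwParams",
    "CcrwoParams",
    "CcrwpParams",
    "loglik",
    "loglik_bw",
    "loglik_tlw",
    "loglik_ccrwo",
    "loglik_ccrwp",
    "forward_predictive",
    "decode_states",
    "markov_stationary",
    "dwell_truncation_for",
]

#: steps below this (metres) are censored at it so log-densities stay finite
MIN_STEP = 0.1

#: sub-state floor for the dwell-expanded HSMM
MIN_DWELL_STATES = 30

#: dwell quantile the truncation must cover
DWELL_QUANTILE = 0.999


@dataclass
class SegmentObs:
    """Steps and aligned turning angles of one segment.

    ``angles[t]`` is the turning angle *into* step t; index 0 and any
    angle ruined by a zero-length step are NaN (missing).
    """

    steps: np.ndarray
    angles: np.ndarray

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.steps.shape != self.angles.shape:
            raise ValueError("steps and angles must align one-to-one")


@dataclass
class Observations:
    """Step/angle series of many independent segments."""

    segments: list[SegmentObs] = field(default_factory=list)

    @classmethod
    def from_step_series(cls, series: list[StepSeries], min_step: float = MIN_STEP):
        segs = []
        for s in series:
            steps = np.maximum(s.step_lengths, min_step)
            angles = np.concatenate(([np.nan], s.turning_angles))
            segs.append(SegmentObs(steps=steps, angles=angles))
        return cls(segments=segs)

    @property
    def n_steps(self) -> int:
        return sum(len(s.steps) for s in self.segments)

    @property
    def n_angles(self) -> int:
        return sum(int(np.sum(~np.isnan(s.angles))) for s in self.segments)

    def all_steps(self) -> np.ndarray:
        if not self.segments:
            return np.empty(0)
        return np.concatenate([s.steps for s in self.segments])

    def all_angles(self) -> np.ndarray:
        if not self.segments:
            return np.empty(0)
        a = np.concatenate([s.angles for s in self.segments])
        return a[~np.isnan(a)]


# ---------------------------------------------------------------------------
# model parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BwParams:
    step: Exponential


@dataclass(frozen=True)
class TlwParams:
    step: TruncatedPareto


def markov_stationary(gamma: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 2-state row-stochastic matrix."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (2, 2) or not np.allclose(gamma.sum(axis=1), 1.0):
        raise ValueError("gamma must be 2x2 row-stochastic")
    p_ie, p_ei = gamma[0, 1], gamma[1, 0]
    total = p_ie + p_ei
    if total <= 0:
        raise ValueError("non-ergodic transition matrix: no switching at all")
    return np.array([p_ei / total, p_ie / total])


@dataclass(frozen=True)
class CcrwoParams:
    """2-state HMM: phase I (intensive) first, phase E (extensive) second."""

    step_i: Exponential
    step_e: Exponential
    angle_e: VonMises
    gamma: np.ndarray  # 2x2 row-stochastic

    def __post_init__(self):
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        markov_stationary(self.gamma)  # validates

    @property
    def delta(self) -> np.ndarray:
        """Initial distribution: the stationary distribution of gamma."""
        return markov_stationary(self.gamma)


@dataclass(frozen=True)
class CcrwpParams:
    """2-phase HSMM with Weibull steps, wrapped-Cauchy angles, Poisson dwell."""

    step_i: Weibull
    step_e: Weibull
    angle_i: WrappedCauchy
    angle_e: WrappedCauchy
    dwell_i: ShiftedPoisson
    dwell_e: ShiftedPoisson

    @property
    def delta(self) -> np.ndarray:
        """Stationary phase proportions: mean dwell shares."""
        mi, me = self.dwell_i.mean(), self.dwell_e.mean()
        return np.array([mi / (mi + me), me / (mi + me)])


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def _iid_loglik(obs: Observations, step_dist) -> float:
    steps = obs.all_steps()
    ll = float(np.sum(step_dist.logpdf(steps)))
    ll += obs.n_angles * UNIFORM_ANGLE_LOGPDF
    return ll


def loglik_bw(obs: Observations, params: BwParams) -> float:
    return _iid_loglik(obs, params.step)


def loglik_tlw(obs: Observations, params: TlwParams) -> float:
    steps = obs.all_steps()
    outside = (steps < params.step.a) | (steps > params.step.b)
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} steps outside the truncated-Pareto support "
            f"[{params.step.a}, {params.step.b}]; likelihood is -inf"
        )
        return -np.inf
    return _iid_loglik(obs, params.step)


def _log_emissions(seg: SegmentObs, step_i, step_e, angle_i_logpdf, angle_e_logpdf):
    m = len(seg.steps)
    logB = np.empty((m, 2))
    logB[:, 0] = step_i.logpdf(seg.steps)
    logB[:, 1] = step_e.logpdf(seg.steps)
    avail = ~np.isnan(seg.angles)
    if np.any(avail):
        th = seg.angles[avail]
        logB[avail, 0] += angle_i_logpdf(th)
        logB[avail, 1] += angle_e_logpdf(th)
    return logB


def _ccrwo_emissions(seg: SegmentObs, params: CcrwoParams):
    return _log_emissions(
        seg,
        params.step_i,
        params.step_e,
        lambda th: np.full(th.shape, UNIFORM_ANGLE_LOGPDF),
        params.angle_e.logpdf,
    )


def _ccrwp_emissions(seg: SegmentObs, params: CcrwpParams):
    return _log_emissions(
        seg,
        params.step_i,
        params.step_e,
        params.angle_i.logpdf,
        params.angle_e.logpdf,
    )


def loglik_ccrwo(obs: Observations, params: CcrwoParams) -> float:
    delta = params.delta
    total = 0.0
    for seg in obs.segments:
        logB = _ccrwo_emissions(seg, params)
        ll, _ = _kernels.hmm_forward(logB, params.gamma, delta)
        total += ll
    return total


def dwell_truncation_for(params: CcrwpParams) -> int:
    """Minimum sub-state count covering the dwell quantile for both phases."""
    q = max(params.dwell_i.quantile(DWELL_QUANTILE), params.dwell_e.quantile(DWELL_QUANTILE))
    return max(MIN_DWELL_STATES, int(q))


def _hazard_matrix(params: CcrwpParams, m: int) -> np.ndarray:
    return np.vstack([params.dwell_i.hazard(m), params.dwell_e.hazard(m)])


def _equilibrium_init(params: CcrwpParams, m: int) -> np.ndarray:
    """Stationary mass over (phase, elapsed dwell age).

    A segment is an arbitrary cut of a continuous walk, so the phase at
    its first step follows the stationary proportions and the elapsed
    dwell age follows the discrete equilibrium (residual-life) law
    P(age = j) = P(D >= j + 1) / E[D]; tail mass beyond the truncation
    is lumped into the last sub-state.
    """
    delta = params.delta
    init = np.empty((2, m))
    for s, dw in ((0, params.dwell_i), (1, params.dwell_e)):
        ages = dw.sf_geq(np.arange(1, m + 1)) / dw.mean()
        ages[-1] = max(1.0 - ages[:-1].sum(), 0.0)
        init[s] = delta[s] * ages
    return init


def loglik_ccrwp(
    obs: Observations, params: CcrwpParams, dwell_truncation: int | None = None
) -> float:
    required = dwell_truncation_for(params)
    if dwell_truncation is None:
        dwell_truncation = required
    elif dwell_truncation < required:
        raise ValueError(
            f"dwell_truncation={dwell_truncation} below the required minimum "
            f"{required} (the {DWELL_QUANTILE} dwell quantile)"
        )
    hazard = _hazard_matrix(params, dwell_truncation)
    init = _equilibrium_init(params, dwell_truncation)
    total = 0.0
    for seg in obs.segments:
        logB = _ccrwp_emissions(seg, params)
        ll, _ = _kernels.hsmm_forward(logB, hazard, init)
        total += ll
    return total


def loglik(obs: Observations, params) -> float:
    """Dispatch on the parameter container type."""
    if isinstance(params, BwParams):
        return loglik_bw(obs, params)
    if isinstance(params, TlwParams):
        return loglik_tlw(obs, params)
    if isinstance(params, CcrwoParams):
        return loglik_ccrwo(obs, params)
    if isinstance(params, CcrwpParams):
        return loglik_ccrwp(obs, params)
    raise TypeError(f"unknown parameter type {type(params)!r}")


def forward_predictive(obs: Observations, params) -> tuple[float, list[np.ndarray]]:
    """One-step-ahead predictive phase probabilities per segment.

    Returns (loglik, [pred_seg]) with pred_seg of shape (T, 2) giving
    P(S_t = phase | observations before t); the base for CCRW
    pseudo-residuals.
    """
    preds = []
    total = 0.0
    if isinstance(params, CcrwoParams):
        delta = params.delta
        for seg in obs.segments:
            ll, pred = _kernels.hmm_forward(
                _ccrwo_emissions(seg, params), params.gamma, delta
            )
            total += ll
            preds.append(pred)
        return total, preds
    if isinstance(params, CcrwpParams):
        m = dwell_truncation_for(params)
        hazard = _hazard_matrix(params, m)
        init = _equilibrium_init(params, m)
        for seg in obs.segments:
            ll, pred = _kernels.hsmm_forward(_ccrwp_emissions(seg, params), hazard, init)
            total += ll
            preds.append(pred)
        return total, preds
    raise TypeError("predictive decomposition applies to CCRW models only")


def decode_states(obs: Observations, params) -> list[np.ndarray]:
    """Viterbi phase labels per segment: 0 = intensive, 1 = extensive.

    Ties resolve to the intensive phase.
    """
    paths = []
    if isinstance(params, CcrwoParams):
        delta = params.delta
        with np.errstate(divide="ignore"):
            log_gamma = np.log(params.gamma)
            log_delta = np.log(delta)
        for seg in obs.segments:
            paths.append(
                _kernels.hmm_viterbi(_ccrwo_emissions(seg, params), log_gamma, log_delta)
            )
        return paths
    if isinstance(params, CcrwpParams):
        m = dwell_truncation_for(params)
        hazard = _hazard_matrix(params, m)
        init = _equilibrium_init(params, m)
        for seg in obs.segments:
            paths.append(
                _kernels.hsmm_viterbi(_ccrwp_emissions(seg, params), hazard, init)
            )
        return paths
    raise TypeError("state decoding applies to CCRW models only")
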