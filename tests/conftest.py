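"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest

from gibbonwalk import geo, synthetic
from gibbonwalk import likelihoods as lk
from gibbonwalk.distributions import (
    Exponential,
    ShiftedPoisson,
    TruncatedPareto,
    VonMises,
    Weibull,
    WrappedCauchy,
)
from gibbonwalk.likelihoods import (
    BwParams,
    CcrwoParams,
    CcrwpParams,
    Observations,
    SegmentObs,
    TlwParams,
)


def obs_from_walk(params, n_steps, seed):
    """Simulate a walk and rebuild the observation series from positions."""
    fixes, truth = synthetic.simulate_walk(params, n_steps, seed=seed)
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    steps = np.hypot(np.diff(x), np.diff(y))
    h = np.arctan2(np.diff(y), np.diff(x))
    th = geo.wrap_angle(np.diff(h))
    obs = Observations(
        [SegmentObs(np.maximum(steps, 0.1), np.concatenate(([np.nan], th)))]
    )
    return obs, truth


def random_segment(rng, T):
    steps = rng.exponential(80.0, T)
    angles = np.concatenate(([np.nan], rng.uniform(-np.pi, np.pi, max(T - 1, 0))))
    return SegmentObs(np.maximum(steps, 0.1), angles)


def random_ccrwo(rng):
    p_ie = rng.uniform(0.05, 0.6)
    p_ei = rng.uniform(0.05, 0.6)
    return CcrwoParams(
        step_i=Exponential(1.0 / rng.uniform(10, 80)),
        step_e=Exponential(1.0 / rng.uniform(100, 500)),
        angle_e=VonMises(rng.uniform(0.1, 5.0)),
        gamma=np.array([[1 - p_ie, p_ie], [p_ei, 1 - p_ei]]),
    )


def random_ccrwp(rng):
    return CcrwpParams(
        step_i=Weibull(rng.uniform(0.7, 2.0), rng.uniform(20, 90)),
        step_e=Weibull(rng.uniform(0.8, 2.5), rng.uniform(120, 500)),
        angle_i=WrappedCauchy(rng.uniform(0.0, 0.5)),
        angle_e=WrappedCauchy(rng.uniform(0.1, 0.9)),
        dwell_i=ShiftedPoisson(rng.uniform(0.0, 8.0)),
        dwell_e=ShiftedPoisson(rng.uniform(0.0, 4.0)),
    )


# ---------------------------------------------------------------------------
# brute-force likelihood oracles (exponential-time path enumeration)
# ---------------------------------------------------------------------------


def brute_hmm_loglik(seg, params):
    """Sum over all 2^T state paths."""
    logB = lk._ccrwo_emissions(seg, params)
    T = logB.shape[0]
    delta, g = params.delta, params.gamma
    total = 0.0
    for path in itertools.product([0, 1], repeat=T):
        p = delta[path[0]] * np.exp(logB[0, path[0]])
        for t in range(1, T):
            p *= g[path[t - 1], path[t]] * np.exp(logB[t, path[t]])
        total += p
    return np.log(total)


def brute_hsmm_loglik(seg, params):
    """Sum over all alternating dwell compositions; final dwell censored.

    A segment is an arbitrary cut of a stationary walk, so the first
    dwell is the equilibrium residual life R with P(R = d) =
    P(D >= d) / E[D]; later dwells are fresh draws from D.
    """
    logB = lk._ccrwp_emissions(seg, params)
    T = logB.shape[0]
    dwell = (params.dwell_i, params.dwell_e)
    delta = params.delta

    def residual_pmf(s, d):
        return float(dwell[s].sf_geq(d)) / dwell[s].mean()

    def residual_sf(s, r):
        # P(R >= r) summed until the dwell tail is numerically exhausted
        top = dwell[s].quantile(1 - 1e-15) + 10
        return sum(residual_pmf(s, d) for d in range(r, top + 1))

    total = 0.0

    def recurse(t, s, prob, first):
        nonlocal total
        for d in range(1, T - t + 1):
            emit = float(np.exp(logB[t : t + d, s]).prod())
            if t + d == T:
                surv = residual_sf(s, d) if first else float(dwell[s].sf_geq(d))
                total += prob * emit * surv
            else:
                mass = residual_pmf(s, d) if first else float(dwell[s].pmf(d))
                recurse(t + d, 1 - s, prob * emit * mass, False)

    for s in (0, 1):
        recurse(0, s, float(delta[s]), True)
    return np.log(total)


@pytest.fixture(scope="session")
def hg_params():
    """Well-separated two-phase regime used across recovery tests."""
    return synthetic.preset("HG")
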