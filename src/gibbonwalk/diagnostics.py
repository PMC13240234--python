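"""One-step-ahead pseudo-residuals and G-test goodness of fit.

Under a correctly specified model the probability-integral transform of
each observation through its one-step-ahead predictive CDF is uniform
on [0, 1]; binning those residuals and applying the likelihood-ratio
(G) test against the uniform gives an absolute goodness-of-fit check
that remains valid under the serial dependence of the CCRW models.

For the i.i.d. models the predictive CDF is just the marginal CDF; for
the HMM/HSMM it is the mixture of per-phase CDFs weighted by the
forward predictive phase probabilities (step residuals), additionally
conditioned on the concurrent step length for angle residuals, since
the emission factorizes as step density times angle density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distributions import VonMises
from .inference import ModelFit
from .likelihoods import (
    BwParams,
    CcrwoParams,
    CcrwpParams,
    Observations,
    TlwParams,
    forward_predictive,
)

__all__ = [
    "PseudoResiduals",
    "pseudo_residuals",
    "g_test_uniform",
    "combined_p",
    "diagnose",
]


@dataclass
class PseudoResiduals:
    """Uniform pseudo-residuals, one list entry per segment."""

    step_residuals: list[np.ndarray]
    angle_residuals: list[np.ndarray]

    def steps_flat(self) -> np.ndarray:
        return np.concatenate(self.step_residuals) if self.step_residuals else np.empty(0)

    def angles_flat(self) -> np.ndarray:
        return np.concatenate(self.angle_residuals) if self.angle_residuals else np.empty(0)


def _uniform_angle_cdf(theta):
    return (np.asarray(theta) + np.pi) / (2.0 * np.pi)


def pseudo_residuals(obs: Observations, fit: ModelFit) -> PseudoResiduals:
    """One-step-ahead PIT residuals of a fitted model.

    Raises if the fit did not converge (residuals of a bad optimum are
    meaningless).
    """
    if not fit.convergence.get("converged", False):
        raise ValueError("pseudo-residuals require a converged fit")
    params = fit.params

    if isinstance(params, (BwParams, TlwParams)):
        step_res, ang_res = [], []
        for seg in obs.segments:
            step_res.append(np.asarray(params.step.cdf(seg.steps), dtype=float))
            avail = ~np.isnan(seg.angles)
            ang_res.append(_uniform_angle_cdf(seg.angles[avail]))
        return PseudoResiduals(step_res, ang_res)

    if isinstance(params, CcrwoParams):
        step_dists = (params.step_i, params.step_e)
        angle_dists = (VonMises(0.0), params.angle_e)
    elif isinstance(params, CcrwpParams):
        step_dists = (params.step_i, params.step_e)
        angle_dists = (params.angle_i, params.angle_e)
    else:
        raise TypeError(f"unsupported model parameters {type(params)!r}")

    _, preds = forward_predictive(obs, params)
    step_res, ang_res = [], []
    for seg, pred in zip(obs.segments, preds):
        f_i = np.exp(step_dists[0].logpdf(seg.steps))
        f_e = np.exp(step_dists[1].logpdf(seg.steps))
        u_step = pred[:, 0] * step_dists[0].cdf(seg.steps) + pred[:, 1] * step_dists[
            1
        ].cdf(seg.steps)
        step_res.append(np.clip(u_step, 0.0, 1.0))
        # angle residuals: predictive weights conditioned on the step length
        w_i = pred[:, 0] * f_i
        w_e = pred[:, 1] * f_e
        tot = w_i + w_e
        tot[tot == 0] = 1.0
        w_i, w_e = w_i / tot, w_e / tot
        avail = ~np.isnan(seg.angles)
        th = seg.angles[avail]
        u_ang = w_i[avail] * np.asarray(angle_dists[0].cdf(th)) + w_e[avail] * np.asarray(
            angle_dists[1].cdf(th)
        )
        ang_res.append(np.clip(u_ang, 0.0, 1.0))
    return PseudoResiduals(step_res, ang_res)


def g_test_uniform(residuals, bins: int = 20):
    """Likelihood-ratio test of uniformity on [0, 1].

    G = 2 sum O_i log(O_i / E_i) over equal-width bins (empty bins
    contribute 0), compared against chi-square with bins - 1 degrees of
    freedom.  Returns (G, p).
    """
    u = np.asarray(residuals, dtype=float)
    n = u.size
    if n == 0:
        raise ValueError("no residuals to test")
    if n < 5 * bins:
        warnings.warn(f"only {n} residuals for {bins} bins; G-test may be unreliable")
    counts, _ = np.histogram(u, bins=bins, range=(0.0, 1.0))
    expected = n / bins
    nz = counts > 0
    g = 2.0 * float(np.sum(counts[nz] * np.log(counts[nz] / expected)))
    p = float(stats.chi2.sf(g, df=bins - 1))
    return g, p


def combined_p(
    step_residuals,
    angle_residuals,
    bins: int = 20,
    method: str = "pooled",
):
    """Overall goodness-of-fit p combining step and angle residuals.

    ``pooled`` (default) runs one G-test on the concatenated residuals;
    ``fisher`` combines the two per-stream p-values by Fisher's method.
    """
    step_residuals = np.asarray(step_residuals, dtype=float)
    angle_residuals = np.asarray(angle_residuals, dtype=float)
    if method == "pooled":
        pooled = np.concatenate([step_residuals, angle_residuals])
        _, p = g_test_uniform(pooled, bins=bins)
        return p
    if method == "fisher":
        _, p_sl = g_test_uniform(step_residuals, bins=bins)
        _, p_ta = g_test_uniform(angle_residuals, bins=bins)
        x = -2.0 * (np.log(p_sl) + np.log(p_ta))
        return float(stats.chi2.sf(x, df=4))
    raise ValueError(f"unknown combination method {method!r}")


def diagnose(obs: Observations, fit: ModelFit, bins: int = 20, method: str = "pooled") -> dict:
    """Goodness-of-fit row: overall, step-length and turning-angle p-values."""
    res = pseudo_residuals(obs, fit)
    sl = res.steps_flat()
    ta = res.angles_flat()
    g_sl, p_sl = g_test_uniform(sl, bins=bins)
    g_ta, p_ta = g_test_uniform(ta, bins=bins)
    p_all = combined_p(sl, ta, bins=bins, method=method)
    return {
        "model": fit.model,
        "PR_p": p_all,
        "SL_p": p_sl,
        "TA_p": p_ta,
        "G_SL": g_sl,
        "G_TA": g_ta,
        "n_SL": int(sl.size),
        "n_TA": int(ta.size),
    }
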