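"""Synthetic trajectories and field-campaign datasets.

The generator inverts each movement model: latent phases are drawn
(single phase for BW/TLW, Markov switching for the HMM variant,
semi-Markov switching with shifted-Poisson dwells for the HSMM
variant), then step lengths and turning angles are drawn from the
phase's distributions and integrated into planar positions.

``simulate_campaign`` wraps a continuous latent walk in the field
sampling design: fixes on a 15-min grid within 06:00-18:00 observation
days, a configurable number of days per month, per-fix dropout, and
per-dietary-period parameter switching by calendar month.  Its output
CSV dialect is exactly what the preprocessing module reads, so the full
pipeline can be exercised without any field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import ShiftedPoisson, Weibull, WrappedCauchy
from .geo import FeedingPeriod, assign_period, wrap_angle
from .likelihoods import BwParams, CcrwoParams, CcrwpParams, TlwParams

__all__ = [
    "SimTruth",
    "GroupDesign",
    "CampaignDesign",
    "simulate_walk",
    "simulate_campaign",
    "ccrwp_preset",
    "PRESETS",
]


@dataclass
class SimTruth:
    """Ground truth of a simulated walk: one row per step."""

    model: str
    states: np.ndarray  # 0 = intensive, 1 = extensive (0 for single-phase models)
    params: object


def _model_name(params) -> str:
    return {
        BwParams: "BW",
        TlwParams: "TLW",
        CcrwoParams: "CCRWo",
        CcrwpParams: "CCRWp",
    }[type(params)]


def _draw_states(params, n_steps: int, rng) -> np.ndarray:
    if isinstance(params, (BwParams, TlwParams)):
        return np.zeros(n_steps, dtype=np.int32)
    if isinstance(params, CcrwoParams):
        states = np.empty(n_steps, dtype=np.int32)
        s = int(rng.choice(2, p=params.delta))
        for t in range(n_steps):
            states[t] = s
            s = int(rng.choice(2, p=params.gamma[s]))
        return states
    if isinstance(params, CcrwpParams):
        states = np.empty(n_steps, dtype=np.int32)
        # stationary start: phase by dwell-mean share, remaining dwell from
        # the equilibrium residual-life law (an arbitrary cut of the process)
        s = int(rng.choice(2, p=params.delta))
        dwell = int((params.dwell_i if s == 0 else params.dwell_e).sample_residual(1, rng)[0])
        for t in range(n_steps):
            states[t] = s
            dwell -= 1
            if dwell == 0:
                s = 1 - s
                dwell = int((params.dwell_i if s == 0 else params.dwell_e).sample(1, rng)[0])
        return states
    raise TypeError(f"unknown parameter type {type(params)!r}")


def _draw_emissions(params, states: np.ndarray, rng):
    n = states.size
    steps = np.empty(n)
    angles = np.empty(n)
    if isinstance(params, (BwParams, TlwParams)):
        steps[:] = params.step.sample(n, rng)
        angles[:] = rng.uniform(-np.pi, np.pi, size=n)
        return steps, angles
    if isinstance(params, CcrwoParams):
        step_dists = (params.step_i, params.step_e)
        for s in (0, 1):
            m = states == s
            steps[m] = step_dists[s].sample(int(m.sum()), rng)
        m_i = states == 0
        angles[m_i] = rng.uniform(-np.pi, np.pi, size=int(m_i.sum()))
        angles[~m_i] = params.angle_e.sample(int((~m_i).sum()), rng)
        return steps, angles
    step_dists = (params.step_i, params.step_e)
    angle_dists = (params.angle_i, params.angle_e)
    for s in (0, 1):
        m = states == s
        steps[m] = step_dists[s].sample(int(m.sum()), rng)
        angles[m] = angle_dists[s].sample(int(m.sum()), rng)
    return steps, angles


def simulate_walk(
    params,
    n_steps: int,
    seed: int | np.random.Generator = 0,
    origin=(0.0, 0.0),
    group_id: str = "sim",
    start: str = "2023-04-03 06:00",
    interval_min: int = 15,
):
    """Simulate one uninterrupted trajectory of ``n_steps`` steps.

    Returns ``(fixes, truth)``: a fix table (group_id, timestamp, x, y)
    with n_steps + 1 rows on a regular time grid, and the per-step
    ground-truth phase labels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = _draw_states(params, n_steps, rng)
    steps, angles = _draw_emissions(params, states, rng)
    # first heading uniform; later headings accumulate turning angles
    headings = np.empty(n_steps)
    headings[0] = rng.uniform(-np.pi, np.pi)
    if n_steps > 1:
        headings[1:] = angles[1:]
        headings = wrap_angle(np.cumsum(headings))
    x = np.concatenate(([origin[0]], origin[0] + np.cumsum(steps * np.cos(headings))))
    y = np.concatenate(([origin[1]], origin[1] + np.cumsum(steps * np.sin(headings))))
    times = pd.date_range(start=start, periods=n_steps + 1, freq=f"{interval_min}min")
    fixes = pd.DataFrame(
        {"group_id": group_id, "timestamp": times, "x": x, "y": y, "crs": "utm"}
    )
    return fixes, SimTruth(model=_model_name(params), states=states, params=params)


# ---------------------------------------------------------------------------
# campaign designs
# ---------------------------------------------------------------------------


@dataclass
class GroupDesign:
    """One simulated group: a model and (optionally per-period) parameters.

    ``params`` is either a single parameter object or a mapping
    {FeedingPeriod: params} switching by calendar month.
    """

    group_id: str
    params: object


@dataclass
class CampaignDesign:
    """Field-campaign emulation: sampling window, cadence, dropout, groups."""

    groups: list[GroupDesign]
    start: str = "2023-04-01"
    n_months: int = 12
    days_per_month: int = 10
    day_start_hour: int = 6
    day_end_hour: int = 18
    interval_min: int = 15
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _params_for(design: GroupDesign, period: FeedingPeriod):
    if isinstance(design.params, dict):
        return design.params[period]
    return design.params


def simulate_campaign(design: CampaignDesign):
    """Simulate every group through the campaign sampling design.

    The latent walk persists across days (one continuous process per
    group, stepping on the 15-min lattice around the clock); only fixes
    inside the observation window on observation days survive, minus
    dropout.  Parameters switch at calendar-month boundaries when a
    group carries per-period parameters; the phase and dwell state
    restart at a switch.

    Returns ``(fixes, truth)`` dataframes; ``truth`` has one row per
    latent step with its phase label and period.
    """
    rng = np.random.default_rng(design.seed)
    t0 = pd.Timestamp(design.start)
    end = t0 + pd.DateOffset(months=design.n_months)
    lattice = pd.date_range(t0, end, freq=f"{design.interval_min}min", inclusive="left")

    obs_days = set()
    for m in range(design.n_months):
        month_start = t0 + pd.DateOffset(months=m)
        month_end = min(end, month_start + pd.DateOffset(months=1))
        days = pd.date_range(month_start, month_end, freq="D", inclusive="left")
        for d in days[: design.days_per_month]:
            obs_days.add(d.date())

    hours = lattice.hour + lattice.minute / 60.0
    in_window = (hours >= design.day_start_hour) & (hours <= design.day_end_hour)
    on_obs_day = np.array([ts.date() in obs_days for ts in lattice])
    observable = in_window & on_obs_day

    fixes_rows = []
    truth_rows = []
    for g in design.groups:
        grng = np.random.default_rng(rng.integers(2**31))
        x, y = 0.0, 0.0
        heading = grng.uniform(-np.pi, np.pi)
        period = assign_period(lattice[0])
        params = _params_for(g, period)
        state = 0
        dwell = 0
        if isinstance(params, (CcrwoParams, CcrwpParams)):
            state = int(grng.choice(2, p=params.delta))
        if isinstance(params, CcrwpParams):
            dwell = int(
                (params.dwell_i if state == 0 else params.dwell_e).sample_residual(1, grng)[0]
            )

        keep = observable & (grng.uniform(size=lattice.size) >= design.dropout)
        xs = np.empty(lattice.size)
        ys = np.empty(lattice.size)
        states = np.empty(lattice.size - 1, dtype=np.int32)

        for t in range(lattice.size):
            xs[t], ys[t] = x, y
            if t == lattice.size - 1:
                break
            new_period = assign_period(lattice[t])
            if new_period != period:
                period = new_period
                params = _params_for(g, period)
                if isinstance(params, (CcrwoParams, CcrwpParams)):
                    state = int(grng.choice(2, p=params.delta))
                if isinstance(params, CcrwpParams):
                    dwell = int(
                        (params.dwell_i if state == 0 else params.dwell_e)
                        .sample_residual(1, grng)[0]
                    )
            # emit one step in the current phase
            if isinstance(params, (BwParams, TlwParams)):
                length = float(params.step.sample(1, grng)[0])
                turn = float(grng.uniform(-np.pi, np.pi))
                states[t] = 0
            elif isinstance(params, CcrwoParams):
                dist = params.step_i if state == 0 else params.step_e
                length = float(dist.sample(1, grng)[0])
                if state == 0:
                    turn = float(grng.uniform(-np.pi, np.pi))
                else:
                    turn = float(params.angle_e.sample(1, grng)[0])
                states[t] = state
                state = int(grng.choice(2, p=params.gamma[state]))
            else:
                dist = params.step_i if state == 0 else params.step_e
                adist = params.angle_i if state == 0 else params.angle_e
                length = float(dist.sample(1, grng)[0])
                turn = float(adist.sample(1, grng)[0])
                states[t] = state
                dwell -= 1
                if dwell == 0:
                    state = 1 - state
                    dwell = int(
                        (params.dwell_i if state == 0 else params.dwell_e).sample(1, grng)[0]
                    )
            heading = float(wrap_angle(heading + turn))
            x += length * np.cos(heading)
            y += length * np.sin(heading)

        sel = np.flatnonzero(keep)
        fixes_rows.append(
            pd.DataFrame(
                {
                    "group_id": g.group_id,
                    "timestamp": lattice[sel],
                    "x": xs[sel],
                    "y": ys[sel],
                    "crs": "utm",
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "group_id": g.group_id,
                    "timestamp": lattice[:-1],
                    "state": np.where(states == 0, "I", "E"),
                    "period": [assign_period(ts).value for ts in lattice[:-1]],
                    "observed": keep[:-1] & keep[1:],
                }
            )
        )

    fixes = pd.concat(fixes_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return fixes, truth


# ---------------------------------------------------------------------------
# presets: parameter regimes shaped like the fitted field estimates
# ---------------------------------------------------------------------------


def ccrwp_preset(
    p_i: float,
    s_i: float,
    s_e: float,
    rho_e: float,
    rho_i: float = 0.1,
    shape_i: float = 1.1,
    shape_e: float = 1.5,
    mean_dwell_e: float = 3.0,
) -> CcrwpParams:
    """Build HSMM parameters hitting target stationary proportions and means.

    ``p_i`` fixes the ratio of mean dwells given ``mean_dwell_e``;
    Weibull scales are solved from the target per-phase mean step
    lengths given the shapes.
    """
    if not 0.0 < p_i < 1.0:
        raise ValueError("p_i must be in (0, 1)")
    mean_dwell_i = mean_dwell_e * p_i / (1.0 - p_i)
    if mean_dwell_i < 1.0 or mean_dwell_e < 1.0:
        raise ValueError("mean dwells must be >= 1 step")
    from scipy.special import gamma as _gamma

    return CcrwpParams(
        step_i=Weibull(shape_i, s_i / _gamma(1.0 + 1.0 / shape_i)),
        step_e=Weibull(shape_e, s_e / _gamma(1.0 + 1.0 / shape_e)),
        angle_i=WrappedCauchy(rho_i),
        angle_e=WrappedCauchy(rho_e),
        dwell_i=ShiftedPoisson(mean_dwell_i - 1.0),
        dwell_e=ShiftedPoisson(mean_dwell_e - 1.0),
    )


#: two-phase regimes shaped like the four reported dataset fits
PRESETS = {
    "HG": dict(p_i=0.78, s_i=66.27, s_e=152.22, rho_e=0.469),
    "LG": dict(p_i=0.96, s_i=61.23, s_e=388.68, rho_e=0.428),
    "FP": dict(p_i=0.84, s_i=66.53, s_e=163.72, rho_e=0.392),
    "MP": dict(p_i=0.97, s_i=57.72, s_e=431.10, rho_e=0.317),
}


def preset(name: str) -> CcrwpParams:
    """Named CCRWp regime (settings, not truth claims about any field data)."""
    return ccrwp_preset(**PRESETS[name])
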