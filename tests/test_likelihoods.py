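"""Model likelihoods: closed forms, forward-algorithm oracles, decoding."""

import numpy as np
import pytest

from conftest import (
    brute_hmm_loglik,
    brute_hsmm_loglik,
    obs_from_walk,
    random_ccrwo,
    random_ccrwp,
    random_segment,
)
from gibbonwalk import _kernels
from gibbonwalk.distributions import (
    Exponential,
    ShiftedPoisson,
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
    decode_states,
    dwell_truncation_for,
    loglik,
    loglik_bw,
    loglik_ccrwo,
    loglik_ccrwp,
    markov_stationary,
)
from gibbonwalk.distributions import TruncatedPareto


def _single_step_obs(l):
    return Observations([SegmentObs(np.array([l]), np.array([np.nan]))])


class TestIidModels:
    def test_single_step_bw_closed_form(self):
        lam = 0.02
        ll = loglik_bw(_single_step_obs(50.0), BwParams(Exponential(lam)))
        assert ll == pytest.approx(np.log(lam) - lam * 50.0, abs=1e-12)

    def test_bw_equals_degenerate_single_state_ccrwp(self):
        rng = np.random.default_rng(0)
        obs = Observations([random_segment(rng, 40), random_segment(rng, 25)])
        lam = 1.0 / 80.0
        bw = loglik_bw(obs, BwParams(Exponential(lam)))
        # both phases identical Weibull(shape 1) + uniform angles: the latent
        # chain is irrelevant and the HSMM collapses to the i.i.d. model
        same = CcrwpParams(
            step_i=Weibull(1.0, 80.0),
            step_e=Weibull(1.0, 80.0),
            angle_i=WrappedCauchy(0.0),
            angle_e=WrappedCauchy(0.0),
            dwell_i=ShiftedPoisson(2.0),
            dwell_e=ShiftedPoisson(3.0),
        )
        assert loglik_ccrwp(obs, same) == pytest.approx(bw, abs=1e-8)

    def test_tlw_outside_support_is_minus_inf(self):
        obs = _single_step_obs(500.0)
        params = TlwParams(TruncatedPareto(2.0, 1.0, 100.0))
        with pytest.warns(UserWarning, match="outside the truncated-Pareto support"):
            assert loglik(obs, params) == -np.inf

    def test_loglik_increment_bounded_by_max_density(self):
        lam = 0.02
        params = BwParams(Exponential(lam))
        base = loglik_bw(_single_step_obs(50.0), params)
        two = Observations(
            [SegmentObs(np.array([50.0, 10.0]), np.array([np.nan, 0.3]))]
        )
        # adding a step and an angle can add at most log(rate) + log(1/2pi)
        assert loglik_bw(two, params) - base <= np.log(lam) - np.log(2 * np.pi) + 1e-12


class TestHmmForward:
    def test_t1_is_delta_weighted_mixture(self):
        params = random_ccrwo(np.random.default_rng(1))
        obs = _single_step_obs(120.0)
        expected = np.log(
            params.delta[0] * float(params.step_i.pdf(120.0))
            + params.delta[1] * float(params.step_e.pdf(120.0))
        )
        assert loglik_ccrwo(obs, params) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            T = int(rng.integers(1, 7))
            seg = random_segment(rng, T)
            params = random_ccrwo(rng)
            fwd = loglik_ccrwo(Observations([seg]), params)
            assert fwd == pytest.approx(brute_hmm_loglik(seg, params), abs=1e-10)

    def test_iid_transition_rows_give_mixture_model(self):
        rng = np.random.default_rng(3)
        seg = random_segment(rng, 30)
        q = 0.35
        params = CcrwoParams(
            step_i=Exponential(1 / 40.0),
            step_e=Exponential(1 / 300.0),
            angle_e=VonMises(1.5),
            gamma=np.array([[q, 1 - q], [q, 1 - q]]),
        )
        from gibbonwalk.likelihoods import _ccrwo_emissions

        logB = _ccrwo_emissions(seg, params)
        delta = params.delta
        mixture = float(
            np.sum(
                np.log(
                    delta[0] * np.exp(logB[:, 0]) + delta[1] * np.exp(logB[:, 1])
                )
            )
        )
        assert loglik_ccrwo(Observations([seg]), params) == pytest.approx(
            mixture, abs=1e-8
        )


class TestHsmmForward:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            T = int(rng.integers(1, 7))
            seg = random_segment(rng, T)
            params = random_ccrwp(rng)
            fwd = loglik_ccrwp(Observations([seg]), params)
            assert fwd == pytest.approx(brute_hsmm_loglik(seg, params), abs=1e-10)

    def test_geometric_dwell_reproduces_matched_hmm(self):
        # constant hazard p makes the expanded HSMM a geometric-dwell chain,
        # identical to the HMM whose switch probabilities equal those hazards
        rng = np.random.default_rng(5)
        seg = random_segment(rng, 60)
        params = random_ccrwo(rng)
        from gibbonwalk.likelihoods import _ccrwo_emissions

        logB = _ccrwo_emissions(seg, params)
        p_ie, p_ei = params.gamma[0, 1], params.gamma[1, 0]
        M = 40
        hazard = np.vstack([np.full(M, p_ie), np.full(M, p_ei)])
        # constant hazard is memoryless: the dwell-age layout is irrelevant,
        # so starting every phase at age zero matches the HMM exactly
        init = np.zeros((2, M))
        init[:, 0] = params.delta
        ll_hsmm, _ = _kernels.hsmm_forward(logB, hazard, init)
        ll_hmm, _ = _kernels.hmm_forward(logB, params.gamma, params.delta)
        assert ll_hsmm == pytest.approx(ll_hmm, abs=1e-8)

    def test_zero_lambda_dwells_strictly_alternate(self):
        rng = np.random.default_rng(6)
        seg = random_segment(rng, 5)
        params = random_ccrwp(rng)
        params = CcrwpParams(
            step_i=params.step_i,
            step_e=params.step_e,
            angle_i=params.angle_i,
            angle_e=params.angle_e,
            dwell_i=ShiftedPoisson(0.0),
            dwell_e=ShiftedPoisson(0.0),
        )
        from gibbonwalk.likelihoods import _ccrwp_emissions

        logB = _ccrwp_emissions(seg, params)
        # only the 2 strictly alternating paths survive
        path_a = sum(logB[t, t % 2] for t in range(5))
        path_b = sum(logB[t, (t + 1) % 2] for t in range(5))
        expected = np.logaddexp(
            np.log(params.delta[0]) + path_a, np.log(params.delta[1]) + path_b
        )
        assert loglik_ccrwp(Observations([seg]), params) == pytest.approx(
            expected, abs=1e-10
        )

    def test_truncation_convergence(self):
        rng = np.random.default_rng(8)
        seg = random_segment(rng, 80)
        params = random_ccrwp(rng)
        obs = Observations([seg])
        m = dwell_truncation_for(params)
        ll_m = loglik_ccrwp(obs, params, m)
        ll_2m = loglik_ccrwp(obs, params, 2 * m)
        assert abs(ll_m - ll_2m) < 1e-6

    def test_truncation_below_required_errors(self):
        params = random_ccrwp(np.random.default_rng(9))
        obs = Observations([random_segment(np.random.default_rng(9), 10)])
        with pytest.raises(ValueError, match="below the required minimum"):
            loglik_ccrwp(obs, params, 5)


class TestLikelihoodStructure:
    def test_segment_order_invariance(self):
        rng = np.random.default_rng(10)
        segs = [random_segment(rng, t) for t in (12, 30, 7)]
        params_o = random_ccrwo(rng)
        params_p = random_ccrwp(rng)
        a = loglik_ccrwo(Observations(segs), params_o)
        b = loglik_ccrwo(Observations(segs[::-1]), params_o)
        assert a == pytest.approx(b, abs=1e-10)
        c = loglik_ccrwp(Observations(segs), params_p)
        d = loglik_ccrwp(Observations(segs[::-1]), params_p)
        assert c == pytest.approx(d, abs=1e-10)

    def test_segments_contribute_additively(self):
        rng = np.random.default_rng(11)
        segs = [random_segment(rng, 15), random_segment(rng, 22)]
        params = random_ccrwp(rng)
        joint = loglik_ccrwp(Observations(segs), params)
        parts = sum(loglik_ccrwp(Observations([s]), params) for s in segs)
        assert joint == pytest.approx(parts, abs=1e-10)

    def test_all_models_finite_on_censored_observations(self, hg_params):
        obs, _ = obs_from_walk(hg_params, 300, seed=12)
        models = [
            BwParams(Exponential(0.01)),
            TlwParams(
                TruncatedPareto(2.0, float(obs.all_steps().min()), float(obs.all_steps().max()))
            ),
            random_ccrwo(np.random.default_rng(12)),
            random_ccrwp(np.random.default_rng(12)),
        ]
        for p in models:
            assert np.isfinite(loglik(obs, p))


class TestDecoding:
    def test_recovers_well_separated_states(self):
        params = CcrwpParams(
            step_i=Weibull(1.2, 10.0),
            step_e=Weibull(1.5, 1000.0),
            angle_i=WrappedCauchy(0.0),
            angle_e=WrappedCauchy(0.8),
            dwell_i=ShiftedPoisson(6.0),
            dwell_e=ShiftedPoisson(3.0),
        )
        obs, truth = obs_from_walk(params, 1500, seed=30)
        decoded = decode_states(obs, params)[0]
        agreement = np.mean(decoded == truth.states)
        assert agreement >= 0.95

    def test_single_state_degenerate_labels_constant(self):
        params = CcrwoParams(
            step_i=Exponential(0.02),
            step_e=Exponential(0.02 - 1e-12),
            angle_e=VonMises(0.0),
            gamma=np.array([[1 - 1e-9, 1e-9], [0.999, 0.001]]),
        )
        obs, _ = obs_from_walk(BwParams(Exponential(0.02)), 100, seed=31)
        labels = decode_states(obs, params)[0]
        assert len(np.unique(labels)) == 1

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(33)
        obs = Observations([random_segment(rng, 50)])
        p = random_ccrwp(rng)
        swapped = CcrwpParams(
            step_i=p.step_e, step_e=p.step_i,
            angle_i=p.angle_e, angle_e=p.angle_i,
            dwell_i=p.dwell_e, dwell_e=p.dwell_i,
        )
        a = decode_states(obs, p)[0]
        b = decode_states(obs, swapped)[0]
        # ties (if any) may break differently; demand near-perfect flip
        assert np.mean(b == 1 - a) > 0.99


class TestStationary:
    def test_markov_stationary_balance(self):
        g = np.array([[0.9, 0.1], [0.4, 0.6]])
        pi = markov_stationary(g)
        np.testing.assert_allclose(pi @ g, pi, atol=1e-12)

    def test_non_ergodic_rejected(self):
        with pytest.raises(ValueError, match="non-ergodic"):
            markov_stationary(np.eye(2))
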