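import itertools

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest, vonmises

from conftest import make_day_frame
from cpforage import hmm
from cpforage.hmm import (
    HmmParams,
    StepSeries,
    classify_foraging,
    compute_steps,
    fit_hmm,
    forward_backward,
    hmm_loglik,
    pseudo_residuals,
    sample_hmm,
    states_to_fixes,
    viterbi,
)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def _obs_logdens(params, series, t, j):
    shape = (params.gamma_mean[j] / params.gamma_sd[j]) ** 2
    scale = params.gamma_sd[j] ** 2 / params.gamma_mean[j]
    ld = gamma_dist.logpdf(max(series.speed[t], hmm.SPEED_FLOOR),
                           shape, scale=scale)
    if np.isfinite(series.angle[t]):
        ld += vonmises.logpdf(series.angle[t],
                              max(params.vm_kappa[j], 1e-10),
                              loc=params.vm_mu[j])
    return ld


def brute_force_loglik(params, series):
    """Exhaustive sum over all K^T state paths."""
    K, T = params.n_states, len(series)
    total = -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(params.init[path[0]])
        for t in range(1, T):
            lp += np.log(params.tpm[path[t - 1], path[t]])
        for t in range(T):
            lp += _obs_logdens(params, series, t, path[t])
        total = np.logaddexp(total, lp)
    return total


def brute_force_viterbi(params, series):
    K, T = params.n_states, len(series)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(params.init[path[0]])
        for t in range(1, T):
            lp += np.log(params.tpm[path[t - 1], path[t]])
        for t in range(T):
            lp += _obs_logdens(params, series, t, path[t])
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best)


def _toy_params(K=2):
    if K == 2:
        return HmmParams(init=[0.6, 0.4], tpm=[[0.8, 0.2], [0.3, 0.7]],
                         gamma_mean=[3.0, 40.0], gamma_sd=[2.0, 20.0],
                         vm_mu=[0.0, 0.1], vm_kappa=[0.5, 2.0])
    return HmmParams(init=[0.5, 0.3, 0.2],
                     tpm=[[0.7, 0.2, 0.1], [0.2, 0.6, 0.2], [0.1, 0.3, 0.6]],
                     gamma_mean=[3.1, 14.2, 78.8], gamma_sd=[2.5, 9.0, 40.0],
                     vm_mu=[0.0, 0.0, 0.0], vm_kappa=[0.3, 0.8, 4.0])


def _toy_series(T, seed=0):
    rng = np.random.default_rng(seed)
    speed = rng.gamma(2.0, 8.0, T)
    angle = rng.vonmises(0.0, 1.0, T)
    angle[0] = np.nan
    return StepSeries(speed=speed, angle=angle)


class TestForwardLoglik:
    @pytest.mark.parametrize("K, T, seed", [
        (2, 3, 0), (2, 8, 1), (3, 3, 2), (3, 6, 3), (3, 8, 4),
    ])
    def test_matches_exhaustive_enumeration(self, K, T, seed):
        params = _toy_params(K)
        series = _toy_series(T, seed)
        assert hmm_loglik(params, [series]) == pytest.approx(
            brute_force_loglik(params, series), abs=1e-10)

    def test_multiple_days_sum_and_restart(self):
        params = _toy_params(3)
        days = [_toy_series(4, 5), _toy_series(6, 6)]
        expected = sum(brute_force_loglik(params, s) for s in days)
        assert hmm_loglik(params, days) == pytest.approx(expected, abs=1e-10)

    def test_single_state_reduces_to_iid(self):
        params = HmmParams(init=[1.0], tpm=[[1.0]], gamma_mean=[10.0],
                           gamma_sd=[5.0], vm_mu=[0.0], vm_kappa=[1.0])
        series = _toy_series(20, 7)
        iid = sum(_obs_logdens(params, series, t, 0) for t in range(20))
        assert hmm_loglik(params, [series]) == pytest.approx(iid, abs=1e-10)

    def test_invariant_under_state_permutation(self):
        params = _toy_params(3)
        series = _toy_series(10, 8)
        base = hmm_loglik(params, [series])
        perm = np.array([2, 0, 1])
        permuted = HmmParams(
            init=params.init[perm], tpm=params.tpm[np.ix_(perm, perm)],
            gamma_mean=params.gamma_mean[perm], gamma_sd=params.gamma_sd[perm],
            vm_mu=params.vm_mu[perm], vm_kappa=params.vm_kappa[perm])
        assert hmm_loglik(permuted, [series]) == pytest.approx(base, abs=1e-10)

    def test_invalid_params_rejected_before_computation(self):
        with pytest.raises(ValueError):
            HmmParams(init=[0.5, 0.5], tpm=[[0.9, 0.1], [0.5, 0.5]],
                      gamma_mean=[1.0, -2.0], gamma_sd=[1.0, 1.0],
                      vm_mu=[0, 0], vm_kappa=[1, 1])


class TestComputeSteps:
    def test_straight_line_constant_speed(self):
        xy = np.column_stack([np.arange(6) * 50.0, np.zeros(6)])
        s = compute_steps(make_day_frame(xy))
        assert np.allclose(s.speed, 10.0)
        assert np.isnan(s.angle[0])
        assert np.allclose(s.angle[1:], 0.0)

    def test_right_angle_turn(self):
        xy = np.array([[0, 0], [100, 0], [100, 100]], float)
        s = compute_steps(make_day_frame(xy))
        assert s.angle[1] == pytest.approx(np.pi / 2)

    def test_rolling_median_suppresses_single_spike(self):
        # raw speeds (low, 100, low): centered window-3 median keeps the
        # low value in the middle
        xy = np.array([[0, 0], [1.0, 0], [501.0, 0], [502.0, 0]], float)
        s = compute_steps(make_day_frame(xy))
        # middle raw speed 100 m/min; median of (0.2, 100, 0.2) = 0.2
        assert s.speed[1] == pytest.approx(0.2, abs=1e-9)

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError):
            compute_steps(make_day_frame([[0, 0], [1, 1]]))


class TestViterbiAndPosteriors:
    @pytest.mark.parametrize("K, T, seed", [(2, 6, 0), (3, 6, 1), (3, 8, 2)])
    def test_path_matches_exhaustive_argmax(self, K, T, seed):
        params = _toy_params(K)
        series = _toy_series(T, seed)
        seq = viterbi(params, series)
        assert np.array_equal(seq.states, brute_force_viterbi(params, series))

    def test_posteriors_sum_to_one(self):
        params = _toy_params(3)
        series = _toy_series(40, 3)
        post = forward_backward(params, series)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_well_separated_states_decoded_accurately(self):
        params = _toy_params(3)
        sers = sample_hmm(params, [300] * 5, seed=9)
        agree = []
        for s in sers:
            seq = viterbi(params, s)
            agree.append(np.mean(seq.states == s.states))
        # speeds 3.1/14.2/78.8 overlap somewhat; near-deterministic
        # separation needs wider emission gaps
        wide = HmmParams(init=params.init, tpm=params.tpm,
                         gamma_mean=[1.0, 50.0, 2000.0],
                         gamma_sd=[0.3, 5.0, 100.0],
                         vm_mu=[0, 0, 0], vm_kappa=[0.5, 0.5, 0.5])
        sers = sample_hmm(wide, [300] * 5, seed=10)
        agree = [np.mean(viterbi(wide, s).states == s.states) for s in sers]
        assert np.mean(agree) >= 0.99


class TestFit:
    def test_parameter_recovery_and_ordering(self):
        truth = _toy_params(3)
        sers = sample_hmm(truth, [200] * 20, seed=21)  # 4000 steps
        fit = fit_hmm(sers, n_starts=8, seed=2)
        assert np.all(np.diff(fit.params.gamma_mean) > 0)
        assert np.allclose(fit.params.tpm.sum(axis=1), 1.0)
        rel = np.abs(fit.params.gamma_mean - truth.gamma_mean) / truth.gamma_mean
        assert (rel < 0.15).all()

    def test_multistart_stability_on_separated_states(self):
        truth = _toy_params(3)
        sers = sample_hmm(truth, [150] * 10, seed=4)
        f1 = fit_hmm(sers, n_starts=1, seed=5)
        f8 = fit_hmm(sers, n_starts=8, seed=5)
        assert f8.loglik >= f1.loglik - 1e-6
        assert abs(f8.loglik - f1.loglik) < 1e-3


class TestPseudoResiduals:
    def test_standard_normal_under_correct_model(self):
        params = _toy_params(3)
        sers = sample_hmm(params, [500] * 4, seed=30)
        z = np.concatenate([pseudo_residuals(params, s)["speed"] for s in sers])
        assert kstest(z, "norm").pvalue > 0.01

    def test_median_observation_gives_zero_residual(self):
        # CDF value 0.5 maps to residual 0 by construction
        params = HmmParams(init=[1.0], tpm=[[1.0]], gamma_mean=[10.0],
                           gamma_sd=[5.0], vm_mu=[0.0], vm_kappa=[1.0])
        shape = (10.0 / 5.0) ** 2
        scale = 25.0 / 10.0
        median_speed = gamma_dist.ppf(0.5, shape, scale=scale)
        s = StepSeries(speed=np.array([median_speed]),
                       angle=np.array([np.nan]))
        z = pseudo_residuals(params, s)["speed"]
        assert z[0] == pytest.approx(0.0, abs=1e-9)

    def test_one_state_fit_on_three_state_data_rejected(self):
        truth = _toy_params(3)
        sers = sample_hmm(truth, [500] * 4, seed=31)
        bad = HmmParams(init=[1.0], tpm=[[1.0]],
                        gamma_mean=[truth.gamma_mean.mean()],
                        gamma_sd=[truth.gamma_sd.mean()],
                        vm_mu=[0.0], vm_kappa=[1.0])
        z = np.concatenate([
            pseudo_residuals(bad, StepSeries(speed=s.speed, angle=s.angle))["speed"]
            for s in sers])
        assert kstest(z, "norm").pvalue < 0.01


class TestForagingClassification:
    @pytest.mark.parametrize("state, habitat, expected", [
        (2, "grassland", False),   # flight over grassland
        (0, "non_agri", False),    # stationary off agricultural land
        (1, "maize", True),        # walking in maize
        (0, "grassland", True),
        (1, "other_agri", True),
        (2, "non_agri", False),
    ])
    def test_rule(self, state, habitat, expected):
        out = classify_foraging(np.array([state]), np.array([habitat]))
        assert out[0] == expected

    def test_states_to_fixes_departure_convention(self):
        states = np.array([0, 1, 2])
        per_fix = states_to_fixes(states, 4)
        assert np.array_equal(per_fix, [0, 1, 2, 2])
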