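"""Three-state hidden Markov segmentation of trajectories.

Each tracking day yields a series of steps between consecutive fixes;
observations are the centered-rolling-median smoothed speed (m/min, gamma
emission) and the turning angle (radians, von Mises emission), conditionally
independent given the hidden state.  The three states are labelled after
fitting by ascending mean speed: stationary (rest / highly restricted walk),
short-distance movement (active walk), long-distance movement (flight).

One population-level model is fitted by direct numerical maximization of
the forward-algorithm log-likelihood over all days pooled; the likelihood
restarts with the initial distribution at each day boundary, and the first
turning angle of each day is undefined (masked).  Decoding is by Viterbi;
model checking uses one-step-ahead forecast pseudo-residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, i0e, i1e, logsumexp
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, vonmises

from .raster import AGRICULTURAL_CLASSES

__all__ = [
    "StepSeries",
    "HmmParams",
    "HmmFit",
    "StateSequence",
    "compute_steps",
    "hmm_loglik",
    "fit_hmm",
    "viterbi",
    "forward_backward",
    "pseudo_residuals",
    "classify_foraging",
    "states_to_fixes",
]

SPEED_FLOOR = 0.1  # m/min; below GPS noise, keeps the gamma density defined
STATE_LABELS = ("stationary", "short_distance", "long_distance")


@dataclass
class StepSeries:
    """Per-day step observations aligned to fixes.

    ``speed[i]`` is the smoothed speed of the step leaving fix ``i``;
    ``angle[i]`` the signed heading change arriving into that step
    (``nan``/masked for the first step of the day).  ``habitat`` optionally
    carries the habitat class of the starting fix of each step.
    """

    speed: np.ndarray
    angle: np.ndarray
    day_id: str = ""
    habitat: np.ndarray | None = None

    def __len__(self):
        return len(self.speed)


def compute_steps(fixes: pd.DataFrame, smoothing_window: int = 3,
                  interval_min: float = 5.0, day_id: str = "") -> StepSeries:
    """Steps (speed, turning angle) from one preprocessed day of fixes.

    Raw speed_i = |fix_{i+1} - fix_i| / interval; smoothing is a centered
    rolling median (window shrinking at the edges).  Turning angle_i is the
    signed heading change from step i-1 to step i, in (-pi, pi].
    """
    if len(fixes) < 3:
        raise ValueError("need at least 3 fixes to form steps")
    xy = fixes[["x", "y"]].to_numpy(float)
    d = np.diff(xy, axis=0)
    dist = np.hypot(d[:, 0], d[:, 1])
    speed = dist / interval_min
    smoothed = (
        pd.Series(speed).rolling(smoothing_window, center=True, min_periods=1)
        .median().to_numpy()
    )
    smoothed = np.maximum(smoothed, SPEED_FLOOR)
    heading = np.arctan2(d[:, 1], d[:, 0])
    angle = np.full(len(speed), np.nan)
    turns = np.diff(heading)
    angle[1:] = (turns + np.pi) % (2.0 * np.pi) - np.pi
    habitat = None
    if "habitat" in fixes.columns:
        habitat = fixes["habitat"].to_numpy()[:-1]
    return StepSeries(speed=smoothed, angle=angle, day_id=day_id, habitat=habitat)


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class HmmParams:
    init: np.ndarray              # (K,)
    tpm: np.ndarray               # (K, K) row-stochastic
    gamma_mean: np.ndarray        # (K,) m/min
    gamma_sd: np.ndarray          # (K,)
    vm_mu: np.ndarray             # (K,)
    vm_kappa: np.ndarray          # (K,)

    def __post_init__(self):
        for name in ("init", "tpm", "gamma_mean", "gamma_sd", "vm_mu", "vm_kappa"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.gamma_mean <= 0) or np.any(self.gamma_sd <= 0):
            raise ValueError("gamma parameters must be positive")
        if np.any(self.vm_kappa < 0):
            raise ValueError("kappa must be nonnegative")
        if not np.allclose(self.tpm.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.init.sum(), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.init)

    def relabelled(self) -> "HmmParams":
        """Relabel states by ascending gamma mean."""
        order = np.argsort(self.gamma_mean)
        return HmmParams(
            init=self.init[order], tpm=self.tpm[np.ix_(order, order)],
            gamma_mean=self.gamma_mean[order], gamma_sd=self.gamma_sd[order],
            vm_mu=self.vm_mu[order], vm_kappa=self.vm_kappa[order])


@dataclass
class HmmFit:
    params: HmmParams
    loglik: float
    n_starts: int
    start_logliks: list = field(default_factory=list)
    converged: bool = True


@dataclass
class StateSequence:
    states: np.ndarray       # (n_obs,) Viterbi path
    posteriors: np.ndarray   # (n_obs, K) forward-backward marginals
    day_id: str = ""


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

def _log_emissions(params: HmmParams, series: StepSeries) -> np.ndarray:
    """(T, K) log densities; masked angles contribute zero."""
    K = params.n_states
    speed = np.maximum(series.speed, SPEED_FLOOR)[:, None]
    shape = (params.gamma_mean / params.gamma_sd) ** 2
    scale = params.gamma_sd**2 / params.gamma_mean
    logb = gamma_dist.logpdf(speed, shape[None, :], scale=scale[None, :])
    ang = series.angle
    ok = np.isfinite(ang)
    if ok.any():
        la = vonmises.logpdf(ang[ok][:, None], np.maximum(params.vm_kappa, 1e-10)[None, :],
                             loc=params.vm_mu[None, :])
        logb[ok] += la
    return logb


def _pad_series(params: HmmParams, series_list) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(s) for s in series_list])
    T_max, K = int(lengths.max()), params.n_states
    logB = np.full((len(series_list), T_max, K), 0.0)
    for i, s in enumerate(series_list):
        logB[i, : lengths[i]] = _log_emissions(params, s)
    return logB, lengths


def hmm_loglik(params: HmmParams, series_list) -> float:
    """Forward-algorithm log-likelihood summed over days.

    The chain restarts from the initial distribution at each day boundary.
    Vectorized across days (padded to the longest day), with per-step
    renormalization for numerical stability.
    """
    if isinstance(series_list, StepSeries):
        series_list = [series_list]
    logB, lengths = _pad_series(params, series_list)
    n_days, T_max, K = logB.shape
    m = logB.max(axis=2)
    Bn = np.exp(logB - m[:, :, None])
    ll = np.zeros(n_days)
    alpha = np.zeros((n_days, K))
    for t in range(T_max):
        active = t < lengths
        if t == 0:
            a = params.init[None, :] * Bn[:, 0]
        else:
            a = (alpha @ params.tpm) * Bn[:, t]
        c = a.sum(axis=1)
        upd = active & (c > 0)
        ll[upd] += np.log(c[upd]) + m[upd, t]
        ll[active & (c <= 0)] = -np.inf
        safe = np.where(c > 0, c, 1.0)
        alpha[upd] = (a / safe[:, None])[upd]
    return float(ll.sum())


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _pack(p: HmmParams) -> np.ndarray:
    return np.concatenate([
        np.log(np.maximum(p.init, 1e-12)),
        np.log(np.maximum(p.tpm, 1e-12)).ravel(),
        np.log(p.gamma_mean), np.log(p.gamma_sd),
        p.vm_mu, np.log(np.maximum(p.vm_kappa, 1e-8)),
    ])


def _unpack(theta: np.ndarray, K: int = 3) -> HmmParams:
    i = 0
    init_l = theta[i:i + K]; i += K
    tpm_l = theta[i:i + K * K].reshape(K, K); i += K * K
    log_mean = theta[i:i + K]; i += K
    log_sd = theta[i:i + K]; i += K
    mu = theta[i:i + K]; i += K
    log_kappa = theta[i:i + K]
    init = np.exp(init_l - logsumexp(init_l))
    tpm = np.exp(tpm_l - logsumexp(tpm_l, axis=1, keepdims=True))
    mu = (mu + np.pi) % (2 * np.pi) - np.pi
    return HmmParams(init=init, tpm=tpm,
                     gamma_mean=np.exp(np.clip(log_mean, -10, 12)),
                     gamma_sd=np.exp(np.clip(log_sd, -10, 12)),
                     vm_mu=mu, vm_kappa=np.exp(np.clip(log_kappa, -18, 8)))


def _random_start(series_list, rng, K: int = 3) -> HmmParams:
    speeds = np.concatenate([s.speed for s in series_list])
    qs = np.quantile(speeds, [0.3, 0.75, 0.97])[:K]
    means = np.maximum(qs * rng.lognormal(0.0, 0.25, K), SPEED_FLOOR * 2)
    sds = means * rng.uniform(0.5, 1.2, K)
    tpm = np.full((K, K), 0.1 / (K - 1)) + np.eye(K) * (0.9 - 0.1 / (K - 1))
    tpm = tpm * rng.uniform(0.7, 1.3, (K, K))
    tpm /= tpm.sum(axis=1, keepdims=True)
    return HmmParams(init=np.full(K, 1.0 / K), tpm=tpm,
                     gamma_mean=np.sort(means), gamma_sd=sds,
                     vm_mu=np.zeros(K), vm_kappa=rng.uniform(0.2, 3.0, K))


def _fb_stats(params: HmmParams, series_list):
    """Forward-backward pass vectorized across (padded) days.

    Returns the total log-likelihood, posterior state marginals gamma
    (n_days, T_max, K, zero beyond each day's length), the summed pairwise
    transition posteriors xi (K, K), and the summed day-initial posteriors.
    """
    logB, lengths = _pad_series(params, series_list)
    n_days, T_max, K = logB.shape
    m = logB.max(axis=2)
    Bn = np.exp(logB - m[:, :, None])
    alpha = np.zeros((n_days, T_max, K))
    c = np.ones((n_days, T_max))
    ll = np.zeros(n_days)
    for t in range(T_max):
        active = t < lengths
        a = params.init[None, :] * Bn[:, 0] if t == 0 else (alpha[:, t - 1] @ params.tpm) * Bn[:, t]
        s = a.sum(axis=1)
        upd = active & (s > 0)
        ll[upd] += np.log(s[upd]) + m[upd, t]
        ll[active & (s <= 0)] = -np.inf
        safe = np.where(s > 0, s, 1.0)
        c[:, t] = safe
        alpha[upd, t] = (a / safe[:, None])[upd]
    beta = np.zeros((n_days, T_max, K))
    xi = np.zeros((K, K))
    last = lengths - 1
    beta[np.arange(n_days), last] = 1.0
    for t in range(T_max - 2, -1, -1):
        active = t < lengths - 1
        bb = Bn[:, t + 1] * beta[:, t + 1]
        # pairwise posteriors for the step t -> t+1
        contrib = (alpha[:, t][:, :, None] * params.tpm[None, :, :]
                   * bb[:, None, :]) / c[:, t + 1][:, None, None]
        xi += contrib[active].sum(axis=0)
        beta[active, t] = ((bb @ params.tpm.T) / c[:, t + 1][:, None])[active]
    gamma = alpha * beta
    norm_g = gamma.sum(axis=2, keepdims=True)
    gamma = np.divide(gamma, norm_g, out=np.zeros_like(gamma), where=norm_g > 0)
    gamma0 = gamma[:, 0, :].sum(axis=0)
    return float(ll.sum()), gamma, xi, gamma0


def _nll_and_grad(theta, series_list, K):
    """Negative forward log-likelihood and its exact gradient.

    Emission-parameter gradients use the Fisher identity (posterior-
    weighted score of the state densities); transition and initial
    gradients use the pairwise posteriors, chained through the softmax
    reparameterization.
    """
    try:
        p = _unpack(theta, K)
    except (ValueError, FloatingPointError):
        return 1e12, np.zeros_like(theta)
    ll, gamma, xi, gamma0 = _fb_stats(p, series_list)
    if not np.isfinite(ll):
        return 1e12, np.zeros_like(theta)

    g_init = gamma0 - gamma0.sum() * p.init
    g_tpm = xi - xi.sum(axis=1, keepdims=True) * p.tpm

    shape = (p.gamma_mean / p.gamma_sd) ** 2
    scale = p.gamma_sd**2 / p.gamma_mean
    g_logmean = np.zeros(K); g_logsd = np.zeros(K)
    g_mu = np.zeros(K); g_logkappa = np.zeros(K)
    for i, s in enumerate(series_list):
        g = gamma[i, : len(s)]
        x = np.maximum(s.speed, SPEED_FLOOR)
        logx = np.log(x)
        for j in range(K):
            w = g[:, j]
            dlda = logx - np.log(scale[j]) - digamma(shape[j])
            dlds = (x - shape[j] * scale[j]) / scale[j] ** 2
            g_logmean[j] += np.dot(w, 2.0 * shape[j] * dlda - scale[j] * dlds)
            g_logsd[j] += np.dot(w, -2.0 * shape[j] * dlda + 2.0 * scale[j] * dlds)
        ok = np.isfinite(s.angle)
        if ok.any():
            ang = s.angle[ok]
            gv = g[ok]
            for j in range(K):
                kap = max(p.vm_kappa[j], 1e-10)
                A = i1e(kap) / i0e(kap)
                g_mu[j] += np.dot(gv[:, j], kap * np.sin(ang - p.vm_mu[j]))
                g_logkappa[j] += kap * np.dot(gv[:, j], np.cos(ang - p.vm_mu[j]) - A)

    grad = np.concatenate([g_init, g_tpm.ravel(), g_logmean, g_logsd,
                           g_mu, g_logkappa])
    return -ll, -grad


def fit_hmm(series_list, n_starts: int = 25, seed=0, K: int = 3,
            maxiter: int = 400, explore_iter: int = 40) -> HmmFit:
    """Fit the pooled population-level HMM by multistart quasi-Newton
    maximization of the forward log-likelihood on an unconstrained
    reparameterization (log scales, row-wise multinomial logits), with
    exact analytic gradients.

    Each start runs a short exploration (``explore_iter`` L-BFGS
    iterations); the best start is then polished to convergence.  States
    are relabelled by ascending fitted gamma mean.
    """
    if isinstance(series_list, StepSeries):
        series_list = [series_list]
    rng = np.random.default_rng(seed)

    best = None
    start_lls, failures = [], []
    for s in range(n_starts):
        p0 = _random_start(series_list, rng, K)
        try:
            res = minimize(_nll_and_grad, _pack(p0), args=(series_list, K),
                           jac=True, method="L-BFGS-B",
                           options={"maxiter": explore_iter, "gtol": 1e-8,
                                    "ftol": 1e-12})
            start_lls.append(-float(res.fun))
            if best is None or res.fun < best.fun:
                best = res
        except Exception as exc:  # noqa: BLE001
            failures.append(str(exc))
            start_lls.append(-np.inf)
    if best is None:
        raise RuntimeError(f"all {n_starts} starts failed: {failures}")
    res = minimize(_nll_and_grad, best.x, args=(series_list, K), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": 1e-8, "ftol": 1e-13})
    final = res if res.fun <= best.fun else best
    params = _unpack(final.x, K).relabelled()
    return HmmFit(params=params, loglik=-float(final.fun), n_starts=n_starts,
                  start_logliks=start_lls, converged=bool(final.success))


def sample_hmm(params: HmmParams, lengths, seed=0) -> list[StepSeries]:
    """Sample observation series (and hidden states) from the model.

    Returns one StepSeries per entry of *lengths*; the generating states
    are attached as ``series.states`` for recovery checks.  The first
    angle of each day is masked, as in real data.
    """
    rng = np.random.default_rng(seed)
    K = params.n_states
    shape = (params.gamma_mean / params.gamma_sd) ** 2
    scale = params.gamma_sd**2 / params.gamma_mean
    out = []
    for d, T in enumerate(np.atleast_1d(lengths)):
        states = np.empty(T, dtype=int)
        states[0] = rng.choice(K, p=params.init)
        for t in range(1, T):
            states[t] = rng.choice(K, p=params.tpm[states[t - 1]])
        speed = rng.gamma(shape[states], scale[states])
        angle = rng.vonmises(params.vm_mu[states],
                             np.maximum(params.vm_kappa[states], 1e-8))
        angle[0] = np.nan
        s = StepSeries(speed=np.maximum(speed, SPEED_FLOOR), angle=angle,
                       day_id=f"sim{d}")
        s.states = states
        out.append(s)
    return out


# --------------------------------------------------------------------------
# decoding and checking
# --------------------------------------------------------------------------

def viterbi(fit: HmmFit | HmmParams, series: StepSeries) -> StateSequence:
    """Most-probable joint state path (log-space DP) plus forward-backward
    posterior state probabilities for one day."""
    params = fit.params if isinstance(fit, HmmFit) else fit
    logB = _log_emissions(params, series)
    T, K = logB.shape
    log_tpm = np.log(np.maximum(params.tpm, 1e-300))
    delta = np.log(np.maximum(params.init, 1e-300)) + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_tpm
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    states = np.zeros(T, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1][states[t + 1]]
    post = forward_backward(params, series)
    return StateSequence(states=states, posteriors=post, day_id=series.day_id)


def forward_backward(params: HmmParams, series: StepSeries) -> np.ndarray:
    """Posterior state marginals (T, K), rows summing to 1."""
    logB = _log_emissions(params, series)
    T, K = logB.shape
    m = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - m)
    alpha = np.zeros((T, K)); beta = np.ones((T, K))
    a = params.init * B[0]
    alpha[0] = a / a.sum()
    for t in range(1, T):
        a = (alpha[t - 1] @ params.tpm) * B[t]
        alpha[t] = a / a.sum()
    for t in range(T - 2, -1, -1):
        b = params.tpm @ (B[t + 1] * beta[t + 1])
        beta[t] = b / b.sum()
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


def pseudo_residuals(fit: HmmFit | HmmParams, series: StepSeries) -> dict[str, np.ndarray]:
    """One-step-ahead forecast pseudo-residuals per data stream.

    For each observation, the predictive CDF under the state mixture with
    weights P(S_t | y_{1:t-1}) is mapped through the standard-normal
    quantile; approximately N(0, 1) under a correct model.  Returned for
    the speed stream and (where defined) the angle stream.
    """
    params = fit.params if isinstance(fit, HmmFit) else fit
    logB = _log_emissions(params, series)
    T, K = logB.shape
    m = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - m)
    shape = (params.gamma_mean / params.gamma_sd) ** 2
    scale = params.gamma_sd**2 / params.gamma_mean
    w = np.zeros((T, K))
    alpha = params.init.copy()
    for t in range(T):
        w[t] = alpha if t == 0 else alpha @ params.tpm
        a = w[t] * B[t]
        alpha = a / a.sum()
    speed = np.maximum(series.speed, SPEED_FLOOR)
    cdf_speed = gamma_dist.cdf(speed[:, None], shape[None, :], scale=scale[None, :])
    u_speed = np.clip((w * cdf_speed).sum(axis=1), 1e-12, 1 - 1e-12)
    out = {"speed": norm.ppf(u_speed)}
    ang = series.angle
    ok = np.isfinite(ang)
    u_ang = np.full(T, np.nan)
    if ok.any():
        cdf_ang = vonmises.cdf(ang[ok][:, None],
                               np.maximum(params.vm_kappa, 1e-10)[None, :],
                               loc=params.vm_mu[None, :])
        u_ang[ok] = np.clip((w[ok] * cdf_ang).sum(axis=1), 1e-12, 1 - 1e-12)
    out["angle"] = norm.ppf(u_ang)
    return out


# --------------------------------------------------------------------------
# foraging classification
# --------------------------------------------------------------------------

def states_to_fixes(states_obs: np.ndarray, n_fixes: int) -> np.ndarray:
    """Map per-step decoded states to per-fix states (departure convention;
    the last fix inherits the final step's state)."""
    if len(states_obs) != n_fixes - 1:
        raise ValueError("expected one step per fix pair")
    return np.append(states_obs, states_obs[-1])


def classify_foraging(states_per_fix: np.ndarray, habitat_per_fix) -> np.ndarray:
    """A fix is a foraging occasion iff its decoded behaviour is stationary
    or short-distance movement AND it lies on agricultural land."""
    states_per_fix = np.asarray(states_per_fix)
    habitat = np.asarray(habitat_per_fix)
    behavioural = (states_per_fix == 0) | (states_per_fix == 1)
    agri = np.isin(habitat, AGRICULTURAL_CLASSES)
    return behavioural & agri
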