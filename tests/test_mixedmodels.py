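import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate
from scipy.special import expit

from cpforage import mixedmodels as mm

LEVELS = list("ABCDEF")


def _factor_data(seed=0, n_per=50, effects=None, family="gaussian"):
    rng = np.random.default_rng(seed)
    per = np.tile(LEVELS, n_per)
    n = len(per)
    eff = effects or dict.fromkeys(LEVELS, 0.0)
    eta = np.array([eff[p] for p in per])
    df = pd.DataFrame({"period": per, "g": rng.choice(8, n)})
    if family == "binomial":
        df["y"] = rng.binomial(1, expit(eta))
    elif family == "gamma":
        df["y"] = rng.gamma(2.0, np.exp(eta) / 2.0)
    else:
        df["y"] = eta + rng.normal(0, 1, n)
    return df


class TestGlmOracle:
    """sigma2_b fixed at 0 must reproduce a plain IRLS GLM."""

    @pytest.mark.parametrize("family, smfam", [
        ("binomial_logit", sm.families.Binomial()),
        ("gamma_log", sm.families.Gamma(sm.families.links.Log())),
        ("gaussian_identity", sm.families.Gaussian()),
    ])
    def test_matches_statsmodels(self, family, smfam):
        fam_key = {"binomial_logit": "binomial", "gamma_log": "gamma",
                   "gaussian_identity": "gaussian"}[family]
        eff = {l: v for l, v in zip(LEVELS, [0.2, 0.6, -0.4, 0.0, 0.3, 0.9])}
        df = _factor_data(seed=3, effects=eff, family=fam_key)
        fit = mm.fit_glmm(df, mm.GlmmSpec(
            family=family, response="y", factor="period", group="g",
            levels=LEVELS, fixed_intercept_variance=0.0))
        X = sm.add_constant(pd.get_dummies(
            pd.Categorical(df["period"], categories=LEVELS),
            drop_first=True).to_numpy(float))
        oracle = sm.GLM(df["y"].to_numpy(), X, family=smfam).fit()
        assert np.abs(fit.beta - oracle.params).max() < 1e-6

    def test_intercept_only_closed_form(self):
        # balanced 0/1 data with 40% successes: intercept = logit(0.4)
        df = pd.DataFrame({"y": [1] * 40 + [0] * 60, "g": 0})
        fit = mm.fit_glmm(df, mm.GlmmSpec(
            family="binomial_logit", response="y", group="g",
            fixed_intercept_variance=0.0))
        assert fit.beta[0] == pytest.approx(np.log(0.4 / 0.6), abs=1e-6)


class TestQuadratureAgainstBruteForce:
    def test_tiny_binomial_marginal_likelihood(self):
        rng = np.random.default_rng(2)
        G, m = 5, 4
        b = rng.normal(0, 0.7, G)
        x = rng.choice(["A", "B"], G * m)
        g = np.repeat(np.arange(G), m)
        eta = np.where(x == "B", 0.8, 0.2) + b[g]
        y = rng.binomial(1, expit(eta))
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        fit = mm.fit_glmm(df, mm.GlmmSpec(
            family="binomial_logit", response="y", factor="x", group="g",
            levels=["A", "B"]))

        def brute(beta0, beta1, s2b):
            tot = 0.0
            for gg in range(G):
                idx = g == gg

                def f(bb):
                    e = np.where(x[idx] == "B", beta0 + beta1, beta0) + bb
                    ll = (y[idx] * e - np.logaddexp(0, e)).sum()
                    return np.exp(ll - bb**2 / (2 * s2b)) / np.sqrt(2 * np.pi * s2b)

                hi = 6 * np.sqrt(s2b)
                v, _ = integrate.quad(f, -hi, hi, limit=300)
                tot += np.log(v)
            return tot

        assert abs(fit.loglik - brute(*fit.beta, fit.sigma2_b)) < 1e-4

    def test_variance_recovery_gamma(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(20):
            G, m = 30, 20
            b = rng.normal(0, np.sqrt(0.5), G)
            g = np.repeat(np.arange(G), m)
            y = rng.gamma(2.0, np.exp(1.0 + b[g]) / 2.0)
            df = pd.DataFrame({"y": y, "g": g})
            fit = mm.fit_glmm(df, mm.GlmmSpec(
                family="gamma_log", response="y", group="g"))
            hits += 0.25 <= fit.sigma2_b <= 0.85
        assert hits >= 16  # ~90% nominal


class TestWald:
    def test_zero_factor_effect_gives_p_one(self):
        df = _factor_data(seed=1)
        fit = mm.fit_glmm(df, mm.GlmmSpec(
            family="gaussian_identity", response="y", factor="period",
            group="g", levels=LEVELS))
        fit.beta[1:] = 0.0
        stat, dof, p = mm.wald_chisq(fit)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert dof == 5
        assert p == pytest.approx(1.0)

    def test_invariant_to_reference_level(self):
        eff = {l: v for l, v in zip(LEVELS, [0.0, 0.5, -0.2, 0.1, 0.4, 0.0])}
        df = _factor_data(seed=9, effects=eff)
        stats = []
        for ref in LEVELS:
            order = [ref] + [l for l in LEVELS if l != ref]
            fit = mm.fit_glmm(df, mm.GlmmSpec(
                family="gaussian_identity", response="y", factor="period",
                group="g", levels=order))
            stats.append(mm.wald_chisq(fit)[0])
        assert np.ptp(stats) < 1e-4 * max(stats)


class TestTukey:
    def _fit(self, seed=0, effects=None, levels=LEVELS):
        df = _factor_data(seed=seed, effects=effects)
        df = df[df["period"].isin(levels)]
        return mm.fit_glmm(df, mm.GlmmSpec(
            family="gaussian_identity", response="y", factor="period",
            group="g", levels=levels))

    def test_two_level_adjustment_is_identity(self):
        fit = self._fit(levels=["A", "B"])
        ph = mm.posthoc_tukey(fit)
        assert np.allclose(ph.p_adjusted, ph.p_unadjusted)

    def test_adjusted_never_below_unadjusted(self):
        eff = {l: v for l, v in zip(LEVELS, [0, 0.8, 0.1, -0.5, 0.3, 0])}
        fit = self._fit(seed=4, effects=eff)
        ph = mm.posthoc_tukey(fit, seed=1)
        assert len(ph.pairs) == 15
        assert (ph.p_adjusted >= ph.p_unadjusted - 1e-12).all()
        assert (ph.p_adjusted <= 1.0).all()

    def test_adjustment_deterministic_under_seed(self):
        fit = self._fit(seed=4)
        a = mm.posthoc_tukey(fit, seed=3).p_adjusted
        b = mm.posthoc_tukey(fit, seed=3).p_adjusted
        assert np.array_equal(a, b)

    def test_letters_separate_clear_groups(self):
        # huge separation between {A,B,C} and {D,E,F}
        eff = {"A": 0, "B": 0, "C": 0, "D": 8, "E": 8, "F": 8}
        fit = self._fit(seed=6, effects=eff)
        ph = mm.posthoc_tukey(fit, seed=0)
        low = {ph.letters[l] for l in "ABC"}
        high = {ph.letters[l] for l in "DEF"}
        assert low == {"a"} and high == {"b"}

    def test_letters_share_when_null(self):
        fit = self._fit(seed=9)
        ph = mm.posthoc_tukey(fit, seed=0)
        assert set(ph.letters.values()) == {"a"}


class TestCompactLetters:
    def test_insert_absorb_chain(self):
        # A<B significant, B<C significant, A~B ns? classic chain:
        # A differs from C only
        levels = ["A", "B", "C"]
        sig = {("A", "C"): True}
        letters = mm.compact_letters(levels, sig,
                                     order_by={"A": 0, "B": 1, "C": 2})
        assert set(letters["B"]) & set(letters["A"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])


class TestPseudoR2:
    def test_no_fixed_variation_gives_zero_marginal(self):
        df = _factor_data(seed=10)
        fit = mm.fit_glmm(df, mm.GlmmSpec(
            family="gaussian_identity", response="y", group="g"))
        r2 = mm.pseudo_r2(fit)
        assert r2.r2m == pytest.approx(0.0, abs=1e-12)
        assert r2.r2m <= r2.r2c <= 1.0

    def test_gaussian_without_random_effect_matches_classical_r2(self):
        eff = {l: v for l, v in zip(LEVELS, [0, 1.0, -1.0, 0.5, 0.2, 0.8])}
        df = _factor_data(seed=11, effects=eff)
        fit = mm.fit_glmm(df, mm.GlmmSpec(
            family="gaussian_identity", response="y", factor="period",
            group="g", levels=LEVELS, fixed_intercept_variance=0.0))
        r2 = mm.pseudo_r2(fit)
        X = sm.add_constant(pd.get_dummies(
            pd.Categorical(df["period"], categories=LEVELS),
            drop_first=True).to_numpy(float))
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        assert r2.r2m == pytest.approx(ols.rsquared, abs=1e-6)
        assert r2.r2c == pytest.approx(r2.r2m, abs=1e-9)

    def test_marginal_never_exceeds_conditional(self):
        eff = {l: v for l, v in zip(LEVELS, [0, 0.5, 0.2, -0.1, 0.3, 0.4])}
        for fam, key in [("gaussian_identity", "gaussian"),
                         ("binomial_logit", "binomial"),
                         ("gamma_log", "gamma")]:
            df = _factor_data(seed=12, effects=eff, family=key)
            fit = mm.fit_glmm(df, mm.GlmmSpec(
                family=fam, response="y", factor="period", group="g",
                levels=LEVELS))
            r2 = mm.pseudo_r2(fit)
            assert 0.0 <= r2.r2m <= r2.r2c <= 1.0


class TestWeights:
    def test_weighted_binomial_moves_intercept(self):
        # weighting the zeros by w shifts the intercept by about -log(w)
        df = pd.DataFrame({
            "y": [1.0] * 100 + [0.0] * 100,
            "w": [1.0] * 100 + [50.0] * 100,
            "g": 0,
        })
        fit = mm.fit_glmm(df, mm.GlmmSpec(
            family="binomial_logit", response="y", group="g", weights="w",
            fixed_intercept_variance=0.0))
        assert fit.beta[0] == pytest.approx(np.log(1 / 50), abs=1e-6)
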