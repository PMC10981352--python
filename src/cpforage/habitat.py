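"""Daily habitat use and duration statistics, habitat-selection functions
(HSFs), and their k-fold cross-validation.

Use probability: per tracking day and habitat, whether at least one
foraging occasion occurred; modelled per habitat as a binomial-logit GLMM
with the biological period fixed and the year-bird random (unless a
habitat is used on more than 99 % of days, where raw proportions are
reported instead of a model).  Duration: foraging-fix count times the
5-min acquisition lag, conditional on use, modelled as gamma-log GLMMs.

The HSF is a weighted used-available logistic model fitted separately per
biological period: for each used (foraging) fix, ten availability points
are drawn area-uniformly in the circle centered on the nest with radius
equal to that day's farthest-isopleth-limit distance; available points get
weight 1000 and response 0, used points weight 1 and response 1; each
tracking day is a stratum whose intercept has a fixed large variance.
Exponentiated habitat coefficients are relative selection strengths (RSS)
against the grassland reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

from .mixedmodels import GlmmFit, GlmmSpec, fit_glmm
from .raster import AGRICULTURAL_CLASSES, HabitatMap

logger = logging.getLogger(__name__)

__all__ = [
    "MAIN_HABITATS",
    "HsfFit",
    "CvResult",
    "tabulate_use",
    "fit_use_models",
    "tabulate_duration",
    "fit_duration_models",
    "sample_available",
    "build_hsf_design",
    "fit_hsf",
    "kfold_cv",
]

MAIN_HABITATS = ("grassland", "cereal", "maize")
HSF_HABITATS = ("grassland", "cereal", "maize", "other_agri")
FIX_INTERVAL_MIN = 5.0


# --------------------------------------------------------------------------
# daily use and duration
# --------------------------------------------------------------------------

def tabulate_use(fixes: pd.DataFrame,
                 habitats=AGRICULTURAL_CLASSES) -> pd.DataFrame:
    """One record per tracking day with per-habitat foraging-fix counts and
    used flags (used <=> count > 0).

    *fixes* must carry columns year_bird, date, period, habitat, foraging.
    """
    recs = []
    for (yb, date, period), day in fixes.groupby(["year_bird", "date", "period"],
                                                 sort=True):
        rec = {"year_bird": yb, "date": date, "period": period}
        forag = day[day["foraging"]]
        counts = forag["habitat"].value_counts()
        for h in habitats:
            c = int(counts.get(h, 0))
            rec[f"count_{h}"] = c
            rec[f"used_{h}"] = int(c > 0)
        recs.append(rec)
    return pd.DataFrame(recs)


def fit_use_models(use_records: pd.DataFrame, period_levels,
                   habitats=MAIN_HABITATS, near_one: float = 0.99) -> dict:
    """Binomial-logit GLMM of daily use per habitat (period fixed,
    year-bird random); habitats used on > ``near_one`` of days get raw
    per-period proportions instead of a model."""
    out = {}
    for h in habitats:
        col = f"used_{h}"
        prop = use_records[col].mean()
        if prop > near_one:
            raw = use_records.groupby("period")[col].mean()
            out[h] = {"model": None,
                      "raw_proportions": raw.reindex(period_levels).to_dict(),
                      "overall": float(prop)}
            continue
        spec = GlmmSpec(family="binomial_logit", response=col,
                        factor="period", group="year_bird",
                        levels=list(period_levels))
        out[h] = {"model": fit_glmm(use_records, spec), "raw_proportions": None,
                  "overall": float(prop)}
    return out


def tabulate_duration(use_records: pd.DataFrame,
                      habitats=MAIN_HABITATS) -> pd.DataFrame:
    """Conditional-on-use daily foraging durations: minutes = 5 x count,
    one row per (day, habitat) with count > 0 (no zero rows)."""
    rows = []
    for h in habitats:
        sub = use_records[use_records[f"count_{h}"] > 0]
        for r in sub.itertuples():
            rows.append({
                "year_bird": r.year_bird, "date": r.date, "period": r.period,
                "habitat": h,
                "minutes": FIX_INTERVAL_MIN * getattr(r, f"count_{h}"),
            })
    return pd.DataFrame(rows, columns=["year_bird", "date", "period",
                                       "habitat", "minutes"])


def fit_duration_models(durations: pd.DataFrame, period_levels,
                        habitats=MAIN_HABITATS) -> dict:
    """Gamma-log GLMM of conditional daily duration per habitat."""
    out = {}
    for h in habitats:
        sub = durations[durations["habitat"] == h]
        if sub.empty or sub["period"].nunique() < 2:
            out[h] = None
            continue
        levels = [p for p in period_levels if (sub["period"] == p).any()]
        spec = GlmmSpec(family="gamma_log", response="minutes",
                        factor="period", group="year_bird", levels=levels)
        out[h] = fit_glmm(sub, spec)
    return out


# --------------------------------------------------------------------------
# availability sampling
# --------------------------------------------------------------------------

def sample_available(n_used: int, nest_xy, radius_m: float,
                     habitat_map: HabitatMap, ratio: int = 10, seed=0,
                     max_redraws: int = 1000) -> pd.DataFrame:
    """Area-uniform availability points in the nest-centered circle.

    Draws ``ratio`` points per used fix (r = R sqrt(u), theta uniform);
    points landing on non-agricultural cells are redrawn, up to
    ``max_redraws`` attempts per point.  Each point is labelled with its
    habitat class.
    """
    rng = np.random.default_rng(seed)
    n = n_used * ratio
    xs = np.empty(n); ys = np.empty(n)
    hab = np.empty(n, dtype=object)
    pending = np.arange(n)
    for attempt in range(max_redraws):
        m = len(pending)
        if m == 0:
            break
        r = radius_m * np.sqrt(rng.uniform(size=m))
        th = rng.uniform(0.0, 2.0 * np.pi, size=m)
        px = nest_xy[0] + r * np.cos(th)
        py = nest_xy[1] + r * np.sin(th)
        inside = habitat_map.contains(px, py)
        codes = np.full(m, -1)
        if inside.any():
            codes[inside] = habitat_map.class_code_at(px[inside], py[inside])
        labels = np.array([habitat_map.classes[c] if c >= 0 else "outside"
                           for c in codes], dtype=object)
        ok = inside & np.isin(labels, AGRICULTURAL_CLASSES)
        idx = pending[ok]
        xs[idx] = px[ok]; ys[idx] = py[ok]; hab[idx] = labels[ok]
        pending = pending[~ok]
    if len(pending) > 0:
        raise RuntimeError(
            f"redraw cap hit: circle at {nest_xy} (r={radius_m:.0f} m) is "
            f"almost entirely non-agricultural ({len(pending)} points left)")
    return pd.DataFrame({"x": xs, "y": ys, "habitat": hab})


def build_hsf_design(foraging_fixes: pd.DataFrame, day_radii: pd.DataFrame,
                     nests: dict, habitat_map: HabitatMap, ratio: int = 10,
                     seed=0) -> pd.DataFrame:
    """Used-available design rows for the HSF of one or more periods.

    Parameters
    ----------
    foraging_fixes : rows = used foraging fixes with columns year_bird,
        date, period, habitat (agricultural classes only).
    day_radii : columns year_bird, date, radius_m (the farthest-limit
        distance of that day, in meters).
    nests : mapping year_bird -> (x, y).

    Returns the stacked design: response (1 used / 0 available), weight
    (1 / 1000), habitat, stratum (tracking day), year_bird, period.  The
    available:used row ratio is exactly ``ratio`` : 1.
    """
    rng = np.random.default_rng(seed)
    radii = {(r.year_bird, r.date): float(r.radius_m) for r in day_radii.itertuples()}
    frames = []
    for (yb, date, period), day in foraging_fixes.groupby(
            ["year_bird", "date", "period"], sort=True):
        if (yb, date) not in radii:
            continue
        stratum = f"{yb}|{date}"
        used = pd.DataFrame({
            "response": 1.0, "weight": 1.0,
            "habitat": day["habitat"].to_numpy(),
            "stratum": stratum, "year_bird": yb, "period": period,
        })
        avail = sample_available(len(day), nests[yb], radii[(yb, date)],
                                 habitat_map, ratio=ratio,
                                 seed=rng.integers(2**31))
        avail = pd.DataFrame({
            "response": 0.0, "weight": 1000.0,
            "habitat": avail["habitat"].to_numpy(),
            "stratum": stratum, "year_bird": yb, "period": period,
        })
        frames.append(used); frames.append(avail)
    if not frames:
        return pd.DataFrame(columns=["response", "weight", "habitat",
                                     "stratum", "year_bird", "period"])
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# HSF fitting
# --------------------------------------------------------------------------

@dataclass
class HsfFit:
    period: str
    habitats: list[str]                # non-reference habitats in the fit
    log_rss: dict[str, float]          # log relative selection strength
    se: dict[str, float]
    ci_low: dict[str, float]           # 95 % CI on the RSS (exponentiated)
    ci_high: dict[str, float]
    rss: dict[str, float]
    glmm: GlmmFit = field(repr=False, default=None)


def fit_hsf(design: pd.DataFrame, period: str | None = None,
            fixed_variance: float = 1e4, n_quad: int = 1) -> HsfFit:
    """Weighted used-available logistic mixed model for one period.

    Tracking-day stratum intercepts are kept at a fixed large variance
    (default 1e4 on the logit scale) so each day carries its own
    availability baseline without a variance component to estimate;
    grassland is the reference habitat.  Returns exponentiated
    coefficients (RSS) with Wald 95 % CIs.

    With the variance held fixed, the marginal likelihood is integrated
    by the Laplace approximation (``n_quad=1``), which is exact in the
    flat-prior limit the large fixed variance approaches.
    """
    if period is not None:
        design = design[design["period"] == period]
    if design.empty:
        raise ValueError("empty HSF design")
    present = [h for h in HSF_HABITATS if (design["habitat"] == h).any()]
    dropped = [h for h in HSF_HABITATS if h not in present]
    if dropped:
        logger.warning("habitats absent from design, dropped: %s", dropped)
    if len(present) < 2:
        raise ValueError("need at least 2 habitats present in the design")
    spec = GlmmSpec(family="binomial_logit", response="response",
                    factor="habitat", group="stratum", levels=present,
                    weights="weight", fixed_intercept_variance=fixed_variance,
                    n_quad=n_quad)
    fit = fit_glmm(design, spec)
    zc = norm.ppf(0.975)
    log_rss, se, lo, hi, rss = {}, {}, {}, {}, {}
    for i, name in enumerate(fit.beta_names):
        if name == "(Intercept)":
            continue
        h = name.split("[")[1].rstrip("]")
        b = float(fit.beta[i])
        s = float(np.sqrt(max(fit.cov_beta[i, i], 0.0)))
        log_rss[h], se[h] = b, s
        lo[h], hi[h] = float(np.exp(b - zc * s)), float(np.exp(b + zc * s))
        rss[h] = float(np.exp(b))
    return HsfFit(period=period or "all", habitats=[h for h in present if h != present[0]],
                  log_rss=log_rss, se=se, ci_low=lo, ci_high=hi, rss=rss, glmm=fit)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class CvResult:
    fold_correlations: list[float]
    n_folds: int
    n_bins: int

    @property
    def mean_correlation(self) -> float:
        return float(np.nanmean(self.fold_correlations))


def kfold_cv(design: pd.DataFrame, k: int = 5, bins: int = 10, seed=0,
             fixed_variance: float = 1e4, n_quad: int = 1) -> CvResult:
    """k-fold cross-validation of an HSF, folds stratified by tracking day.

    Each fold is fitted on the remaining days; held-out rows (used +
    available) are scored by the fixed-effect linear predictor, rank-binned
    into ``bins`` equal-size bins (ties broken at random), and the Spearman
    correlation between bin rank and the proportion of used rows per bin is
    recorded.
    """
    days = np.array(sorted(design["stratum"].unique()))
    if len(days) < k:
        raise ValueError(f"need at least k={k} tracking days, have {len(days)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(days))
    folds = np.array_split(days[perm], k)
    cors = []
    used_bins = bins
    for fold_days in folds:
        test_mask = design["stratum"].isin(fold_days)
        train, test = design[~test_mask], design[test_mask]
        if test.empty or train.empty:
            continue
        fit = fit_hsf(train, fixed_variance=fixed_variance, n_quad=n_quad)
        coef = {h: fit.log_rss.get(h, 0.0) for h in HSF_HABITATS}
        coef[fit.glmm.levels[0]] = 0.0
        scores = test["habitat"].map(coef).fillna(0.0).to_numpy()
        n_bins = min(bins, max(2, len(test) // 5))
        if n_bins < bins:
            logger.warning("reducing bin count to %d (few held-out rows)", n_bins)
        used_bins = n_bins
        order = np.lexsort((rng.uniform(size=len(scores)), scores))
        resp = test["response"].to_numpy()[order]
        chunks = np.array_split(resp, n_bins)
        props = np.array([c.mean() for c in chunks if len(c)])
        ranks = np.arange(len(props))
        if np.allclose(props, props[0]):
            cors.append(0.0)
        else:
            rho = spearmanr(ranks, props).statistic
            cors.append(float(rho))
    return CvResult(fold_correlations=cors, n_folds=len(cors), n_bins=used_bins)
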