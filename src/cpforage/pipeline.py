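"""End-to-end orchestration: simulate (or load) a study, preprocess,
segment, estimate daily occurrence distributions and descriptors, fit the
mixed models, and fit/cross-validate the habitat-selection functions.

Every stochastic stage derives its seed deterministically from the master
seed and the stage name, so editing one stage's parameters never perturbs
another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import habitat as hab
from . import hmm as hmm_mod
from . import mixedmodels as mm
from . import occurrence as occ
from .periods import PERIOD_ORDER, PeriodCalendar, default_calendar
from .preprocess import TrackingDay, preprocess_study, read_fixes, read_nests
from .raster import HabitatMap, read_ascii_grid
from .synthetic import SyntheticScenario, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "stage_seed", "run_pipeline",
           "decode_and_classify", "make_report"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    output_dir: str = "cpforage_out"
    # either a synthetic scenario ...
    scenario: SyntheticScenario | None = None
    # ... or input paths
    fixes_path: str | None = None
    nests_path: str | None = None
    raster_path: str | None = None
    crs: str = "projected"
    latlon: tuple[float, float] = (47.866, -3.550)
    fix_interval_min: float = 5.0
    max_missing_frac: float = 0.05
    hmm_n_starts: int = 10
    hmm_max_fit_steps: int = 30000
    brb_cell: float = 20.0
    brb_t_max_min: float = 30.0
    brb_l_min: float = 5.0
    brb_h_min: float = 20.0
    hsf_ratio: int = 10
    hsf_fixed_variance: float = 1e4
    cv_k: int = 5
    cv_bins: int = 10
    master_seed: int = 0
    write_outputs: bool = True


@dataclass
class PipelineResult:
    config: PipelineConfig
    fixes: pd.DataFrame = None
    nests: pd.DataFrame = None
    habitat_map: HabitatMap = None
    truth: dict | None = None
    days: list = field(default_factory=list)
    rejections: list = field(default_factory=list)
    hmm_fit: object = None
    classified: pd.DataFrame = None
    descriptors: pd.DataFrame = None
    descriptor_models: dict = field(default_factory=dict)
    use_records: pd.DataFrame = None
    use_models: dict = field(default_factory=dict)
    durations: pd.DataFrame = None
    duration_models: dict = field(default_factory=dict)
    use_models_raw: dict = field(default_factory=dict)
    hsf_design: pd.DataFrame = None
    hsf_fits: dict = field(default_factory=dict)
    cv_results: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def decode_and_classify(days: list[TrackingDay], fit, habitat_map: HabitatMap,
                        interval_min: float = 5.0) -> pd.DataFrame:
    """Decode every tracking day with a fitted HMM and classify foraging.

    Returns the fix-level table with columns year_bird, date, period, x, y,
    interpolated, habitat, state (label), p_state1..3, foraging.
    """
    frames = []
    for day in days:
        series = hmm_mod.compute_steps(day.fixes, interval_min=interval_min,
                                       day_id=f"{day.year_bird}|{day.date}")
        seq = hmm_mod.viterbi(fit, series)
        states_fix = hmm_mod.states_to_fixes(seq.states, len(day.fixes))
        post = np.vstack([seq.posteriors, seq.posteriors[-1]])
        habs = habitat_map.classes
        x = day.fixes["x"].to_numpy(); y = day.fixes["y"].to_numpy()
        inside = habitat_map.contains(x, y)
        hab_labels = np.full(len(x), "non_agri", dtype=object)
        if inside.any():
            codes = habitat_map.class_code_at(x[inside], y[inside])
            hab_labels[inside] = [habs[c] for c in codes]
        df = day.fixes[["timestamp", "x", "y", "interpolated"]].copy()
        df.insert(0, "year_bird", day.year_bird)
        df.insert(1, "date", day.date)
        df.insert(2, "period", day.period)
        df["habitat"] = hab_labels
        df["state"] = [hmm_mod.STATE_LABELS[s] for s in states_fix]
        for k in range(post.shape[1]):
            df[f"p_state{k + 1}"] = post[:, k]
        df["foraging"] = hmm_mod.classify_foraging(states_fix, hab_labels)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _fit_population_hmm(days, config):
    rng = np.random.default_rng(stage_seed(config.master_seed, "hmm_fit_subsample"))
    series = []
    total = 0
    order = rng.permutation(len(days))
    for i in order:
        d = days[i]
        if d.n_fixes < 3:
            continue
        s = hmm_mod.compute_steps(d.fixes, interval_min=config.fix_interval_min,
                                  day_id=f"{d.year_bird}|{d.date}")
        series.append(s)
        total += len(s)
        if total >= config.hmm_max_fit_steps:
            break
    return hmm_mod.fit_hmm(series, n_starts=config.hmm_n_starts,
                           seed=stage_seed(config.master_seed, "hmm_fit"))


def _occurrence_stage(days, config):
    # per-bird diffusion, shared across the bird's days
    by_bird: dict[str, list] = {}
    for d in days:
        by_bird.setdefault(d.year_bird, []).append(d)
    D_of = {}
    for yb, bird_days in by_bird.items():
        tracks = [d.fixes[["x", "y"]].to_numpy(float) for d in bird_days]
        try:
            D_of[yb] = occ.estimate_diffusion(tracks, interval_min=config.fix_interval_min,
                                              h_min=config.brb_h_min)
        except ValueError:
            D_of[yb] = occ.D_FLOOR
    uds, regions = {}, {}
    rows = []
    for d in days:
        key = (d.year_bird, d.date)
        ud = occ.brb_ud(d.fixes, D_of[d.year_bird], cell=config.brb_cell,
                        t_max_min=config.brb_t_max_min, l_min=config.brb_l_min,
                        h_min=config.brb_h_min, day_id=f"{d.year_bird}|{d.date}")
        uds[key] = ud
        regions[key] = occ.isopleth(ud, 0.95)
    # overlaps within (year_bird, period)
    group: dict[tuple, list] = {}
    for d in days:
        group.setdefault((d.year_bird, d.period), []).append(d)
    for (yb, period), ds in group.items():
        for d in ds:
            key = (d.year_bird, d.date)
            others = [regions[(o.year_bird, o.date)] for o in ds if o.date != d.date]
            desc = occ.day_descriptors(uds[key], regions[key], d.nest_xy,
                                       others, d.year_bird, d.date, d.period)
            rows.append(dataclasses.asdict(desc))
    descriptors = pd.DataFrame(rows)
    return descriptors, uds, regions, D_of


def _descriptor_models(descriptors, period_levels):
    """The four descriptor models: gamma-log GLMMs for area and the two
    nest distances, a gaussian LMM for the overlap (spatial fidelity)."""
    out = {}
    specs = {
        "area_km2": "gamma_log",
        "mean_overlap_pct": "gaussian_identity",
        "centroid_nest_km": "gamma_log",
        "farthest_nest_km": "gamma_log",
    }
    for resp, family in specs.items():
        data = descriptors.dropna(subset=[resp]).copy()
        if family == "gamma_log":
            data = data[data[resp] > 0]
        if data.empty or data["period"].nunique() < 2:
            out[resp] = None
            continue
        levels = [p for p in period_levels if (data["period"] == p).any()]
        fit = mm.fit_glmm(data, mm.GlmmSpec(family=family, response=resp,
                                            factor="period", group="year_bird",
                                            levels=levels))
        out[resp] = _inference_bundle(fit)
    return out


def _inference_bundle(fit):
    # a single observed factor level leaves nothing to test or contrast
    if len(fit.levels) < 2:
        return {"fit": fit, "wald": None, "posthoc": None,
                "r2": mm.pseudo_r2(fit), "emmeans": mm.emmeans_table(fit)}
    stat, df, p = mm.wald_chisq(fit)
    posthoc = mm.posthoc_tukey(fit, seed=0)
    r2 = mm.pseudo_r2(fit)
    return {"fit": fit, "wald": {"chisq": stat, "df": df, "p": p},
            "posthoc": posthoc, "r2": r2,
            "emmeans": mm.emmeans_table(fit)}


def _hsf_stage(result: PipelineResult, config: PipelineConfig):
    classified = result.classified
    # the used-available design is built from *recorded* foraging locations:
    # interpolated positions are model output, not observed habitat choices
    foraging = classified[classified["foraging"]
                          & ~classified["interpolated"]].copy()
    radii = (result.descriptors
             .assign(radius_m=lambda d: d["farthest_nest_km"] * 1000.0)
             [["year_bird", "date", "radius_m"]])
    nests = {d.year_bird: d.nest_xy for d in result.days}
    design = hab.build_hsf_design(
        foraging[["year_bird", "date", "period", "habitat"]], radii, nests,
        result.habitat_map, ratio=config.hsf_ratio,
        seed=stage_seed(config.master_seed, "hsf_available"))
    hsf_fits, cv_results = {}, {}
    for period in PERIOD_ORDER:
        sub = design[design["period"] == period]
        if sub.empty or sub[sub["response"] == 1].empty:
            continue
        try:
            hsf_fits[period] = hab.fit_hsf(sub, period=period,
                                           fixed_variance=config.hsf_fixed_variance)
        except (ValueError, RuntimeError) as exc:
            logger.warning("HSF for %s skipped: %s", period, exc)
            continue
        n_days = sub["stratum"].nunique()
        k = min(config.cv_k, n_days)
        if k >= 2:
            cv_results[period] = hab.kfold_cv(
                sub, k=k, bins=config.cv_bins,
                seed=stage_seed(config.master_seed, f"cv_{period}"),
                fixed_variance=config.hsf_fixed_variance)
    return design, hsf_fits, cv_results


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig,
                 calendar: PeriodCalendar | None = None) -> PipelineResult:
    """Execute the full analysis; writes tables, model summaries and a
    manifest under ``config.output_dir`` (unless ``write_outputs=False``).

    Any stage failure raises :class:`StageError` naming the stage, after
    writing a partial manifest.
    """
    calendar = calendar or default_calendar()
    result = PipelineResult(config=config)
    out = Path(config.output_dir)
    if config.write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "parameters": _jsonable(dataclasses.asdict(config)),
                "seeds": {}}
    result.manifest = manifest

    def stage(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"].append({"name": name, "status": "ok"})
            except Exception as exc:
                manifest["stages"].append({"name": name, "status": "failed",
                                           "error": str(exc)})
                if config.write_outputs:
                    (out / "manifest.json").write_text(
                        json.dumps(manifest, indent=2, default=str))
                raise StageError(name, exc) from exc
        return deco

    @stage("inputs")
    def _inputs():
        if config.scenario is not None:
            scen = dataclasses.replace(
                config.scenario,
                seed=stage_seed(config.master_seed, "simulate"))
            fixes, nests, hmap, truth = generate_study(scen, calendar)
            result.fixes, result.nests = fixes, nests
            result.habitat_map, result.truth = hmap, truth
            if config.write_outputs:
                fixes.to_csv(out / "fixes.csv", index=False)
                nests.to_csv(out / "nests.csv", index=False)
                hmap.write(out / "habitat.asc")
                (out / "truth.json").write_text(json.dumps(truth, indent=2))
        else:
            result.fixes = read_fixes(config.fixes_path, crs=config.crs)
            result.nests = read_nests(config.nests_path)
            result.habitat_map = read_ascii_grid(config.raster_path)

    @stage("preprocess")
    def _pre():
        days, rej = preprocess_study(
            result.fixes, result.nests, config.latlon, calendar,
            interval_min=config.fix_interval_min,
            max_missing_frac=config.max_missing_frac)
        if not days:
            raise ValueError("no tracking days survived preprocessing")
        result.days, result.rejections = days, rej
        if config.write_outputs and rej:
            pd.DataFrame([dataclasses.asdict(r) for r in rej]).to_csv(
                out / "rejected_days.csv", index=False)

    @stage("hmm")
    def _hmm():
        result.hmm_fit = _fit_population_hmm(result.days, config)
        result.classified = decode_and_classify(
            result.days, result.hmm_fit, result.habitat_map,
            interval_min=config.fix_interval_min)
        if config.write_outputs:
            result.classified.to_csv(out / "classified_fixes.csv", index=False)
            p = result.hmm_fit.params
            (out / "hmm_params.json").write_text(json.dumps({
                "init": p.init.tolist(), "tpm": p.tpm.tolist(),
                "gamma_mean": p.gamma_mean.tolist(),
                "gamma_sd": p.gamma_sd.tolist(),
                "vm_mu": p.vm_mu.tolist(), "vm_kappa": p.vm_kappa.tolist(),
                "loglik": result.hmm_fit.loglik,
                "n_starts": result.hmm_fit.n_starts}, indent=2))

    @stage("occurrence")
    def _occ():
        descriptors, _, _, D_of = _occurrence_stage(result.days, config)
        result.descriptors = descriptors
        if config.write_outputs:
            descriptors.to_csv(out / "day_descriptors.csv", index=False)
            (out / "diffusion.json").write_text(json.dumps(D_of, indent=2))

    @stage("descriptor_models")
    def _dmod():
        result.descriptor_models = _descriptor_models(result.descriptors,
                                                      calendar.names)
        if config.write_outputs:
            _write_model_summaries(out / "descriptor_models.json",
                                   result.descriptor_models)

    @stage("use_duration")
    def _use():
        result.use_records = hab.tabulate_use(result.classified)
        use_fits = hab.fit_use_models(result.use_records, calendar.names)
        result.use_models = {
            h: (None if v["model"] is None else _inference_bundle(v["model"]))
            if isinstance(v, dict) and "model" in v else v
            for h, v in use_fits.items()}
        result.use_models_raw = use_fits
        result.durations = hab.tabulate_duration(result.use_records)
        dur_fits = hab.fit_duration_models(result.durations, calendar.names)
        result.duration_models = {
            h: None if f is None else _inference_bundle(f)
            for h, f in dur_fits.items()}
        if config.write_outputs:
            result.use_records.to_csv(out / "daily_use.csv", index=False)
            result.durations.to_csv(out / "daily_durations.csv", index=False)
            _write_model_summaries(out / "use_models.json", result.use_models)
            _write_model_summaries(out / "duration_models.json",
                                   result.duration_models)

    @stage("hsf")
    def _hsf():
        design, hsf_fits, cv_results = _hsf_stage(result, config)
        result.hsf_design = design
        result.hsf_fits, result.cv_results = hsf_fits, cv_results
        if config.write_outputs:
            rows = []
            for period, f in hsf_fits.items():
                for h in f.log_rss:
                    rows.append({"period": period, "habitat": h,
                                 "log_rss": f.log_rss[h], "se": f.se[h],
                                 "rss": f.rss[h], "ci_low": f.ci_low[h],
                                 "ci_high": f.ci_high[h]})
            pd.DataFrame(rows).to_csv(out / "hsf_rss.csv", index=False)
            cv_rows = [{"period": p, "mean_spearman": c.mean_correlation,
                        "n_folds": c.n_folds}
                       for p, c in cv_results.items()]
            pd.DataFrame(cv_rows).to_csv(out / "hsf_cv.csv", index=False)

    if config.write_outputs:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        (out / "report.md").write_text(make_report(result))
    return result


def _write_model_summaries(path, bundles):
    blob = {}
    for key, b in bundles.items():
        if b is None:
            blob[key] = None
            continue
        fit = b["fit"]
        blob[key] = {
            "beta": dict(zip(fit.beta_names, fit.beta.tolist())),
            "sigma2_b": fit.sigma2_b, "phi": fit.phi, "sigma2_e": fit.sigma2_e,
            "loglik": fit.loglik,
            "wald": b["wald"],
            "r2m": b["r2"].r2m, "r2c": b["r2"].r2c,
            "letters": b["posthoc"].letters if b["posthoc"] else None,
            "emmeans": b["emmeans"].to_dict("records"),
        }
    Path(path).write_text(json.dumps(blob, indent=2, default=str))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    return obj


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def make_report(result: PipelineResult) -> str:
    """Render a human-readable summary: tracking effort per period, daily
    use probabilities with CIs and letters, durations, descriptors, and
    relative selection strengths."""
    lines = ["# Central-place forager movement analysis — run report", ""]

    if result.days:
        eff = pd.DataFrame([{
            "period": d.period, "year_bird": d.year_bird,
            "n_fixes": d.n_fixes} for d in result.days])
        lines.append("## Tracking effort")
        lines.append("")
        lines.append("| period | year-birds | tracking days | mean fixes/day |")
        lines.append("|---|---|---|---|")
        for period in PERIOD_ORDER:
            sub = eff[eff["period"] == period]
            if sub.empty:
                continue
            lines.append(f"| {period} | {sub['year_bird'].nunique()} | "
                         f"{len(sub)} | {sub['n_fixes'].mean():.1f} |")
        lines.append("")

    def model_section(title, bundles, value_fmt="{:.3f}"):
        if not bundles:
            return
        lines.append(f"## {title}")
        lines.append("")
        for key, b in bundles.items():
            if b is None:
                lines.append(f"- {key}: no model (fewer than two periods "
                             "observed, or reported as raw proportions)")
                continue
            w = b["wald"]
            if w is not None:
                lines.append(
                    f"- **{key}**: Wald chi2 = {w['chisq']:.2f}, df = {w['df']}, "
                    f"p = {w['p']:.3g}; R2m = {b['r2'].r2m:.2f}, "
                    f"R2c = {b['r2'].r2c:.2f}")
            else:
                lines.append(f"- **{key}**: single period observed, no "
                             f"cross-period contrasts; R2m = {b['r2'].r2m:.2f}, "
                             f"R2c = {b['r2'].r2c:.2f}")
            em = b["emmeans"]
            letters = b["posthoc"].letters if b["posthoc"] else {}
            for r in em.itertuples():
                lines.append(
                    f"    - {r.level}: " + value_fmt.format(r.mean)
                    + f" ({value_fmt.format(r.ci_low)}-"
                    + f"{value_fmt.format(r.ci_high)}) {letters.get(r.level, '')}")
        lines.append("")

    model_section("Daily occurrence descriptors", result.descriptor_models)
    if isinstance(result.use_models, dict):
        model_section("Daily use probability", {
            h: v for h, v in result.use_models.items() if v is not None})
        raw = {h: v for h, v in getattr(result, "use_models_raw", {}).items()
               if isinstance(v, dict) and v.get("model") is None}
        for h, v in raw.items():
            lines.append(f"- {h}: used on {100 * v['overall']:.1f}% of days "
                         "(no model; raw per-period proportions in outputs)")
        lines.append("")
    model_section("Daily foraging duration (min, conditional on use)",
                  result.duration_models, value_fmt="{:.0f}")

    if result.hsf_fits:
        lines.append("## Relative selection strength (vs grassland)")
        lines.append("")
        lines.append("| period | habitat | RSS | 95% CI | mean CV Spearman |")
        lines.append("|---|---|---|---|---|")
        for period, f in result.hsf_fits.items():
            cv = result.cv_results.get(period)
            cv_txt = f"{cv.mean_correlation:.2f}" if cv else "-"
            for h in f.log_rss:
                lines.append(f"| {period} | {h} | {f.rss[h]:.2f} | "
                             f"({f.ci_low[h]:.2f}, {f.ci_high[h]:.2f}) | {cv_txt} |")
        lines.append("")
    return "\n".join(lines)
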