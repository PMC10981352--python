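import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chisquare

from cpforage.periods import default_calendar
from cpforage.raster import read_ascii_grid
from cpforage.synthetic import (
    SyntheticScenario,
    TrueParameters,
    default_scenario,
    generate_landscape,
    generate_study,
    inject_missingness,
    simulate_day,
)

LATLON = (47.866, -3.550)


class TestLandscape:
    def test_proportions_within_three_points(self, agri_map):
        target = {"grassland": 0.33, "cereal": 0.29, "maize": 0.30,
                  "other_agri": 0.08}
        realized = agri_map.class_proportions()
        for cls, p in target.items():
            assert abs(realized[cls] - p) <= 0.03

    def test_degenerate_single_class(self):
        hm = generate_landscape(1000, 20, {"grassland": 1.0}, 10, seed=0)
        assert (hm.grid == 0).all()

    def test_determinism(self):
        a = generate_landscape(1000, 20, {"grassland": 0.5, "maize": 0.5}, 30, seed=9)
        b = generate_landscape(1000, 20, {"grassland": 0.5, "maize": 0.5}, 30, seed=9)
        assert np.array_equal(a.grid, b.grid)

    def test_patches_are_contiguous_parcels(self):
        # each class should occur in far fewer connected blobs than cells
        hm = generate_landscape(2000, 20, {"grassland": 0.5, "maize": 0.5}, 40, seed=2)
        from scipy.ndimage import label

        n_blobs, _ = label(hm.grid == 0)[1], None
        assert n_blobs <= 40

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_landscape(1000, 20, {"grassland": 0.5}, 10, seed=0)

    def test_impossible_target_rejected(self):
        # a 1% class cannot be realized with 3 huge patches
        with pytest.raises(ValueError):
            generate_landscape(1000, 20,
                               {"grassland": 0.495, "maize": 0.495,
                                "cereal": 0.01}, 3, seed=0)

    def test_ascii_roundtrip(self, agri_map, tmp_path):
        path = tmp_path / "map.asc"
        agri_map.write(path)
        back = read_ascii_grid(path)
        assert np.array_equal(back.grid, agri_map.grid)
        assert back.cell_size == agri_map.cell_size
        assert back.classes == agri_map.classes


class TestSimulateDay:
    def test_timestamps_are_sunrise_sunset_grid(self, uniform_grass_map):
        from cpforage.preprocess import expected_slots

        tp = TrueParameters()
        day = simulate_day((500, 500), tp, uniform_grass_map,
                           dt.date(2021, 5, 1), LATLON, seed=3)
        slots = expected_slots(dt.date(2021, 5, 1), LATLON, 5.0)
        assert list(day["timestamp"]) == list(slots)

    def test_nest_outside_raster_rejected(self, uniform_grass_map):
        with pytest.raises(ValueError, match="nest"):
            simulate_day((-50, 500), TrueParameters(), uniform_grass_map,
                         dt.date(2021, 5, 1), LATLON, seed=0)

    def test_strong_attraction_confines_to_nest(self, uniform_grass_map):
        # derived check: with strong homing, no habitat bias, and flight
        # steps shorter than the radius, nearly all fixes stay within
        # 500 m of the nest
        tp = TrueParameters(nest_attraction=5e-3,
                            gamma_mean=np.array([3.1, 14.2, 40.0]),
                            gamma_sd=np.array([2.5, 9.0, 12.0]))
        dists = []
        for s in range(30):
            day = simulate_day((500, 500), tp, uniform_grass_map,
                               dt.date(2021, 5, 1), LATLON, seed=s)
            dists.append(np.hypot(day["x"] - 500, day["y"] - 500))
        dists = np.concatenate(dists)
        assert np.mean(dists <= 500) >= 0.99

    def test_high_kappa_gives_straight_flight(self):
        big = generate_landscape(20000, 20, {"grassland": 1.0}, 10, seed=0)
        tp = TrueParameters(
            transition_matrix=np.array([[0.0, 0.0, 1.0]] * 3),
            vonmises_kappa=np.array([1e4, 1e4, 1e4]),
            nest_attraction=0.0)
        day = simulate_day((10000, 10000), tp, big, dt.date(2021, 5, 1),
                           LATLON, seed=4)
        d = np.diff(day[["x", "y"]].to_numpy(), axis=0)
        heading = np.arctan2(d[:, 1], d[:, 0])
        turns = np.abs((np.diff(heading) + np.pi) % (2 * np.pi) - np.pi)
        assert np.nanmean(turns) < 0.05

    def test_statewise_speeds_match_gamma_means(self, uniform_grass_map):
        tp = TrueParameters(nest_attraction=1e-5)
        big = generate_landscape(60000, 50, {"grassland": 1.0}, 10, seed=0)
        frames = [simulate_day((30000, 30000), tp, big, dt.date(2021, 6, 1),
                               LATLON, seed=s) for s in range(60)]
        speeds, states = [], []
        for f in frames:
            d = np.diff(f[["x", "y"]].to_numpy(), axis=0)
            speeds.append(np.hypot(d[:, 0], d[:, 1]) / 5.0)
            # the state drawn at fix t generates the step arriving at t
            states.append(f["true_state"].to_numpy()[1:])
        sp = np.concatenate(speeds)
        st = np.concatenate(states)
        assert len(sp) > 10_000
        for k, mean in enumerate(tp.gamma_mean):
            realized = sp[st == k].mean()
            assert abs(realized - mean) / mean < 0.05, f"state {k}"

    def test_state_occupancy_matches_stationary_distribution(self, uniform_grass_map):
        tp = TrueParameters(nest_attraction=1e-5)
        big = generate_landscape(60000, 50, {"grassland": 1.0}, 10, seed=1)
        frames = [simulate_day((30000, 30000), tp, big, dt.date(2021, 6, 1),
                               LATLON, seed=100 + s) for s in range(60)]
        # thin the sticky chain to near-independent draws so the chi-square
        # sampling model holds (>10^4 raw steps before thinning)
        states = np.concatenate(
            [f["true_state"].to_numpy()[::20] for f in frames])
        pi = tp.stationary_distribution()
        counts = np.bincount(states, minlength=3)
        stat, p = chisquare(counts, pi * counts.sum())
        assert p > 0.01

    def test_habitat_bias_matches_acceptance_weights(self):
        # symmetric availability: left half grassland, right half maize,
        # nest on the boundary; foraging fixes should hit maize vs
        # grassland in the exp(weight) = 2 ratio
        from cpforage.raster import HabitatMap

        n = 300
        grid = np.zeros((n, n), dtype=int)
        grid[:, n // 2:] = 2  # maize
        hm = HabitatMap(x0=0.0, y0=0.0, cell_size=20.0, grid=grid)
        w = {p: {"grassland": 0.0, "cereal": 0.0, "maize": np.log(2.0),
                 "other_agri": 0.0, "non_agri": 0.0}
             for p in default_calendar().names}
        tp = TrueParameters(selection_log_weights=w, nest_attraction=2e-4)
        frames = [simulate_day((3000.0, 3000.0), tp, hm, dt.date(2021, 5, 1),
                               LATLON, period="incubation", seed=s)
                  for s in range(40)]
        day = pd.concat(frames)
        forag = day[day["true_state"].isin([0, 1])]
        counts = forag["habitat"].value_counts()
        ratio = counts["maize"] / counts["grassland"]
        assert 1.6 < ratio < 2.4


class TestMissingness:
    def test_zero_probability_is_identity(self, uniform_grass_map):
        day = simulate_day((500, 500), TrueParameters(), uniform_grass_map,
                           dt.date(2021, 5, 1), LATLON, seed=0)
        out = inject_missingness(day, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, day)

    def test_dropout_count_is_binomial(self):
        # 200 replicates of 180 slots at p = .5: counts inside the central
        # 99% binomial interval
        df = pd.DataFrame({"timestamp": pd.date_range("2021-01-01", periods=180,
                                                      freq="5min"),
                           "x": 0.0, "y": 0.0})
        lo, hi = binom.ppf([0.005, 0.995], 180, 0.5)
        dropped = [180 - len(inject_missingness(df, 0.5, seed=s))
                   for s in range(200)]
        inside = np.mean([(lo <= d <= hi) for d in dropped])
        assert inside >= 0.97

    def test_seeded_dropout_is_reproducible(self):
        df = pd.DataFrame({"timestamp": pd.date_range("2021-01-01", periods=50,
                                                      freq="5min"),
                           "x": np.arange(50.0), "y": 0.0})
        a = inject_missingness(df, 0.3, seed=7)
        b = inject_missingness(df, 0.3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_probability_rejected(self):
        df = pd.DataFrame({"timestamp": [pd.Timestamp("2021-01-01")],
                           "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError):
            inject_missingness(df, 1.0)


class TestGenerateStudy:
    def test_tiny_study_structure(self, tiny_study):
        fixes = tiny_study["fixes"]
        assert set(["bird_id", "timestamp", "x", "y", "true_state",
                    "habitat"]) <= set(fixes.columns)
        assert len(tiny_study["nests"]) == 3
        assert fixes["true_state"].isin([0, 1, 2]).all()

    def test_same_seed_identical_output(self):
        scen = SyntheticScenario(
            n_birds=2, n_repeat_birds=0, extent_m=3000, n_patches=200,
            days_per_bird_per_period={"incubation": 2.0},
            participation={"incubation": 1.0}, seed=12)
        f1, n1, m1, t1 = generate_study(scen)
        f2, n2, m2, t2 = generate_study(scen)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(n1, n2)
        assert np.array_equal(m1.grid, m2.grid)

    def test_zero_days_gives_empty_table_with_headers(self):
        scen = SyntheticScenario(
            n_birds=2, n_repeat_birds=0, extent_m=3000, n_patches=200,
            days_per_bird_per_period={}, participation={}, seed=0)
        fixes, nests, _, _ = generate_study(scen)
        assert len(fixes) == 0
        assert list(fixes.columns) == ["bird_id", "timestamp", "x", "y",
                                       "true_state", "habitat"]

    def test_default_scale_matches_tracking_effort(self):
        # calibration: per-period mean fixes per tracking day in 100-190
        fixes, nests, _, truth = generate_study(default_scenario(seed=3))
        days = pd.DataFrame(truth["days"])
        per_period = days.groupby("period")["n_fixes"].mean()
        assert (per_period >= 100).all() and (per_period <= 190).all()
        # year-bird and tracking-day scale in the vicinity of the design
        n_year_birds = len(nests)
        assert 25 <= n_year_birds <= 35
        assert 350 <= len(days) <= 750
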