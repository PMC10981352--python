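import numpy as np
import pandas as pd
import pytest

from cpforage.raster import HabitatMap
from cpforage.synthetic import SyntheticScenario, generate_landscape, generate_study

STUDY_AREA_PROPORTIONS = {"grassland": 0.33, "cereal": 0.29, "maize": 0.30,
                     "other_agri": 0.08}


@pytest.fixture(scope="session")
def agri_map():
    """A small agricultural mosaic matching the study-area composition."""
    return generate_landscape(2000.0, 20.0, STUDY_AREA_PROPORTIONS, 80, seed=11)


@pytest.fixture(scope="session")
def uniform_grass_map():
    grid = np.zeros((50, 50), dtype=int)
    return HabitatMap(x0=0.0, y0=0.0, cell_size=20.0, grid=grid)


@pytest.fixture(scope="session")
def tiny_study():
    """A deliberately small two-period study with ground truth."""
    scen = SyntheticScenario(
        n_birds=3, n_repeat_birds=0, extent_m=4000.0, n_patches=300,
        days_per_bird_per_period={"incubation": 3.0, "post_fledging": 3.0},
        participation={"incubation": 1.0, "post_fledging": 1.0},
        seed=5)
    fixes, nests, hmap, truth = generate_study(scen)
    return {"scenario": scen, "fixes": fixes, "nests": nests,
            "map": hmap, "truth": truth}


def make_day_frame(xy, start="2021-05-01 06:00", freq_min=5, extra=None):
    """Build a fix DataFrame from an (n, 2) coordinate array."""
    xy = np.asarray(xy, float)
    ts = pd.date_range(start, periods=len(xy), freq=f"{freq_min}min", tz="UTC")
    df = pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1]})
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df
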