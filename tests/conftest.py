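import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cloverwatch import SimulationConfig, TableBundle, simulate_season, validate_bundle

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

D = "2021-07-10"


def _ts(*clock: str) -> list[str]:
    return [f"{D}T{c}:00" for c in clock]


@pytest.fixture(scope="session")
def tiny_bundle() -> TableBundle:
    """A hand-built two-camera day with known events and indices.

    F01 (focused, 1-min): a 3-frame moth event and a single bumblebee
    frame on inflorescence A. C01 (continuous, 5-min): a moth split into
    two events by an unannotated frame, and one 'other' frame, on B.
    C (on F01) is never visited and has zero seeds.
    """
    frames = pd.DataFrame(
        {
            "camera_id": ["F01"] * 17 + ["C01"] * 5,
            "timestamp": _ts(*[f"01:{m:02d}" for m in range(6)],
                             *[f"12:{m:02d}" for m in range(11)],
                             "02:00", "02:05", "02:10", "14:00", "14:05"),
            "regime": ["focused"] * 17 + ["continuous"] * 5,
        }
    )
    visits = pd.DataFrame(
        {
            "camera_id": ["F01"] * 4 + ["C01"] * 3,
            "inflorescence_id": ["A"] * 4 + ["B"] * 3,
            "timestamp": _ts("01:00", "01:01", "01:02", "12:03",
                             "02:00", "02:10", "14:00"),
            "taxon": ["moth"] * 3 + ["bumblebee", "moth", "moth", "other"],
        }
    )
    phenology = pd.DataFrame(
        {
            "inflorescence_id": ["A", "B", "C"],
            "camera_id": ["F01", "C01", "F01"],
            "doy_last_floret_emerged": [188.0, 190.0, 185.0],
            "doy_first_floret_senesced": [196.0, 195.0, 191.0],
            "fully_recorded": [True, True, False],
        }
    )
    dissection = pd.DataFrame(
        {
            "inflorescence_id": ["A"] * 5 + ["B"] * 4 + ["C"] * 3,
            "floret_rank": [1, 2, 3, 4, 5, 1, 2, 3, 4, 1, 2, 3],
            "n_florets": [5] * 5 + [4] * 4 + [3] * 3,
            "percentile": [np.nan] * 12,  # filled from rank on validation
            "n_seeds": [0, 1, 2, 1, 0, 1, 1, 1, 1, 0, 0, 0],
        }
    )
    cover = pd.DataFrame(
        {
            "camera_id": ["C01", "C01", "C01", "F01"],
            "doy": [190.0, 191.0, 192.0, 190.0],
            "cover": [0.1, 0.4, 0.2, 0.2],
        }
    )
    return validate_bundle(
        TableBundle(frames=frames, visits=visits, phenology=phenology,
                    dissection=dissection, cover=cover)
    )


def small_config(**overrides) -> SimulationConfig:
    """A short, few-camera season that still yields visits and seeds."""
    defaults = dict(
        n_cameras_focused=2,
        n_cameras_continuous=2,
        inflorescences_per_camera=3.0,
        season_start_doy=185,
        season_end_doy=204,
        flowering_start_mean_doy=190.0,
        flowering_start_sd_days=2.5,
        bee_rate=0.6,
        moth_rate=0.3,
        rng_seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_season():
    return simulate_season(small_config(), seed=11)
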