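"""Shared fixtures: small simulated datasets reused across the suite."""

from __future__ import annotations

from datetime import timedelta

import pytest

import hivevib as hv
from hivevib.pipeline import colony_mode_series


def simulate_night_frames(scenario, sensor="comb", band=(10.0, 600.0)):
    """Night-window (00:00-06:00), band-cropped frames for every night."""
    nights = {}
    for i in range(scenario.n_days):
        d = scenario.start_date + timedelta(days=i)
        frames = hv.simulate_day_window(scenario, d, sensor=sensor, hours=(0.0, 6.0))
        nights[d] = [hv.crop_band(fr, *band) for fr in frames]
    return nights


@pytest.fixture(scope="session")
def default_scenario():
    return hv.ColonyScenario(seed=1)


@pytest.fixture(scope="session")
def quiet_scenario():
    """Default scenario with all stochastic terms switched off."""
    return hv.ColonyScenario(seed=1, noise_sigma=0.0, night_jitter_sigma=0.0)


@pytest.fixture(scope="session")
def default_colony_nights(default_scenario):
    """150 nights of band-cropped night frames for the default colony."""
    return simulate_night_frames(default_scenario)


@pytest.fixture(scope="session")
def default_mode_series(default_colony_nights):
    series, bin_width = colony_mode_series(default_colony_nights)
    return series


@pytest.fixture(scope="session")
def apiary5():
    """Five-colony training apiary: night frames, mode series, scenarios.

    This is the dataset for the spectral-shape discrimination tests: five
    colonies over a 150-night season, distinct per-hive spectral
    fingerprints, brood cycles with distinct periods and phases.
    """
    scenarios = hv.make_apiary_scenarios(5, master_seed=3)
    frames_by, series_by = {}, {}
    for sc in scenarios:
        nights = simulate_night_frames(sc)
        frames_by[sc.colony_id] = nights
        series_by[sc.colony_id], _ = colony_mode_series(nights)
    return {
        "scenarios": {sc.colony_id: sc for sc in scenarios},
        "frames": frames_by,
        "series": series_by,
    }


@pytest.fixture(scope="session")
def trained_model(apiary5):
    training = hv.build_training_set(
        apiary5["frames"], apiary5["series"], duration_minutes=60, normalize=True
    )
    return hv.train_discriminant_model(training), training
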