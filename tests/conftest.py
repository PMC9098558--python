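import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tmsmap as tm
from tmsmap.pipeline import MapOptions, _sites_frame, analyze_trials

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One full simulated cohort under the default study design (seed 11)."""
    cfg = tm.SynthConfig(seed=11)
    trials, truth = tm.simulate_experiment(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def analyzed_cohort(default_cohort):
    """MEPs, maps and overlap records for the default cohort (no EMD)."""
    cfg, trials, truth = default_cohort
    meps, maps, overlaps = analyze_trials(
        trials, _sites_frame(trials), MapOptions(compute_emd=False)
    )
    return meps, maps, overlaps, truth


@pytest.fixture()
def gaussian_map():
    """Finely interpolated map of one analytic field (A=400 µV, σ=5 mm)."""
    ax = np.linspace(-11.0, 11.0, 12)
    xx, yy = np.meshgrid(ax, ax)
    sites = np.column_stack([xx.ravel(), yy.ravel()])
    amps = 400.0 * np.exp(-(sites**2).sum(axis=1) / (2.0 * 5.0**2))
    return tm.interpolate_map(sites, amps, resolution_mm=0.5, margin_mm=10.0)


def random_motor_map(rng, shape=(12, 12), resolution=1.0, peak=400.0):
    grid = rng.uniform(0.0, peak, size=shape)
    return tm.MotorMap(origin=(0.0, 0.0), resolution=resolution, grid=grid)
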