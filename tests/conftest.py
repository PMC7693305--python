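import numpy as np
import pytest

from glottalmidline.benchmark import BenchmarkConfig, run_benchmark


@pytest.fixture(scope="session")
def study_records():
    """Detector records over a freshly simulated study-scale dataset.

    250 sequences at the study conditions (independent per-side Q
    factors, contour noise p = 0.5, static rotation U[-30, 30] deg with
    slow sinusoidal translation), evaluated on the single peak frame
    and on 21-frame temporal sums.  Shared by the acceptance-level
    statistics tests; regenerating takes several minutes.
    """
    cfg = BenchmarkConfig(n_simulations=250, seed=7, half_ranges=(0, 10))
    table, summary = run_benchmark(cfg)
    return table, summary


@pytest.fixture(scope="session")
def short_sequence():
    """A short rendered mask sequence (cheap shared input for mask,
    temporal and metric tests)."""
    from glottalmidline.sixmass import SimulationConfig, simulate
    from glottalmidline.masks import render_sequence

    cfg = SimulationConfig(sim_duration=100e-3, seed=11)
    traj = simulate(cfg)
    return render_sequence(traj, cfg, rng_seed=11)


def ellipse_mask(semi_major=80.0, semi_minor=30.0, angle_deg=0.0,
                 shape=(256, 256)):
    from glottalmidline.benchmark import rasterized_ellipse

    return rasterized_ellipse(semi_major, semi_minor, angle_deg, shape)
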