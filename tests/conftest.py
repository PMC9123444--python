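import numpy as np
import pytest

from colonytrack.pipeline import RunConfig, process_plate
from colonytrack.plate_io import split_series
from colonytrack.synthetic import simulate_series, single_plate_spec


@pytest.fixture(scope="session")
def small_run():
    """One small synthetic plate run shared by read-only tests:
    12 colonies, 9 frames at 60-min cadence, short lags."""
    spec = single_plate_spec(
        seed=3,
        colonies_per_plate=12,
        lag_h=(1.0, 3.0),
        duration_h=8.0,
        interval_min=60.0,
    )
    frames, gt = simulate_series(spec)
    series = split_series(frames, spec.rois())[0]
    return spec, frames, gt, series


@pytest.fixture(scope="session")
def small_processed(small_run):
    spec, frames, gt, series = small_run
    cfg = RunConfig(write_masks=False, write_plots=False, area_min_px2=5.0)
    tracks, fits, summary, masks = process_plate(series, cfg)
    return spec, gt, series, tracks, fits, summary, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
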