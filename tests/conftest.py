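import numpy as np
import pytest

import heatvar as hv


@pytest.fixture(scope="session")
def strong_city():
    """20-year city with a strong constant heat slope (0.1 log-RR/degC)."""
    climate = hv.ClimateConfig(n_years=20)
    truth = hv.MortalityTruth.constant_slope(20, 0.1)
    series, sim_truth = hv.make_city(climate, truth, 3, seed=5)
    frame = hv.build_frame(series, 3)
    # Recovery fixtures use the robust analysis settings: a temperature
    # basis rich enough to represent the generator's kinked heat response,
    # and the mild time-curvature penalty that keeps poorly supported
    # summers from destabilizing the year-varying curve.
    model = hv.fit_model(frame, hv.BasisSpec.from_frame(frame, n_temp_interior=6),
                         time_penalty=10.0)
    return {"series": series, "truth": sim_truth, "frame": frame, "model": model}


@pytest.fixture(scope="session")
def step_city():
    """20-year city whose heat slope steps 0.05 -> 0.02 at year 10."""
    climate = hv.ClimateConfig(n_years=20)
    truth = hv.MortalityTruth.with_step(20, 0.05, 0.02, 10)
    series, sim_truth = hv.make_city(climate, truth, 3, seed=11)
    frame = hv.build_frame(series, 3)
    model = hv.fit_model(frame, hv.BasisSpec.from_frame(frame, n_temp_interior=6),
                         time_penalty=10.0)
    return {"series": series, "truth": sim_truth, "frame": frame, "model": model}


@pytest.fixture(scope="session")
def small_city():
    """Cheap 5-year city for fast structural tests."""
    climate = hv.ClimateConfig(n_years=5)
    truth = hv.MortalityTruth.constant_slope(5, 0.05)
    series, sim_truth = hv.make_city(climate, truth, 3, seed=3)
    frame = hv.build_frame(series, 3)
    model = hv.fit_model(frame)
    return {"series": series, "truth": sim_truth, "frame": frame, "model": model}
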