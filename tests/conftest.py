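import numpy as np
import pytest

from upcount import ProtocolConfig, RasterPlan, regime_config, sample_point_pattern


@pytest.fixture(scope="session")
def imaging_plan() -> RasterPlan:
    """IR imaging raster: 15 μm pixels, washout-safe 100 ms pulse spacing."""
    return RasterPlan(spot_diameter=30.0, scan_speed=150.0, repetition_rate=10.0,
                      line_spacing=15.0, area_width=1000.0, area_height=1000.0,
                      washout_time_ms=75.0, flyback_return_s=0.1)


@pytest.fixture(scope="session")
def small_plan() -> RasterPlan:
    """Quarter-size raster for fast simulation tests."""
    return RasterPlan(spot_diameter=30.0, scan_speed=150.0, repetition_rate=10.0,
                      line_spacing=15.0, area_width=500.0, area_height=500.0,
                      washout_time_ms=75.0, flyback_return_s=0.1)


@pytest.fixture(scope="session")
def dense_layer():
    """Reference-density layer (7000/mm²) over 1 mm²."""
    return sample_point_pattern(7000.0, (1000.0, 1000.0), 1.0, seed=1)


@pytest.fixture(scope="session")
def sparse_layer():
    """Low-density layer where spots/events never collide."""
    return sample_point_pattern(200.0, (500.0, 500.0), 1.0, seed=2)


@pytest.fixture(scope="session")
def ir_run(small_plan, sparse_layer):
    """One noise-carrying IR pass over the sparse layer."""
    from upcount import simulate_transient
    return simulate_transient(sparse_layer, small_plan,
                              regime_config("ir_2940"), 100.0, seed=3)
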