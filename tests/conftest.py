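import numpy as np
import pytest

from beamfov import geometry, simulator


@pytest.fixture(scope="session")
def linear_geom():
    return geometry.build_linear_array()


@pytest.fixture(scope="session")
def star_small():
    return geometry.build_star_array("small")


@pytest.fixture(scope="session")
def star_large():
    return geometry.build_star_array("large")


@pytest.fixture(scope="session")
def default_source():
    return simulator.PistonSource()


@pytest.fixture(scope="session")
def default_click(default_source):
    return simulator.synth_click_waveform(default_source, 500e3)


@pytest.fixture(scope="session")
def noise_free_linear_trial(linear_geom, default_source):
    """Three-click, noise-free approach trial on the linear array."""
    track = simulator.schedule_approach(
        3.4, 2.8, 4.0, ici_profile=0.05, beamwidth_profile=8.2,
    )
    return simulator.synthesize_trial(
        linear_geom, track, source=default_source, seed=11, tail_s=0.01
    )


@pytest.fixture(scope="session")
def noise_free_star_trial(star_small, default_source):
    """Two-click, noise-free trial on the small star array."""
    track = simulator.schedule_approach(
        1.1, 0.9, 2.0, ici_profile=0.05, beamwidth_profile=8.2,
    )
    return simulator.synthesize_trial(
        star_small, track, source=default_source, seed=5, tail_s=0.01
    )
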