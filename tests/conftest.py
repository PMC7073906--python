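import numpy as np
import pytest

import meatspec as ms


@pytest.fixture(scope="session")
def wl284():
    return ms.wavelength_grid(284)


@pytest.fixture(scope="session")
def endmembers(wl284):
    return ms.make_endmembers(wl284, seed=0)


@pytest.fixture()
def noise_free_config():
    """Small phantom with every stochastic term switched off."""
    return ms.PhantomConfig(
        rows=24, cols=24, disk_radius=8,
        gain_sd=0.0, baseline_sd=0.0, noise_sd=0.0, jitter_sd=0.0, level_sd=0.0,
    )


@pytest.fixture()
def small_config():
    """Small phantom with the default noise conditions."""
    return ms.PhantomConfig(rows=40, cols=40, disk_radius=14)


@pytest.fixture(scope="session")
def small_study():
    """A reduced but complete study, shared across tests that only need
    some fitted artifact (models, wavelength sets, maps)."""
    design = ms.DesignSpec(replicates_per_level=8, calibration_per_level=6)
    config = ms.PhantomConfig(rows=48, cols=48, disk_radius=17)
    return ms.run_phantom_study(
        design, config, seed=7,
        pretreatments=("none", "snv"),
        max_lv=10,
        selection_pretreatment="snv",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
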