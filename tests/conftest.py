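import numpy as np
import pytest

import thzkerr as tk


@pytest.fixture(scope="session")
def water():
    return tk.get_material("water")


@pytest.fixture(scope="session")
def silica():
    return tk.get_material("silica")


@pytest.fixture(scope="session")
def default_pulse():
    return tk.synth_single_cycle(5.1e7, 0.25)


@pytest.fixture(scope="session")
def water_stack(water):
    return tk.cuvette_stack(water)


@pytest.fixture(scope="session")
def water_dataset():
    """Noisy water trace at the standard noise calibration, seed 7."""
    return tk.generate_experiment(tk.water_fixture(seed=7))


def small_config(fixture_fn, **kw):
    """Coarser grids for speed in tests that refit many times."""
    cfg = fixture_fn(**kw)
    return cfg.replace(t_start=-6.0, t_stop=19.0, dt=0.04, n_z=32)


@pytest.fixture(scope="session")
def small_water_dataset():
    return tk.generate_experiment(small_config(tk.water_fixture, seed=3))
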