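import numpy as np
import pytest

import larvamatch as lm


@pytest.fixture(scope="session")
def default_grid():
    return lm.GridSpec()


@pytest.fixture(scope="session")
def scenario_run():
    """Factory running a reduced-particle drift simulation for a scenario
    preset on the full study grid; results are cached per scenario.

    50 particles per release (instead of 300) keeps the suite fast while
    preserving the arrival timing and composition patterns the qualitative
    checks probe.
    """
    cache = {}

    def _run(name: str, seed: int = 1):
        key = (name, seed)
        if key not in cache:
            grid = lm.GridSpec()
            preset = lm.scenario_preset(name, seed=seed)
            fields = lm.make_coastal_fields(grid, preset.ocean)
            schedule = lm.ReleaseSchedule(particles_per_release=50, seed=seed)
            history = lm.run_simulation(fields, schedule, lm.default_grounds(), lm.DriftConfig())
            abundance = lm.daily_abundance(history, lm.ColonyBox(), fields)
            cache[key] = {
                "preset": preset,
                "fields": fields,
                "history": history,
                "abundance": abundance,
            }
        return cache[key]

    return _run


@pytest.fixture()
def tiny_fields():
    """A small quiescent-ocean grid for unit tests (no jet, no eddies)."""
    grid = lm.GridSpec(nx=12, ny=30, dx=10.0, n_days=30)
    params = lm.OceanParams(jet_speed=0.0, eddy_amplitude=0.0, sst_seasonal_ramp=0.0,
                            sst_south_excess=0.0)
    return lm.make_coastal_fields(grid, params)


def make_uniform_fields(v=10.0, u=0.0, sst=5.0, nx=12, ny=40, n_days=30, dx=10.0):
    """Uniform-velocity fields (off land) for closed-form advection tests."""
    grid = lm.GridSpec(nx=nx, ny=ny, dx=dx, n_days=n_days)
    params = lm.OceanParams(jet_speed=0.0, eddy_amplitude=0.0)
    fields = lm.make_coastal_fields(grid, params)
    off = ~fields.land_mask
    fields.v[:, off] = v
    fields.u[:, off] = u
    fields.sst[:] = sst
    return fields
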