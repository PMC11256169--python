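"""Shared fixtures.

The heavy scenario runs (full-grid, multi-replicate simulations) are module-
scoped so that several acceptance checks can share one simulation.
"""

import dataclasses

import pytest

from dermasim import defaults
from dermasim import experiments as ex
from dermasim.config import GridConfig


@pytest.fixture(scope="session")
def baseline_run():
    """3-replicate baseline: residents to steady state, invader at t=4500."""
    return ex.run_scenario(ex.preset("baseline", base_seed=0))


@pytest.fixture(scope="session")
def malate_top_run():
    top = max(ex.MALATE_DOSES)
    return ex.run_scenario(ex.preset(f"malate:{top:g}", base_seed=0), stop_after_invader_extinct=True)


@pytest.fixture(scope="session")
def antibiotic_top_run():
    return ex.run_scenario(ex.preset("antibiotic:10", base_seed=0), stop_after_invader_extinct=True)


def small_scenario(base_seed=0, **overrides):
    """Reduced lattice (40x40) used for seed ensembles.

    Per-patch nutrient fluxes are unchanged, so populations scale with patch
    count while per-capita dynamics (and hence survival times) do not; the
    community settles well before a t=2000 introduction on this size.
    """
    kwargs = dict(
        grid=GridConfig(rows=40, cols=40, carrying_capacity=10, area_cm2=0.16),
        n0=80,
        invader_n=80,
        invader_at=2000,
        total_timesteps=3500,
        n_replicates=1,
        base_seed=base_seed,
    )
    kwargs.update(overrides)
    return defaults.baseline_config(**kwargs)
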