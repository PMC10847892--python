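"""Shared fixtures.

The heavyweight fixture is ``reduced_study``: a memoizing factory for
model cells of a scaled-down study (60 boxes spanning 0-59 °N, 20 model
years, otherwise default parameters and the default synthetic
climatology). Cells are computed on first request and shared across
tests, so the acceptance-level checks reuse integrations instead of
re-running them.
"""

from __future__ import annotations

import functools
from types import SimpleNamespace

import numpy as np
import pytest

import thermoniche as tn

REDUCED_LATS = np.arange(0.0, 60.0)
REDUCED_YEARS = 20


@pytest.fixture(scope="session")
def traits45() -> tn.SpeciesTraits:
    return tn.default_traits()


@pytest.fixture(scope="session")
def reduced_climatology() -> tn.ClimatologyGrid:
    return tn.synthesize_climatology(tn.SyntheticForcingParams(), REDUCED_LATS)


@pytest.fixture(scope="session")
def reduced_study(reduced_climatology, traits45):
    """Factory: (mode, K_H, gamma) -> namespace with trajectory, extantness
    report, diversity table, niche table and per-box seasonal amplitude."""
    grid = tn.ModelGrid(reduced_climatology.latitudes)
    amplitude = np.array(
        [tn.temperature_amplitude(reduced_climatology, b) for b in range(grid.n_boxes)]
    )

    @functools.lru_cache(maxsize=None)
    def cell(mode: str, K_H: float, gamma: float):
        forcing = tn.to_forcing(reduced_climatology, 0.125, REDUCED_YEARS, mode)
        params = tn.ModelParams(gamma=gamma, K_H=K_H, years=REDUCED_YEARS)
        traj = tn.run_simulation(traits45, grid, params, forcing)
        report = tn.classify_extant(traj)
        return SimpleNamespace(
            traj=traj,
            report=report,
            diversity=tn.diversity_profile(traj, report=report),
            niches=tn.estimate_all_niches(traj, report),
            amplitude=amplitude,
        )

    return cell


@pytest.fixture(scope="session")
def e1_reduction(traits45):
    """A 20-box, 40-year control run (constant forcing, no dispersal) —
    long enough that competitive exclusion has settled in near-tie boxes."""
    clim = tn.synthesize_climatology(tn.SyntheticForcingParams(), np.arange(0.0, 20.0))
    grid = tn.ModelGrid(clim.latitudes)
    forcing = tn.to_forcing(clim, 0.125, 40, "constant")
    params = tn.ModelParams(gamma=0.05, K_H=0.0, years=40)
    traj = tn.run_simulation(traits45, grid, params, forcing)
    report = tn.classify_extant(traj)
    return SimpleNamespace(
        clim=clim,
        traj=traj,
        report=report,
        diversity=tn.diversity_profile(traj, report=report),
    )
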