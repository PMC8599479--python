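"""Shared fixtures.

Two tiers:

* ``small`` — a 31x31 grid with a two-run 45-TR protocol and a reduced
  search space, for fast unit tests of the fitting machinery.
* ``study`` — the package's default study conditions (51x51 grid over
  +/-17.4 deg, two 225-TR runs, default search space).  The coarse grid
  and the heavyweight fitted datasets are session-scoped so every test
  that needs them shares one computation.
"""

from types import SimpleNamespace

import numpy as np
import pytest

import dogprf as d


def make_small_conditions() -> SimpleNamespace:
    grid = d.VisualFieldGrid(17.4, 41)
    protocol = d.ProtocolConfig(volumes_per_run=90, wedge_cycle=45.0, ring_cycle=30.0)
    apertures = d.build_protocol(protocol, grid)
    kernel = d.hrf_kernel(d.HRFModel(), protocol.tr)
    space = d.SearchSpace(
        n_positions=13,
        foveal_density=2.0,
        sigma2_values=(0.5, 0.9, 1.6, 2.8, 5.0),
        ratios=(0.35, 0.5, 0.65),
        deltas=(0.2, 0.5, 0.8),
    )
    return SimpleNamespace(grid=grid, protocol=protocol, apertures=apertures,
                           kernel=kernel, space=space)


@pytest.fixture(scope="session")
def small():
    cond = make_small_conditions()
    cond.coarse = d.CoarseGrid(cond.space, cond.apertures, cond.kernel)
    return cond


@pytest.fixture(scope="session")
def study():
    grid = d.VisualFieldGrid(17.4, 51)
    protocol = d.ProtocolConfig()
    apertures = d.build_protocol(protocol, grid)
    kernel = d.hrf_kernel(d.HRFModel(), protocol.tr)
    space = d.SearchSpace()
    coarse = d.CoarseGrid(space, apertures, kernel)
    return SimpleNamespace(grid=grid, protocol=protocol, apertures=apertures,
                           kernel=kernel, space=space, coarse=coarse)


@pytest.fixture(scope="session")
def balanced_noisy_fits(study):
    """200 balanced-generated voxels at default noise, fitted (both
    variants) on the detrended+z-scored series.  Shared by the noisy
    recovery and AIC-direction tests."""
    truth = d.sample_ground_truth(
        200, d.GroundTruthConfig(variant="balanced"), seed=20
    )
    raw = d.simulate_dataset(truth, study.apertures, study.kernel,
                             d.NoiseModel(seed=20))
    norm = [d.preprocess(ts, True) for ts in raw]
    fits = d.fit_map(norm, study.apertures, study.kernel, coarse=study.coarse)
    return SimpleNamespace(truth=truth, raw=raw, fits=fits)
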