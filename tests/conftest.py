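"""Shared fixtures.

The expensive DMC ensembles (dimer at the scaled spectroscopy protocol,
a smaller trimer run) are session-scoped and shared between the module
tests and the acceptance tests to keep the suite within a sane runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from aquavib import fixtures, pes
from aquavib.dmc import DMCConfig, run_dmc
from aquavib.landscape import IsomerCatalog

#: scaled dimer spectroscopy protocol shared by the heavy tests
DIMER_PROTOCOL = dict(n_walkers=2000, tau_total=20_000.0, tau_eq=12_000.0,
                      n_snapshots=20, tau_dw=1000.0, n_dw=3,
                      weighting="continuous", guided=True,
                      dw_checkpoints=(250.0, 500.0))


@pytest.fixture(scope="session")
def params() -> pes.QspcfwParams:
    return pes.load_params()


@pytest.fixture(scope="session")
def guiding(params) -> pes.GuidingParams:
    return pes.reduced_masses(params)


@pytest.fixture(scope="session")
def monomer(params) -> pes.Configuration:
    return fixtures.make_monomer(params)


@pytest.fixture(scope="session")
def dimer_catalog(params) -> IsomerCatalog:
    return fixtures.fixture_generator(2, seed=3, mc_steps=150)


@pytest.fixture(scope="session")
def dimer_system(dimer_catalog, params, guiding) -> pes.WaterSystem:
    return pes.WaterSystem(dimer_catalog.gm, params, guiding)


@pytest.fixture(scope="session")
def dimer_run(dimer_system, dimer_catalog):
    """Two concatenated scaled-protocol repetitions on the dimer."""
    seeds = np.random.SeedSequence(2024).spawn(2)
    x0 = dimer_system.flatten(dimer_catalog.gm)
    return [run_dmc(dimer_system, x0, DMCConfig(seed=s, **DIMER_PROTOCOL))
            for s in seeds]


@pytest.fixture(scope="session")
def trimer_catalog(params) -> IsomerCatalog:
    return fixtures.fixture_generator(3, seed=5, mc_steps=250)


@pytest.fixture(scope="session")
def trimer_system(trimer_catalog, params, guiding) -> pes.WaterSystem:
    return pes.WaterSystem(trimer_catalog.gm, params, guiding)


@pytest.fixture(scope="session")
def trimer_run(trimer_system, trimer_catalog):
    """Two scaled trimer repetitions (smaller than the dimer protocol)."""
    out = []
    for s in np.random.SeedSequence(77).spawn(2):
        cfg = DMCConfig(n_walkers=2500, tau_total=12_000.0, tau_eq=7_000.0,
                        n_snapshots=10, tau_dw=500.0, n_dw=2, guided=True,
                        weighting="continuous", seed=s,
                        dw_checkpoints=(250.0,))
        out.append(run_dmc(trimer_system,
                           trimer_system.flatten(trimer_catalog.gm), cfg))
    return out
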