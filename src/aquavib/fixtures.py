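"""Self-contained starting-structure generation.

The repository carries no geometry data: equilibrium monomers, random
cluster starts and isomer catalogs are all generated programmatically from
the force-field parameters, deterministically under a seed.
"""

from __future__ import annotations

import numpy as np

from . import landscape, pes

__all__ = ["make_monomer", "fixture_generator"]


def make_monomer(params: pes.QspcfwParams | None = None) -> pes.Configuration:
    """Equilibrium water monomer (O at origin, C2v axis along z)."""
    params = params or pes.load_params()
    th, l = params.theta_eq, params.l_eq
    coords = np.array([
        [0.0, 0.0, 0.0],
        [l * np.sin(th / 2), 0.0, l * np.cos(th / 2)],
        [-l * np.sin(th / 2), 0.0, l * np.cos(th / 2)],
    ])
    return pes.Configuration.water(coords)


def fixture_generator(n_molecules: int, seed: int = 0,
                      params: pes.QspcfwParams | None = None,
                      mc_steps: int = 400) -> landscape.IsomerCatalog:
    """Deterministic isomer catalog for a cluster size (GM first)."""
    params = params or pes.load_params()
    if n_molecules == 1:
        cfg, e = landscape.minimize(make_monomer(params), params)
        return landscape.IsomerCatalog([cfg], [e], params)
    return landscape.isomer_search(n_molecules, params, mc_steps=mc_steps,
                                   seed=seed)
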