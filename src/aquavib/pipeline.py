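"""Declarative run configuration and the end-to-end pipeline.

A run is described by a :class:`RunConfig` (YAML-serializable).  Defaults
encode the full-scale simulation protocol — tau_total = 50000, d_tau = 1,
tau_eq = 30000, 20 snapshots over the final 20000, tau_DW = 1000 with
N_DW = 3, walker counts of 5000 (monomer), 10000 (dimer), 50000 (trimer)
and 100000 (tetramer/hexamer), and N_DMC_c = 5 concatenated repetitions —
so a bare ``cluster: dimer`` reproduces the full-scale protocol; the ``scale``
knob shrinks walker counts and propagation times proportionally for
desk-size runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import gspa, landscape, pes
from .dmc import DMCConfig, DMCResult, run_dmc

__all__ = ["RunConfig", "default_walkers", "build_system", "run_sampling",
           "analyze_run"]

CLUSTER_SIZES = {"monomer": 1, "dimer": 2, "trimer": 3, "tetramer": 4,
                 "hexamer": 6}
_NW_DEFAULT = {1: 5_000, 2: 10_000, 3: 50_000, 4: 100_000, 6: 100_000}


def default_walkers(n_molecules: int) -> int:
    return _NW_DEFAULT.get(n_molecules, 100_000)


@dataclass
class RunConfig:
    """Schema-validated declarative configuration for the full pipeline."""

    cluster: str = "dimer"
    scheme: str = "chem_informed"       # chem_informed | standard
    basis: str = "N2"                   # N2 | N3
    n_reps: int = 5                     # N_DMC^c concatenated repetitions
    scale: float = 1.0                  # desk-scale shrink factor
    seed: int = 0
    guided: bool = True
    weighting: str = "continuous"
    n_walkers: int | None = None        # default: per-cluster full-scale value
    tau_total: float = 50_000.0
    tau_eq: float = 30_000.0
    n_snapshots: int = 20
    tau_dw: float = 1000.0
    n_dw: int = 3
    param_file: str | None = None
    output_dir: str = "aquavib_out"

    def __post_init__(self) -> None:
        if self.cluster not in CLUSTER_SIZES:
            raise ValueError(
                f"unknown cluster {self.cluster!r}; choose from "
                f"{sorted(CLUSTER_SIZES)}")
        if self.scheme not in ("chem_informed", "standard"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.basis not in ("N2", "N3"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if not (0 < self.scale <= 1.0):
            raise ValueError("scale must lie in (0, 1]")

    @property
    def n_molecules(self) -> int:
        return CLUSTER_SIZES[self.cluster]

    def dmc_config(self, seed=None) -> DMCConfig:
        nw = self.n_walkers or default_walkers(self.n_molecules)
        return DMCConfig(
            n_walkers=max(int(round(nw * self.scale)), 100),
            tau_total=self.tau_total * max(self.scale, 0.2),
            tau_eq=self.tau_eq * max(self.scale, 0.2),
            n_snapshots=self.n_snapshots,
            tau_dw=self.tau_dw, n_dw=self.n_dw,
            guided=self.guided, weighting=self.weighting,
            seed=self.seed if seed is None else seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        for key in data:
            if key not in known:
                raise ValueError(f"unknown configuration key {key!r}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def build_system(config: RunConfig,
                 catalog: landscape.IsomerCatalog | None = None):
    """(system, catalog): PES + guide around the cluster's global minimum."""
    params = pes.load_params(config.param_file)
    if catalog is None:
        catalog = landscape.isomer_search(
            config.n_molecules, params, seed=config.seed)
    guiding = pes.reduced_masses(params) if config.guided else None
    system = pes.WaterSystem(catalog.gm, params, guiding)
    return system, catalog


def run_sampling(config: RunConfig, system=None, catalog=None
                 ) -> tuple[list[DMCResult], "pes.WaterSystem", landscape.IsomerCatalog]:
    """Run the N_DMC^c repetitions (independent seeds, concatenated later)."""
    if system is None:
        system, catalog = build_system(config, catalog)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    results = [run_dmc(system, system.flatten(catalog.gm),
                       config.dmc_config(seed=s)) for s in seeds]
    return results, system, catalog


def analyze_run(config: RunConfig, results: list[DMCResult], system,
                catalog) -> gspa.SpectraResult:
    snaps = [s for r in results for s in r.snapshots]
    zpe = float(np.mean([r.zpe for r in results]))
    return gspa.analyze(snaps, system, catalog.gm, config.scheme,
                        config.basis, zpe=zpe)
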