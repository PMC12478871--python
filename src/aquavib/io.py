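"""Readers and writers: XYZ geometries, snapshot containers, spectra tables.

XYZ follows the plain convention — atom count line, free-form comment line,
then ``element x y z`` in Å.  Parse errors report the offending line number.
Snapshot ensembles are persisted in an HDF5 container together with the run
configuration, seed and a config hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .dmc import DMCConfig, DMCResult, Snapshot
from .pes import Configuration
from .units import ATOMIC_WEIGHTS

__all__ = [
    "read_xyz", "read_xyz_frames", "write_xyz", "XYZParseError",
    "save_run", "load_run", "config_hash",
]


class XYZParseError(ValueError):
    """Malformed XYZ input; message carries the 1-based line number."""


def _parse_frame(lines: list[str], offset: int):
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"line {offset + 1}: expected an atom count")
    if len(lines) < n + 2:
        raise XYZParseError(
            f"line {offset + 1}: frame declares {n} atoms but only "
            f"{max(len(lines) - 2, 0)} atom lines follow")
    comment = lines[1].rstrip("\n")
    elements: list[str] = []
    coords = np.empty((n, 3))
    for i in range(n):
        ln = lines[2 + i].split()
        if len(ln) < 4:
            raise XYZParseError(f"line {offset + 3 + i}: expected 'El x y z'")
        elements.append(ln[0])
        try:
            coords[i] = [float(v) for v in ln[1:4]]
        except ValueError:
            raise XYZParseError(f"line {offset + 3 + i}: non-numeric coordinate")
    return elements, coords, comment, n + 2


def _to_config(elements, coords) -> Configuration:
    masses = np.array([ATOMIC_WEIGHTS.get(e, np.nan) for e in elements])
    if np.any(np.isnan(masses)):
        bad = elements[int(np.flatnonzero(np.isnan(masses))[0])]
        raise XYZParseError(f"unsupported element {bad!r} (water clusters only)")
    # O,H,H contiguous ordering per monomer
    mol_index = np.repeat(np.arange(len(elements) // 3), 3)
    return Configuration(coords, elements, masses, mol_index)


def read_xyz(path: str | Path) -> Configuration:
    """Read a single-frame XYZ file into a :class:`Configuration`."""
    lines = Path(path).read_text().splitlines()
    elements, coords, _, _ = _parse_frame(lines, 0)
    return _to_config(elements, coords)


def read_xyz_frames(path: str | Path) -> list[Configuration]:
    """Read a multi-frame XYZ trajectory."""
    lines = Path(path).read_text().splitlines()
    out = []
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        elements, coords, _, used = _parse_frame(lines[pos:], pos)
        out.append(_to_config(elements, coords))
        pos += used
    return out


def write_xyz(path: str | Path, configs, comment: str = "") -> None:
    """Write one configuration or a trajectory (list) to XYZ."""
    if isinstance(configs, Configuration):
        configs = [configs]
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"{cfg.n_atoms}\n{comment}\n")
            for el, xyz in zip(cfg.elements, cfg.coords):
                fh.write(f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


# ---------------------------------------------------------------------------
# snapshot container
# ---------------------------------------------------------------------------


def config_hash(config: DMCConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def save_run(path: str | Path, result: DMCResult, meta: dict | None = None) -> None:
    """Persist a DMC run (V_ref trace and snapshots) with provenance."""
    with h5py.File(path, "w") as fh:
        fh.attrs["config"] = json.dumps(dataclasses.asdict(result.config),
                                        default=str)
        fh.attrs["config_hash"] = config_hash(result.config)
        fh.attrs["zpe"] = result.zpe
        fh.attrs["acceptance_rate"] = result.acceptance_rate
        for k, v in (meta or {}).items():
            fh.attrs[f"meta_{k}"] = v
        fh.create_dataset("vref", data=result.vref)
        fh.create_dataset("taus", data=result.taus)
        for i, s in enumerate(result.snapshots):
            g = fh.create_group(f"snapshots/{i}")
            g.create_dataset("x", data=s.x)
            g.create_dataset("w", data=s.w)
            if s.w_dw is not None:
                g.create_dataset("w_dw", data=s.w_dw)
            if s.log_guide is not None:
                g.create_dataset("log_guide", data=s.log_guide)
            g.attrs["tau"] = s.tau
            for t, prof in s.dw_profile.items():
                g.create_dataset(f"dw_profile/{t:g}", data=prof)


def load_run(path: str | Path) -> DMCResult:
    with h5py.File(path, "r") as fh:
        cfg_d = json.loads(fh.attrs["config"])
        cfg_d["seed"] = int(cfg_d["seed"]) if str(cfg_d["seed"]).isdigit() else 0
        cfg_d["dw_checkpoints"] = tuple(cfg_d.get("dw_checkpoints", ()))
        config = DMCConfig(**cfg_d)
        snaps = []
        i = 0
        while f"snapshots/{i}" in fh:
            g = fh[f"snapshots/{i}"]
            s = Snapshot(
                x=g["x"][()], w=g["w"][()],
                w_dw=g["w_dw"][()] if "w_dw" in g else None,
                log_guide=g["log_guide"][()] if "log_guide" in g else None,
                tau=float(g.attrs["tau"]))
            if "dw_profile" in g:
                s.dw_profile = {float(t): g[f"dw_profile/{t}"][()]
                                for t in g["dw_profile"]}
            snaps.append(s)
            i += 1
        return DMCResult(
            vref=fh["vref"][()], taus=fh["taus"][()], zpe=float(fh.attrs["zpe"]),
            snapshots=snaps, acceptance_rate=float(fh.attrs["acceptance_rate"]),
            config=config)
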