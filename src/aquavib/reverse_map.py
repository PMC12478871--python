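"""Optimization-based reverse mapping of vibrational coordinates.

The forward map x -> v_MW (descriptors, reduction, PCA rotation,
mass-weighting) is many-to-one only through rigid motions, since every
descriptor is rotation/translation invariant.  Reverse mapping finds a
Cartesian geometry whose mass-weighted vibrational displacement matches a
target by BFGS minimization of

    err(x) = || v_MW(x) - v_MW,target ||^2

with the analytic Jacobian J = P^T <G>^{-1/2} U^T B(x), down to err < 1e-8.
Because the objective is gauge-invariant the solver works in plain
Cartesian coordinates and the solution is Eckart-aligned to the reference
once at the end, which fixes the six-dimensional rigid null space.

Mode animation displaces v_MW along one mode in steps of +-delta, reverse
mapping each frame warm-started from the previous one, and emits the frames
as a trajectory suitable for standard molecular viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import internal_coords as ic
from .gspa import SpectraResult
from .landscape import eckart_frame
from .pes import Configuration, WaterSystem

__all__ = ["AnimationConfig", "ModeMap", "ReverseMapError"]


class ReverseMapError(RuntimeError):
    """Reverse mapping failed to reach the error threshold."""


@dataclass
class AnimationConfig:
    """Animation protocol: per-step displacement delta (mass-weighted a.u.;
    default 0.25*sqrt(lambda_l), a quarter of the mode's ground-state
    spread), k_max steps per direction, and the convergence threshold."""

    delta: float | None = None
    k_max: int = 8
    err_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be positive")


class ModeMap:
    """Forward and reverse maps between Cartesian space and the
    mass-weighted vibrational coordinates of a GSPA analysis."""

    def __init__(self, spectra: SpectraResult, system: WaterSystem):
        self.basis = spectra.basis
        self.u = spectra.reduction.u
        self.gis = spectra.gmat.inv_sqrt
        self.p = spectra.p
        self.q_mean = spectra.q_mean
        self.eigenvalues = np.array([m.eigenvalue for m in spectra.modes])
        self.system = system
        self.reference = spectra.reference
        self._ref_bohr = spectra.reference.coords_bohr()
        self._masses = system.pes.masses_au
        # chain matrix: v_MW = A (r - <r> U) with A = P^T G^{-1/2} U^T
        self._a = self.p.T @ self.gis @ self.u.T
        self._x_eq: np.ndarray | None = None

    # -- forward ------------------------------------------------------------
    def forward(self, x_bohr: np.ndarray, align: bool = True) -> np.ndarray:
        """v_MW displacement of a geometry (n_atoms, 3) in bohr.

        The stored ensemble mean is subtracted, so the ensemble centroid maps
        to the zero vector.  Alignment is optional because the descriptors
        are rigid-motion invariant; it only matters for reporting frames.
        """
        if align:
            x_bohr = eckart_frame(x_bohr, self._ref_bohr, self._masses)
        r = ic.evaluate(x_bohr, self.basis)
        return self._a @ r - self.p.T @ self.gis @ self.q_mean

    # -- reverse ------------------------------------------------------------
    def reverse(self, target: np.ndarray, x0: np.ndarray | None = None,
                err_tol: float = 1e-8, max_iter: int = 2000) -> np.ndarray:
        """Geometry whose forward map equals ``target``; Eckart-aligned.

        Raises :class:`ReverseMapError` (reporting the best error reached)
        when BFGS cannot push the squared deviation below ``err_tol``.
        """
        if x0 is None:
            x0 = self._ref_bohr
        na = x0.shape[0]

        def err(xf):
            d = self.forward(xf.reshape(na, 3), align=False) - target
            return float(d @ d)

        def jac(xf):
            x = xf.reshape(na, 3)
            d = self.forward(x, align=False) - target
            b = ic.wilson_b(x, self.basis)
            return 2.0 * (d @ self._a @ b)

        res = optimize.minimize(err, x0.ravel(), jac=jac, method="BFGS",
                                options={"gtol": 1e-12, "maxiter": max_iter})
        if res.fun >= err_tol:
            raise ReverseMapError(
                f"reverse mapping stalled at err = {res.fun:.3e} "
                f"(threshold {err_tol:.0e})")
        x = res.x.reshape(na, 3)
        return eckart_frame(x, self._ref_bohr, self._masses)

    def equilibrium(self, err_tol: float = 1e-8) -> np.ndarray:
        """Geometry mapping to zero displacement (the amplitude centroid),
        solved from the global-minimum structure; cached."""
        if self._x_eq is None:
            self._x_eq = self.reverse(np.zeros(self._a.shape[0]),
                                      self._ref_bohr, err_tol)
        return self._x_eq

    # -- animation ----------------------------------------------------------
    def animate(self, mode: int, config: AnimationConfig | None = None
                ) -> list[Configuration]:
        """Frames along one mode: -k_max..+k_max steps of delta, each frame
        reverse mapped warm-started from its neighbor, equilibrium at k=0."""
        config = config or AnimationConfig()
        delta = (config.delta if config.delta is not None
                 else 0.25 * np.sqrt(self.eigenvalues[mode]))
        e_l = np.zeros(self._a.shape[0])
        e_l[mode] = 1.0
        x_eq = self.equilibrium(config.err_tol)
        plus: list[np.ndarray] = []
        minus: list[np.ndarray] = []
        for sign, frames in ((1.0, plus), (-1.0, minus)):
            x_prev = x_eq
            for k in range(1, config.k_max + 1):
                x_prev = self.reverse(sign * k * delta * e_l, x_prev,
                                      config.err_tol)
                frames.append(x_prev)
        traj = minus[::-1] + [x_eq] + plus
        tpl = self.reference
        return [tpl.with_coords_bohr(x) for x in traj]
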