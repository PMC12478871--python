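"""Closed-form model oscillators used as DMC/GSPA benchmarks.

These implement the same batched problem interface as the water-cluster
adapter, in atomic units, and carry their exact spectra so sampling results
can be checked against analytic values:

* separable harmonic oscillators — ZPE = sum hbar omega_i / 2, ground state
  Gaussian with variance hbar/(2 m omega);
* the 1-D Morse oscillator — exact anharmonic levels
  E_n = hbar w0 (n + 1/2) - [hbar w0 (n + 1/2)]^2 / (4 De), the canonical
  test that the amplitude-based fundamental beats the effective-harmonic
  (variance-only) estimate when anharmonicity is strong.
"""

from __future__ import annotations

import numpy as np

__all__ = ["HarmonicOscillator", "MorseOscillator"]


class HarmonicOscillator:
    """Separable harmonic problem: V = sum_i (m_i w_i^2 / 2) x_i^2.

    The exact ground state is used as the guiding function, which makes the
    local energy exactly constant (zero variance) — the textbook check of
    the importance-sampled branching.
    """

    def __init__(self, omegas, masses=None):
        self.omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
        self.masses = (np.ones_like(self.omegas) if masses is None
                       else np.atleast_1d(np.asarray(masses, dtype=float)))
        self._a = self.masses * self.omegas  # Gaussian exponent m*w (hbar=1)

    @property
    def zpe(self) -> float:
        return float(0.5 * self.omegas.sum())

    def ground_state_variance(self) -> np.ndarray:
        """<x_i^2> in the exact ground state = hbar/(2 m_i w_i)."""
        return 1.0 / (2.0 * self._a)

    def potential(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * np.sum(self.masses * self.omegas**2 * x * x, axis=-1)

    def log_guide(self, x: np.ndarray) -> np.ndarray:
        return -0.5 * np.sum(self._a * x * x, axis=-1)

    def grad_log_guide(self, x: np.ndarray) -> np.ndarray:
        return -self._a * x

    def local_energy(self, x: np.ndarray) -> np.ndarray:
        return np.full(x.shape[:-1], self.zpe)

    def step_eval(self, x: np.ndarray):
        v = self.potential(x)
        return v, self.log_guide(x), self.grad_log_guide(x), self.zpe - v


class MorseOscillator:
    """1-D Morse potential V = De (1 - exp(-a x))^2 with exact levels.

    w0 = a sqrt(2 De / m);  E_n = w0 (n + 1/2) - [w0 (n + 1/2)]^2 / (4 De).
    An optional harmonic guide (the w0 Gaussian) supports guided runs.
    """

    def __init__(self, de: float, a: float, mass: float = 1.0, guided: bool = False):
        self.de = float(de)
        self.a = float(a)
        self.mass = float(mass)
        self.masses = np.array([mass])
        self.w0 = a * np.sqrt(2.0 * de / mass)
        self.guided = guided
        self._g = mass * self.w0

    def level(self, n: int) -> float:
        e = self.w0 * (n + 0.5)
        return float(e - e * e / (4.0 * self.de))

    @property
    def zpe(self) -> float:
        return self.level(0)

    @property
    def fundamental(self) -> float:
        """Exact anharmonic 0 -> 1 gap."""
        return self.level(1) - self.level(0)

    def potential(self, x: np.ndarray) -> np.ndarray:
        e = np.exp(-self.a * x[..., 0])
        return self.de * (1.0 - e) ** 2

    def log_guide(self, x: np.ndarray) -> np.ndarray:
        return -0.5 * self._g * x[..., 0] ** 2

    def grad_log_guide(self, x: np.ndarray) -> np.ndarray:
        return -self._g * x

    def local_energy(self, x: np.ndarray) -> np.ndarray:
        # E_L of the harmonic trial on the Morse surface (not constant)
        v = self.potential(x)
        s = self._g * x[..., 0]
        return v + (self._g - s * s) / (2.0 * self.mass)

    def step_eval(self, x: np.ndarray):
        v = self.potential(x)
        s = self._g * x[..., 0]
        kin = (self._g - s * s) / (2.0 * self.mass)
        return v, self.log_guide(x), self.grad_log_guide(x), kin
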