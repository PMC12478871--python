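"""Vectorized geometric primitives: distances, angles, gradients, Laplacians.

All functions accept coordinate arrays of shape ``(..., n_atoms, 3)`` so the
same code paths serve a single geometry and a whole walker ensemble.  Units
are whatever the caller uses (the formulas are scale-covariant); the DMC and
analysis layers call them in atomic units.

The per-atom Laplacians of bond lengths and bend angles are needed for the
local energy of the Gaussian guiding function.  For a bond ``l = |x_a - x_b|``
the Laplacian with respect to either atom is ``2/l``.  For an angle theta at
vertex j with arms to i and k (lengths r1, r2, cosine c, sine s):

    lap_i theta = c / (s r1^2)
    lap_k theta = c / (s r2^2)
    lap_j theta = c/s (1/r1^2 + 1/r2^2) - 2/(r1 r2 s)

(The arm results follow from the spherical Laplacian of the polar angle; the
vertex result adds the mixed-arm trace -2/(r1 r2 s).  All three are validated
against finite differences in the test suite.)
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bond_lengths",
    "bond_gradients",
    "bend_angles",
    "bend_gradients",
]

#: sin(theta) floor below which bend Jacobians are regularized (near-linear angle)
SIN_FLOOR = 1e-6


def bond_lengths(x: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Distances for index ``pairs`` (npairs, 2); returns (..., npairs)."""
    d = x[..., pairs[:, 0], :] - x[..., pairs[:, 1], :]
    return np.linalg.norm(d, axis=-1)


def bond_gradients(x: np.ndarray, pairs: np.ndarray):
    """Return (lengths, grad_a, grad_b) with grads of shape (..., npairs, 3).

    grad_a is d l/d x_a = unit vector from b to a; grad_b = -grad_a.
    """
    d = x[..., pairs[:, 0], :] - x[..., pairs[:, 1], :]
    l = np.linalg.norm(d, axis=-1)
    u = d / l[..., None]
    return l, u, -u


def bend_angles(x: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Angles i-j-k (vertex j) for ``triples`` (nt, 3); returns (..., nt) in rad."""
    u = x[..., triples[:, 0], :] - x[..., triples[:, 1], :]
    w = x[..., triples[:, 2], :] - x[..., triples[:, 1], :]
    r1 = np.linalg.norm(u, axis=-1)
    r2 = np.linalg.norm(w, axis=-1)
    c = np.einsum("...ij,...ij->...i", u, w) / (r1 * r2)
    return np.arccos(np.clip(c, -1.0, 1.0))


def bend_gradients(x: np.ndarray, triples: np.ndarray, with_laplacian: bool = False):
    """Angles plus analytic Wilson gradients (and optionally Laplacians).

    Returns ``(theta, g_i, g_j, g_k)`` or, with ``with_laplacian``,
    ``(theta, g_i, g_j, g_k, lap_i, lap_j, lap_k)``.  Gradient shapes are
    (..., nt, 3); Laplacian shapes (..., nt).  Near-linear angles
    (sin(theta) < 1e-6) are regularized by flooring the sine; such geometries
    do not occur for equilibrium water clusters but can for wild walkers.
    """
    u = x[..., triples[:, 0], :] - x[..., triples[:, 1], :]
    w = x[..., triples[:, 2], :] - x[..., triples[:, 1], :]
    r1 = np.linalg.norm(u, axis=-1)
    r2 = np.linalg.norm(w, axis=-1)
    uh = u / r1[..., None]
    wh = w / r2[..., None]
    c = np.clip(np.einsum("...ij,...ij->...i", uh, wh), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.maximum(1.0 - c * c, SIN_FLOOR**2))

    g_i = (c[..., None] * uh - wh) / (r1 * s)[..., None]
    g_k = (c[..., None] * wh - uh) / (r2 * s)[..., None]
    g_j = -g_i - g_k
    if not with_laplacian:
        return theta, g_i, g_j, g_k

    lap_i = c / (s * r1**2)
    lap_k = c / (s * r2**2)
    lap_j = c / s * (1.0 / r1**2 + 1.0 / r2**2) - 2.0 / (r1 * r2 * s)
    return theta, g_i, g_j, g_k, lap_i, lap_j, lap_k
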