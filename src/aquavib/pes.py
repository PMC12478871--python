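"""q-SPC/Fw potential energy surface, dipole, and the intramolecular guide.

The flexible point-charge water model used here has, per monomer, harmonic
bond-stretch and angle-bend terms

    V_intra = (k_OH/2)(l1 - l_eq)^2 + (k_OH/2)(l2 - l_eq)^2 + (k_A/2)(th - th_eq)^2

plus, between molecules only, a Lennard-Jones term for every O-O pair and a
Coulomb term for every intermolecular atom pair.  There are no intramolecular
nonbonded terms.  The dipole is the point-charge sum mu = sum_i q_i x_i.

Because the intramolecular part is explicitly parametrized by force constants,
the decoupled ground state is an analytic product of Gaussians in the bond
and angle displacements; that product is used as the DMC guiding function

    psi_g = prod_k exp{ -1/(2 hbar) [ sqrt(k_OH mu_OH) dl1^2
                                     + sqrt(k_OH mu_OH) dl2^2
                                     + sqrt(k_A  mu_A ) dth^2 ] }

with the reduced masses mu_OH = m_O m_H/(m_O + m_H) and
mu_A = (l_eq^2/2) / (1/m_H + (1 - cos th_eq)/m_O).

All public array APIs are batched: coordinate arrays of shape
``(..., n_atoms, 3)`` in bohr, energies in hartree.  The scalar convenience
wrappers at the bottom of the module speak Å / kcal/mol / e·Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import geometry
from .units import (
    AMU_TO_ME,
    ANGSTROM_TO_BOHR,
    ATOMIC_WEIGHTS,
    BOHR_TO_ANGSTROM,
    HARTREE_TO_KCALMOL,
    HARTREE_TO_WAVENUMBER,
    KCALMOL_TO_HARTREE,
)

#: hard floor on interatomic distances for Coulomb evaluation (Å)
MIN_DISTANCE_ANGSTROM = 0.1


class DegenerateGeometryError(ValueError):
    """Raised when two atoms come closer than the Coulomb distance guard."""


# ---------------------------------------------------------------------------
# configuration container
# ---------------------------------------------------------------------------


@dataclass
class Configuration:
    """One cluster geometry: coordinates (Å), elements, masses (amu), monomer map.

    Atom order within each monomer is O, H, H; monomers are contiguous.
    """

    coords: np.ndarray
    elements: list[str]
    masses: np.ndarray
    mol_index: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.mol_index = np.asarray(self.mol_index, dtype=int)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if n % 3 != 0:
            raise ValueError("atom count must be 3 x n_molecules")
        for m in range(self.n_molecules):
            sym = [self.elements[i] for i in np.flatnonzero(self.mol_index == m)]
            if sorted(sym) != ["H", "H", "O"]:
                raise ValueError(f"monomer {m} is not one O and two H: {sym}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_molecules(self) -> int:
        return self.n_atoms // 3

    @classmethod
    def water(cls, coords: np.ndarray) -> "Configuration":
        """Build a water-cluster configuration from (3*n_mol, 3) Å coordinates
        in O,H,H per-monomer order with standard atomic weights."""
        coords = np.asarray(coords, dtype=float)
        n_mol = coords.shape[0] // 3
        elements = ["O", "H", "H"] * n_mol
        masses = np.array([ATOMIC_WEIGHTS[e] for e in elements])
        mol_index = np.repeat(np.arange(n_mol), 3)
        return cls(coords, elements, masses, mol_index)

    def coords_bohr(self) -> np.ndarray:
        return self.coords * ANGSTROM_TO_BOHR

    def with_coords_bohr(self, x: np.ndarray) -> "Configuration":
        return Configuration(
            np.asarray(x) * BOHR_TO_ANGSTROM, list(self.elements),
            self.masses.copy(), self.mol_index.copy(),
        )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QspcfwParams:
    """q-SPC/Fw force-field parameters in I/O units (kcal/mol, Å, e, rad).

    Convention: V = (k/2) x^2 for both stretch and bend.
    """

    k_oh: float      # kcal/mol/Å^2
    l_eq: float      # Å
    k_a: float       # kcal/mol/rad^2
    theta_eq: float  # rad
    q_o: float       # e
    q_h: float       # e
    epsilon: float   # kcal/mol (O-O Lennard-Jones)
    sigma: float     # Å

    def __post_init__(self) -> None:
        if not (self.k_oh > 0 and self.k_a > 0 and self.epsilon > 0 and self.sigma > 0):
            raise ValueError("force constants and LJ parameters must be positive")
        if abs(self.q_o + 2.0 * self.q_h) > 1e-12:
            raise ValueError("monomer is not neutral: q_O + 2 q_H != 0")

    # --- atomic-unit views -------------------------------------------------
    @property
    def k_oh_au(self) -> float:
        return self.k_oh * KCALMOL_TO_HARTREE / ANGSTROM_TO_BOHR**2

    @property
    def l_eq_au(self) -> float:
        return self.l_eq * ANGSTROM_TO_BOHR

    @property
    def k_a_au(self) -> float:
        return self.k_a * KCALMOL_TO_HARTREE

    @property
    def epsilon_au(self) -> float:
        return self.epsilon * KCALMOL_TO_HARTREE

    @property
    def sigma_au(self) -> float:
        return self.sigma * ANGSTROM_TO_BOHR


def load_params(path: str | Path | None = None) -> QspcfwParams:
    """Read the flat ``key value`` parameter file (bundled file by default).

    Schema: one ``key value`` pair per line; '#' starts a comment.  Keys:
    k_oh, l_eq, k_a, theta_eq_deg, q_o, q_h, epsilon, sigma.
    """
    if path is None:
        text = resources.files("aquavib").joinpath("params/qspcfw.params").read_text()
    else:
        text = Path(path).read_text()
    kv: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, val = line.split()
        kv[key] = float(val)
    return QspcfwParams(
        k_oh=kv["k_oh"], l_eq=kv["l_eq"], k_a=kv["k_a"],
        theta_eq=np.deg2rad(kv["theta_eq_deg"]),
        q_o=kv["q_o"], q_h=kv["q_h"], epsilon=kv["epsilon"], sigma=kv["sigma"],
    )


@dataclass(frozen=True)
class GuidingParams:
    """Reduced masses of the local stretch/bend problems plus the PES parameters."""

    mu_oh: float  # amu
    mu_a: float   # amu·Å^2
    params: QspcfwParams

    def __post_init__(self) -> None:
        if not (self.mu_oh > 0 and self.mu_a > 0):
            raise ValueError("reduced masses must be positive")


def reduced_masses(params: QspcfwParams,
                   m_o: float = ATOMIC_WEIGHTS["O"],
                   m_h: float = ATOMIC_WEIGHTS["H"]) -> GuidingParams:
    """Local-mode reduced masses mu_OH (amu) and mu_A (amu·Å^2)."""
    mu_oh = m_o * m_h / (m_o + m_h)
    mu_a = (params.l_eq**2 / 2.0) / (1.0 / m_h + (1.0 - np.cos(params.theta_eq)) / m_o)
    return GuidingParams(mu_oh=mu_oh, mu_a=mu_a, params=params)


def local_mode_harmonics(guiding: GuidingParams) -> tuple[float, float]:
    """Local-mode harmonic wavenumbers (stretch, bend) in cm^-1.

    nu~ = sqrt(k/mu)/(2 pi c), i.e. hbar*omega in wavenumbers with the
    (k/2)x^2 convention.
    """
    p = guiding.params
    mu_oh_au = guiding.mu_oh * AMU_TO_ME
    mu_a_au = guiding.mu_a * AMU_TO_ME * ANGSTROM_TO_BOHR**2
    w_stretch = np.sqrt(p.k_oh_au / mu_oh_au)
    w_bend = np.sqrt(p.k_a_au / mu_a_au)
    return (w_stretch * HARTREE_TO_WAVENUMBER, w_bend * HARTREE_TO_WAVENUMBER)


# ---------------------------------------------------------------------------
# batched PES
# ---------------------------------------------------------------------------


class WaterPES:
    """Vectorized q-SPC/Fw energy/gradient/dipole for a fixed cluster topology.

    Built once from a template :class:`Configuration`; evaluation then accepts
    coordinate arrays of shape ``(..., n_atoms, 3)`` in bohr and returns
    hartree (energies), hartree/bohr (gradients) and e·bohr (dipoles).
    """

    def __init__(self, template: Configuration, params: QspcfwParams):
        self.params = params
        self.n_atoms = template.n_atoms
        self.n_molecules = template.n_molecules
        mol = template.mol_index
        self.o_idx = np.array(
            [np.flatnonzero((mol == m) & (np.array(template.elements) == "O"))[0]
             for m in range(self.n_molecules)])
        h_idx = [np.flatnonzero((mol == m) & (np.array(template.elements) == "H"))
                 for m in range(self.n_molecules)]
        self.h1_idx = np.array([h[0] for h in h_idx])
        self.h2_idx = np.array([h[1] for h in h_idx])

        # intramolecular bonds (2 per monomer, O first) and bends (H-O-H)
        self.bonds = np.concatenate([
            np.stack([self.o_idx, self.h1_idx], axis=1),
            np.stack([self.o_idx, self.h2_idx], axis=1)])
        self.bends = np.stack([self.h1_idx, self.o_idx, self.h2_idx], axis=1)

        # O-O Lennard-Jones pairs
        oo = [(self.o_idx[a], self.o_idx[b])
              for a in range(self.n_molecules) for b in range(a + 1, self.n_molecules)]
        self.oo_pairs = np.array(oo, dtype=int).reshape(-1, 2)

        # all intermolecular atom pairs (Coulomb)
        charges = np.where(np.array(template.elements) == "O", params.q_o, params.q_h)
        self.charges = charges
        pairs = [(i, j) for i in range(self.n_atoms) for j in range(i + 1, self.n_atoms)
                 if mol[i] != mol[j]]
        self.coul_pairs = np.array(pairs, dtype=int).reshape(-1, 2)
        self.qprod = charges[self.coul_pairs[:, 0]] * charges[self.coul_pairs[:, 1]]

        self.masses_amu = template.masses
        self.masses_au = template.masses * AMU_TO_ME
        self._rmin = MIN_DISTANCE_ANGSTROM * ANGSTROM_TO_BOHR
        self.n_clamped = 0  # running count of distance-guard activations

    # -- energy -------------------------------------------------------------
    def potential(self, x: np.ndarray) -> np.ndarray:
        """V(R) in hartree for x in bohr, shape (..., n_atoms, 3) -> (...)."""
        p = self.params
        l = geometry.bond_lengths(x, self.bonds)
        th = geometry.bend_angles(x, self.bends)
        v = 0.5 * p.k_oh_au * np.sum((l - p.l_eq_au) ** 2, axis=-1)
        v += 0.5 * p.k_a_au * np.sum((th - p.theta_eq) ** 2, axis=-1)
        if self.oo_pairs.size:
            r_oo = geometry.bond_lengths(x, self.oo_pairs)
            sr6 = (p.sigma_au / r_oo) ** 6
            v += 4.0 * p.epsilon_au * np.sum(sr6 * sr6 - sr6, axis=-1)
            r_c = geometry.bond_lengths(x, self.coul_pairs)
            n_low = int(np.count_nonzero(r_c < self._rmin))
            if n_low:
                self.n_clamped += n_low
                r_c = np.maximum(r_c, self._rmin)
            v += np.sum(self.qprod / r_c, axis=-1)
        return v

    # -- gradient -----------------------------------------------------------
    def gradient(self, x: np.ndarray) -> np.ndarray:
        """dV/dx in hartree/bohr, same shape as x.  Analytic."""
        p = self.params
        g = np.zeros_like(x)

        l, ga, gb = geometry.bond_gradients(x, self.bonds)
        dl = p.k_oh_au * (l - p.l_eq_au)
        np.add.at(g, (..., self.bonds[:, 0], slice(None)), dl[..., None] * ga)
        np.add.at(g, (..., self.bonds[:, 1], slice(None)), dl[..., None] * gb)

        th, gi, gj, gk = geometry.bend_gradients(x, self.bends)
        dth = p.k_a_au * (th - p.theta_eq)
        np.add.at(g, (..., self.bends[:, 0], slice(None)), dth[..., None] * gi)
        np.add.at(g, (..., self.bends[:, 1], slice(None)), dth[..., None] * gj)
        np.add.at(g, (..., self.bends[:, 2], slice(None)), dth[..., None] * gk)

        if self.oo_pairs.size:
            r, ua, _ = geometry.bond_gradients(x, self.oo_pairs)
            sr6 = (p.sigma_au / r) ** 6
            dv = 4.0 * p.epsilon_au * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            np.add.at(g, (..., self.oo_pairs[:, 0], slice(None)), dv[..., None] * ua)
            np.add.at(g, (..., self.oo_pairs[:, 1], slice(None)), -dv[..., None] * ua)

            r, ua, _ = geometry.bond_gradients(x, self.coul_pairs)
            r = np.maximum(r, self._rmin)
            dv = -self.qprod / r**2
            np.add.at(g, (..., self.coul_pairs[:, 0], slice(None)), dv[..., None] * ua)
            np.add.at(g, (..., self.coul_pairs[:, 1], slice(None)), -dv[..., None] * ua)
        return g

    # -- dipole -------------------------------------------------------------
    def dipole(self, x: np.ndarray) -> np.ndarray:
        """Point-charge dipole sum q_i x_i in e·bohr, shape (..., 3)."""
        return np.einsum("i,...ij->...j", self.charges, x)


class WaterGuide:
    """Intramolecular Gaussian guiding function psi_g = exp(-S) (atomic units).

    S = sum_monomers (a_l/2)(dl1^2 + dl2^2) + (a_th/2) dth^2 with
    a_l = sqrt(k_OH mu_OH), a_th = sqrt(k_A mu_A) (hbar = 1).
    """

    def __init__(self, pes: WaterPES, guiding: GuidingParams):
        self.pes = pes
        p = guiding.params
        mu_oh_au = guiding.mu_oh * AMU_TO_ME
        mu_a_au = guiding.mu_a * AMU_TO_ME * ANGSTROM_TO_BOHR**2
        self.a_l = float(np.sqrt(p.k_oh_au * mu_oh_au))
        self.a_th = float(np.sqrt(p.k_a_au * mu_a_au))
        self.l_eq = p.l_eq_au
        self.theta_eq = p.theta_eq
        #: ZPE of the decoupled intramolecular problem (local-mode estimate)
        self.e_local = pes.n_molecules * 0.5 * (
            2.0 * np.sqrt(p.k_oh_au / mu_oh_au) + np.sqrt(p.k_a_au / mu_a_au))

    def log_value(self, x: np.ndarray) -> np.ndarray:
        """log psi_g, shape (...,).  Exposed instead of psi_g for stability."""
        dl = geometry.bond_lengths(x, self.pes.bonds) - self.l_eq
        dth = geometry.bend_angles(x, self.pes.bends) - self.theta_eq
        return -(0.5 * self.a_l * np.sum(dl * dl, axis=-1)
                 + 0.5 * self.a_th * np.sum(dth * dth, axis=-1))

    def _terms(self, x: np.ndarray):
        pes = self.pes
        l, ga, gb = geometry.bond_gradients(x, pes.bonds)
        th, gi, gj, gk, li, lj, lk = geometry.bend_gradients(
            x, pes.bends, with_laplacian=True)
        return l, ga, gb, th, gi, gj, gk, li, lj, lk

    def grad_log(self, x: np.ndarray) -> np.ndarray:
        """grad log psi_g = -grad S, same shape as x."""
        pes = self.pes
        l, ga, gb, th, gi, gj, gk, *_ = self._terms(x)
        g = np.zeros_like(x)
        dl = self.a_l * (l - self.l_eq)
        # bond pairs are (O, H): ga belongs to O, gb to H.  Each monomer's
        # O/H1/H2 indices are distinct -> direct scatter adds are safe.
        nm = pes.n_molecules
        g[..., pes.o_idx, :] += dl[..., :nm, None] * ga[..., :nm, :]
        g[..., pes.o_idx, :] += dl[..., nm:, None] * ga[..., nm:, :]
        g[..., pes.h1_idx, :] += dl[..., :nm, None] * gb[..., :nm, :]
        g[..., pes.h2_idx, :] += dl[..., nm:, None] * gb[..., nm:, :]
        dth = self.a_th * (th - self.theta_eq)
        g[..., pes.h1_idx, :] += dth[..., None] * gi
        g[..., pes.o_idx, :] += dth[..., None] * gj
        g[..., pes.h2_idx, :] += dth[..., None] * gk
        return -g

    def local_energy(self, x: np.ndarray, v: np.ndarray | None = None) -> np.ndarray:
        """E_L = V + sum_i (lap_i S - |grad_i S|^2)/(2 m_i)  (hartree).

        For the decoupled 1-D stretch/bend problems this is constant (the
        zero-variance property of an exact guide); for the full cluster the
        curvilinear kinetic couplings and intermolecular terms contribute.
        """
        pes = self.pes
        if v is None:
            v = pes.potential(x)
        l, ga, gb, th, gi, gj, gk, li, lj, lk = self._terms(x)
        nm = pes.n_molecules

        grad_s = np.zeros_like(x)
        dl = self.a_l * (l - self.l_eq)
        grad_s[..., pes.o_idx, :] += dl[..., :nm, None] * ga[..., :nm, :]
        grad_s[..., pes.o_idx, :] += dl[..., nm:, None] * ga[..., nm:, :]
        grad_s[..., pes.h1_idx, :] += dl[..., :nm, None] * gb[..., :nm, :]
        grad_s[..., pes.h2_idx, :] += dl[..., nm:, None] * gb[..., nm:, :]
        dth = self.a_th * (th - self.theta_eq)
        grad_s[..., pes.h1_idx, :] += dth[..., None] * gi
        grad_s[..., pes.o_idx, :] += dth[..., None] * gj
        grad_s[..., pes.h2_idx, :] += dth[..., None] * gk

        # per-atom Laplacian of S: sum over terms a (|grad g|^2 + dg lap g)
        lap_s = np.zeros(x.shape[:-1])
        dl1, dl2 = l[..., :nm] - self.l_eq, l[..., nm:] - self.l_eq
        inv_l1, inv_l2 = 2.0 / l[..., :nm], 2.0 / l[..., nm:]
        lap_s[..., pes.h1_idx] += self.a_l * (1.0 + dl1 * inv_l1)
        lap_s[..., pes.h2_idx] += self.a_l * (1.0 + dl2 * inv_l2)
        lap_s[..., pes.o_idx] += self.a_l * (2.0 + dl1 * inv_l1 + dl2 * inv_l2)
        dth_raw = th - self.theta_eq
        g2 = np.einsum("...ij,...ij->...i", gi, gi)
        lap_s[..., pes.h1_idx] += self.a_th * (g2 + dth_raw * li)
        g2 = np.einsum("...ij,...ij->...i", gj, gj)
        lap_s[..., pes.o_idx] += self.a_th * (g2 + dth_raw * lj)
        g2 = np.einsum("...ij,...ij->...i", gk, gk)
        lap_s[..., pes.h2_idx] += self.a_th * (g2 + dth_raw * lk)

        inv2m = 1.0 / (2.0 * pes.masses_au)
        kin = np.einsum("...i,i->...", lap_s, inv2m) - np.einsum(
            "...ij,i->...", grad_s * grad_s, inv2m / 1.0)
        return v + kin


class WaterSystem:
    """Flat-coordinate adapter exposing the DMC problem interface.

    Walker coordinates are (n_walkers, 3*n_atoms) in bohr; masses are
    per-degree-of-freedom (each atom's mass repeated three times).
    """

    def __init__(self, template: Configuration, params: QspcfwParams,
                 guiding: GuidingParams | None = None, accelerate: bool = True):
        self.template = template
        self.params = params
        self.pes = WaterPES(template, params)
        self.guide = WaterGuide(self.pes, guiding) if guiding is not None else None
        self.masses = np.repeat(self.pes.masses_au, 3)
        self.n_atoms = template.n_atoms
        from . import fastpath
        self._fast = accelerate and fastpath.HAVE_NUMBA
        p = self.pes
        self._kargs = (p.bonds.astype(np.int64), p.bends.astype(np.int64),
                       p.oo_pairs.astype(np.int64), p.coul_pairs.astype(np.int64),
                       np.ascontiguousarray(p.qprod, dtype=float),
                       params.k_oh_au, params.l_eq_au, params.k_a_au,
                       params.theta_eq, params.epsilon_au, params.sigma_au,
                       p._rmin)

    def _fold(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(*x.shape[:-1], self.n_atoms, 3)

    def potential(self, x: np.ndarray) -> np.ndarray:
        if self._fast and x.ndim == 2:
            from . import fastpath
            return fastpath._potential_kernel(
                np.ascontiguousarray(self._fold(x)), *self._kargs)
        return self.pes.potential(self._fold(x))

    def step_eval(self, x: np.ndarray):
        """Fused per-step evaluation: (V, log psi_g, grad log psi_g, E_L - V).

        ``x`` is (n, 3*n_atoms); the numba kernel is used when available and
        matches the numpy reference to floating-point roundoff.
        """
        if self.guide is None:
            raise ValueError("step_eval requires a guiding function")
        if self._fast and x.ndim == 2:
            from . import fastpath, geometry
            v, lg, grad, kin = fastpath._guided_kernel(
                np.ascontiguousarray(self._fold(x)), *self._kargs,
                self.guide.a_l, self.guide.a_th,
                1.0 / (2.0 * self.pes.masses_au), geometry.SIN_FLOOR)
            return v, lg, grad.reshape(x.shape), kin
        xf = self._fold(x)
        v = self.pes.potential(xf)
        lg = self.guide.log_value(xf)
        grad = self.guide.grad_log(xf).reshape(x.shape)
        kin = self.guide.local_energy(xf, v) - v
        return v, lg, grad, kin

    @property
    def has_fused_step(self) -> bool:
        return self._fast and self.guide is not None

    def fused_step(self, x: np.ndarray, state, noise: np.ndarray,
                   log_u: np.ndarray, d_tau: float) -> float:
        """One in-place drift-Metropolis step for the whole ensemble.

        ``x`` (n, 3*n_atoms, C-contiguous) and the cached ``state`` arrays
        (V, log psi_g, grad, E_L - V) are mutated for accepted walkers;
        returns the acceptance fraction.  Available on the numba path only.
        """
        from . import fastpath, geometry
        v, lg, grad, kin = state
        na = self.n_atoms
        var = d_tau / self.pes.masses_au  # 2 D dtau per atom
        n_acc = fastpath._guided_step_kernel(
            x.reshape(-1, na, 3), v, lg, grad.reshape(-1, na, 3), kin,
            noise.reshape(-1, na, 3), log_u, var, np.sqrt(var),
            *self._kargs, self.guide.a_l, self.guide.a_th,
            1.0 / (2.0 * self.pes.masses_au), geometry.SIN_FLOOR)
        return n_acc / x.shape[0]

    def dipole(self, x: np.ndarray) -> np.ndarray:
        return self.pes.dipole(self._fold(x))

    def log_guide(self, x: np.ndarray) -> np.ndarray:
        return self.guide.log_value(self._fold(x))

    def grad_log_guide(self, x: np.ndarray) -> np.ndarray:
        g = self.guide.grad_log(self._fold(x))
        return g.reshape(*x.shape[:-1], 3 * self.n_atoms)

    def local_energy(self, x: np.ndarray) -> np.ndarray:
        return self.guide.local_energy(self._fold(x))

    def flatten(self, config: Configuration) -> np.ndarray:
        return config.coords_bohr().ravel()


# ---------------------------------------------------------------------------
# scalar convenience API (Å / kcal/mol / e·Å), per-configuration
# ---------------------------------------------------------------------------


def _check_distances(config: Configuration) -> None:
    x = config.coords
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < MIN_DISTANCE_ANGSTROM:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise DegenerateGeometryError(
            f"atoms {i} and {j} are {d.min():.3g} Å apart (< {MIN_DISTANCE_ANGSTROM} Å)")


def potential_energy(config: Configuration, params: QspcfwParams) -> float:
    """V(R) in kcal/mol."""
    _check_distances(config)
    pes = WaterPES(config, params)
    return float(pes.potential(config.coords_bohr())) * HARTREE_TO_KCALMOL


def gradient(config: Configuration, params: QspcfwParams) -> np.ndarray:
    """dV/dx in kcal/mol/Å, shape (n_atoms, 3)."""
    _check_distances(config)
    pes = WaterPES(config, params)
    return pes.gradient(config.coords_bohr()) * (HARTREE_TO_KCALMOL * ANGSTROM_TO_BOHR)


def dipole_moment(config: Configuration, params: QspcfwParams) -> np.ndarray:
    """Point-charge dipole in e·Å."""
    pes = WaterPES(config, params)
    return pes.dipole(config.coords_bohr()) * BOHR_TO_ANGSTROM


def guiding_value(config: Configuration, guiding: GuidingParams) -> float:
    """psi_g at a configuration (dimensionless)."""
    return float(np.exp(guiding_log_value(config, guiding)))


def guiding_log_value(config: Configuration, guiding: GuidingParams) -> float:
    pes = WaterPES(config, guiding.params)
    return float(WaterGuide(pes, guiding).log_value(config.coords_bohr()))


def guiding_log_gradient(config: Configuration, guiding: GuidingParams) -> np.ndarray:
    """grad log psi_g in 1/Å, shape (n_atoms, 3)."""
    pes = WaterPES(config, guiding.params)
    return WaterGuide(pes, guiding).grad_log(config.coords_bohr()) * ANGSTROM_TO_BOHR
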