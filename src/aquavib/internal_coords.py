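"""Redundant internal coordinates, Wilson B/G machinery, SVD reductions.

The redundant descriptor sets are

* ``N2`` — all intramolecular OH bond lengths and HOH angles plus every
  intermolecular atom-pair distance (quadratic growth with cluster size);
* ``N3`` — ``N2`` plus all intermolecular angles (cubic growth).

Descriptor ordering is deterministic: the intramolecular block first (all
bonds in monomer order, then all angles), then the intermolecular block.
That makes the first K = 3 n_mol rows the "fixed" rows of the chemically
informed reduction.

Two redundancy reductions to 3N-6 coordinates are provided:

* standard — left singular vectors of the ensemble-averaged Jacobian <B>;
* chemically informed — the K intramolecular descriptors are kept as exact
  coordinates (identity block), and the remaining 3N-6-K directions are the
  leading singular vectors of the intermolecular rows projected onto the
  orthogonal complement of the intramolecular row space.

The character imbalance factors (CIFs) quantify how much squared weight a
descriptor class carries in the reduced basis relative to proportional
representation; they vanish identically for the chemically informed scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import geometry
from .pes import Configuration

__all__ = [
    "Descriptor", "build_basis", "evaluate", "wilson_b", "BEnsemble",
    "ensemble_b", "ReductionU", "reduce_standard", "reduce_chem_informed",
    "GMatrix", "g_matrix", "g_inv_sqrt", "transform_T", "cif_diagnostics",
    "mixing_fraction", "mode_character",
]

INTRA_KINDS = ("oh_bond", "hoh_angle")


@dataclass(frozen=True)
class Descriptor:
    """One tagged internal coordinate: a distance (2 atoms) or angle (3 atoms,
    vertex in the middle)."""

    kind: str  # oh_bond | hoh_angle | inter_distance | inter_angle
    atoms: tuple[int, ...]

    @property
    def is_intra(self) -> bool:
        return self.kind in INTRA_KINDS

    @property
    def is_angle(self) -> bool:
        return len(self.atoms) == 3


def build_basis(template: Configuration, level: str = "N2",
                inter_angle_rule: str = "bonded") -> list[Descriptor]:
    """Construct the ordered redundant basis for a cluster topology.

    ``inter_angle_rule`` selects which angle triples count as intermolecular
    in the N3 basis (all readings scale cubically with cluster size):

    * ``"bonded"`` (default) — one arm of the angle is a covalent O-H bond
      and the other arm an intermolecular contact, with the vertex at the
      shared atom.  This is the standard construction of interfragment
      bending coordinates and contains every hydrogen-bond angle
      (O-H···O and O···H-O);
    * ``"arms"`` — both arms are intermolecular contacts (the vertex
      monomer contains neither endpoint);
    * ``"any"`` — any triple not fully contained in one monomer;
    * ``"strict"`` — the three atoms lie in three distinct monomers (empty
      for a dimer).
    """
    if level not in ("N2", "N3"):
        raise ValueError(f"unknown basis level {level!r}")
    mol = template.mol_index
    elements = np.array(template.elements)
    n_mol = template.n_molecules
    basis: list[Descriptor] = []

    o_of = {m: int(np.flatnonzero((mol == m) & (elements == "O"))[0])
            for m in range(n_mol)}
    h_of = {m: [int(i) for i in np.flatnonzero((mol == m) & (elements == "H"))]
            for m in range(n_mol)}
    for m in range(n_mol):
        basis.append(Descriptor("oh_bond", (o_of[m], h_of[m][0])))
        basis.append(Descriptor("oh_bond", (o_of[m], h_of[m][1])))
    for m in range(n_mol):
        basis.append(Descriptor("hoh_angle", (h_of[m][0], o_of[m], h_of[m][1])))

    n = template.n_atoms
    for i, j in combinations(range(n), 2):
        if mol[i] != mol[j]:
            basis.append(Descriptor("inter_distance", (i, j)))

    if level == "N3":
        if inter_angle_rule not in ("bonded", "arms", "any", "strict"):
            raise ValueError(f"unknown inter_angle_rule {inter_angle_rule!r}")
        covalent = set()
        for m in range(n_mol):
            for h in h_of[m]:
                covalent.add((o_of[m], h))
                covalent.add((h, o_of[m]))
        for j in range(n):
            for i, k in combinations([a for a in range(n) if a != j], 2):
                mols = {mol[i], mol[j], mol[k]}
                if len(mols) == 1:
                    continue
                if inter_angle_rule == "strict" and len(mols) < 3:
                    continue
                if inter_angle_rule == "arms" and (
                        mol[i] == mol[j] or mol[k] == mol[j]):
                    continue
                if inter_angle_rule == "bonded":
                    arm_i = ((i, j) in covalent, mol[i] != mol[j])
                    arm_k = ((k, j) in covalent, mol[k] != mol[j])
                    if not ((arm_i[0] and arm_k[1]) or (arm_k[0] and arm_i[1])):
                        continue
                basis.append(Descriptor("inter_angle", (i, j, k)))
    return basis


def n_fixed(basis: list[Descriptor]) -> int:
    """K — the number of intramolecular descriptors (leading block)."""
    return sum(1 for d in basis if d.is_intra)


def _split(basis: list[Descriptor]):
    pairs = np.array([d.atoms for d in basis if not d.is_angle], dtype=int)
    triples = np.array([d.atoms for d in basis if d.is_angle], dtype=int)
    pair_rows = np.array([i for i, d in enumerate(basis) if not d.is_angle], dtype=int)
    trip_rows = np.array([i for i, d in enumerate(basis) if d.is_angle], dtype=int)
    return pairs.reshape(-1, 2), triples.reshape(-1, 3), pair_rows, trip_rows


def evaluate(x: np.ndarray, basis: list[Descriptor]) -> np.ndarray:
    """Descriptor values r(x) for x of shape (..., n_atoms, 3) -> (..., M)."""
    pairs, triples, pr, tr = _split(basis)
    out = np.empty(x.shape[:-2] + (len(basis),))
    if pr.size:
        out[..., pr] = geometry.bond_lengths(x, pairs)
    if tr.size:
        out[..., tr] = geometry.bend_angles(x, triples)
    return out


def wilson_b(x: np.ndarray, basis: list[Descriptor]) -> np.ndarray:
    """Per-walker Wilson Jacobian B_ij = dr_i/dx_j, shape (..., M, 3*n_atoms)."""
    n_at = x.shape[-2]
    pairs, triples, pr, tr = _split(basis)
    b = np.zeros(x.shape[:-2] + (len(basis), n_at, 3))
    if pr.size:
        _, ga, gb = geometry.bond_gradients(x, pairs)
        b[..., pr, pairs[:, 0], :] = ga
        b[..., pr, pairs[:, 1], :] = gb
    if tr.size:
        _, gi, gj, gk = geometry.bend_gradients(x, triples)
        b[..., tr, triples[:, 0], :] = gi
        b[..., tr, triples[:, 1], :] = gj
        b[..., tr, triples[:, 2], :] = gk
    return b.reshape(x.shape[:-2] + (len(basis), 3 * n_at))


@dataclass
class BEnsemble:
    """Ensemble-averaged Jacobian <B> and kinetic kernel <B Lambda B^T>."""

    b_mean: np.ndarray    # (M, 3N)
    blbt_mean: np.ndarray  # (M, M), Lambda = diag(1/m) per dof
    basis: list[Descriptor]


def ensemble_b(xs: np.ndarray, weights: np.ndarray, basis: list[Descriptor],
               masses_dof: np.ndarray, chunk: int = 4096) -> BEnsemble:
    """Accumulate <B> and <B Lambda B^T> over an (n, n_atoms, 3) ensemble
    with normalized ``weights`` (amplitude weights W_DW * w)."""
    m = len(basis)
    dof = xs.shape[-2] * 3
    inv_m = 1.0 / np.asarray(masses_dof)
    wsum = weights.sum()
    b_acc = np.zeros((m, dof))
    k_acc = np.zeros((m, m))
    for lo in range(0, xs.shape[0], chunk):
        xb = xs[lo:lo + chunk]
        wb = weights[lo:lo + chunk]
        b = wilson_b(xb, basis)
        b_acc += np.einsum("n,nmd->md", wb, b)
        k_acc += np.einsum("nmd,d,nkd,n->mk", b, inv_m, b, wb, optimize=True)
    return BEnsemble(b_mean=b_acc / wsum, blbt_mean=k_acc / wsum, basis=basis)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------


@dataclass
class ReductionU:
    """Orthonormal reduction matrix U (M x n_modes) with its provenance."""

    u: np.ndarray
    singular_values: np.ndarray
    scheme: str              # "standard" | "chem_informed"
    k_fixed: int = 0


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Deterministic column signs: largest-|entry| positive, ties -> lowest row."""
    u = u.copy()
    for col in range(u.shape[1]):
        c = u[:, col]
        imax = int(np.argmax(np.round(np.abs(c), 12)))  # ties: lowest index wins
        if c[imax] < 0:
            u[:, col] = -c
    return u


def _warn_degenerate(s: np.ndarray, cut: int, rtol: float = 1e-10) -> None:
    if 0 < cut < s.size and abs(s[cut - 1] - s[cut]) <= rtol * max(s[0], 1.0):
        warnings.warn(
            f"singular values degenerate at the retained cut "
            f"({s[cut-1]:.3e} vs {s[cut]:.3e}); ties broken by column order",
            stacklevel=3)


def reduce_standard(b_ens: BEnsemble, n_keep: int) -> ReductionU:
    """Leading ``n_keep`` (= 3N - 6) left singular vectors of <B>."""
    u, s, _ = np.linalg.svd(b_ens.b_mean, full_matrices=True)
    _warn_degenerate(s, n_keep)
    return ReductionU(u=_fix_signs(u[:, :n_keep]), singular_values=s[:n_keep],
                      scheme="standard")


def reduce_chem_informed(b_ens: BEnsemble, n_keep: int,
                         k_fixed: int | None = None) -> ReductionU:
    """Block reduction pinning the K intramolecular rows as exact coordinates.

    QR of <B>_fixed^T spans the fixed row space; the free (intermolecular)
    rows are projected onto its orthogonal complement and reduced by SVD to
    the remaining n_keep - K directions.  The assembled U is
    [[I_K, 0], [0, U_free]].
    """
    k = n_fixed(b_ens.basis) if k_fixed is None else k_fixed
    m = b_ens.b_mean.shape[0]
    b_fixed = b_ens.b_mean[:k]
    q_f, r_f = np.linalg.qr(b_fixed.T)
    if np.min(np.abs(np.diag(r_f))) < 1e-10 * max(1.0, np.abs(r_f).max()):
        raise ValueError(
            "fixed intramolecular rows of <B> are rank deficient; the bonded "
            "coordinates are linearly dependent for this ensemble")
    b_free = b_ens.b_mean[k:]
    proj = b_free - (b_free @ q_f) @ q_f.T  # rows through P_perp = I - Qf Qf^T
    u_free, s, _ = np.linalg.svd(proj, full_matrices=True)
    n_free = n_keep - k
    _warn_degenerate(s, n_free)
    u = np.zeros((m, n_keep))
    u[:k, :k] = np.eye(k)
    u[k:, k:] = _fix_signs(u_free[:, :n_free])
    return ReductionU(u=u, singular_values=s[:n_free], scheme="chem_informed",
                      k_fixed=k)


# ---------------------------------------------------------------------------
# G matrix
# ---------------------------------------------------------------------------


@dataclass
class GMatrix:
    g: np.ndarray
    inv_sqrt: np.ndarray
    eigenvalues: np.ndarray


def g_matrix(b_ens: BEnsemble, reduction: ReductionU,
             eig_floor: float = 1e-12) -> GMatrix:
    """<G> = U^T <B Lambda B^T> U and its symmetric inverse square root."""
    u = reduction.u
    g = u.T @ b_ens.blbt_mean @ u
    g = 0.5 * (g + g.T)
    inv_sqrt, evals = g_inv_sqrt(g, eig_floor, return_evals=True)
    return GMatrix(g=g, inv_sqrt=inv_sqrt, eigenvalues=evals)


def g_inv_sqrt(g: np.ndarray, eig_floor: float = 1e-12,
               return_evals: bool = False):
    """Symmetric eigendecomposition inverse square root with a relative
    eigenvalue floor (clamped eigenvalues are reported via a warning)."""
    evals, vecs = np.linalg.eigh(0.5 * (g + g.T))
    floor = eig_floor * max(evals.max(), 1e-300)
    if np.any(evals < floor):
        warnings.warn(
            f"{int(np.sum(evals < floor))} G-matrix eigenvalue(s) clamped to "
            f"{floor:.3e}", stacklevel=2)
    ev = np.maximum(evals, floor)
    out = (vecs / np.sqrt(ev)) @ vecs.T
    if return_evals:
        return out, evals
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def transform_T(p: np.ndarray, u: np.ndarray) -> np.ndarray:
    """T = P^T U^T — the map from redundant descriptors to vibrational modes."""
    return p.T @ u.T


def _kind_columns(basis: list[Descriptor], kinds) -> np.ndarray:
    return np.array([i for i, d in enumerate(basis) if d.kind in kinds], dtype=int)


def cif_diagnostics(t: np.ndarray, basis: list[Descriptor]) -> dict[str, float]:
    """Character imbalance factors from the squared entries of T.

    chi_total(class) = sum of T_ij^2 over all modes i and class columns j;
    CIF(class) = (chi_total - K_class)/K_class.  Zero means the class is
    proportionally represented; negative means under-representation.
    """
    t2 = t * t
    out: dict[str, float] = {}
    intra = _kind_columns(basis, INTRA_KINDS)
    bond = _kind_columns(basis, ("oh_bond",))
    angle = _kind_columns(basis, ("hoh_angle",))
    chi_intra = float(t2[:, intra].sum())
    out["chi_intra_total"] = chi_intra
    out["cif_intra"] = (chi_intra - intra.size) / intra.size
    out["cif_bond"] = (float(t2[:, bond].sum()) - bond.size) / bond.size
    out["cif_angle"] = (float(t2[:, angle].sum()) - angle.size) / angle.size
    return out


def mixing_fraction(t: np.ndarray, basis: list[Descriptor],
                    k: int | None = None) -> float:
    """f_inter->intra: share of intermolecular-descriptor weight inside the
    first K vibrational modes, normalized by chi_intra_total."""
    if k is None:
        k = n_fixed(basis)
    t2 = t * t
    intra = _kind_columns(basis, INTRA_KINDS)
    chi = float(t2[:, intra].sum())
    if chi == 0.0 or t.shape[1] == k:
        return 0.0
    inter = np.array([j for j in range(t.shape[1]) if j not in set(intra)], dtype=int)
    return float(t2[:k][:, inter].sum() / chi)


def mode_character(t: np.ndarray, basis: list[Descriptor], mode: int,
                   kind: str = "oh_bond") -> float:
    """chi_l: squared weight of one descriptor class in mode ``mode``."""
    if kind == "inter":
        cols = _kind_columns(basis, ("inter_distance", "inter_angle"))
    else:
        cols = _kind_columns(basis, (kind,))
    return float(np.sum(t[mode, cols] ** 2))
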