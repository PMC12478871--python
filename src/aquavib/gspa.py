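"""Ground-state probability amplitude (GSPA) vibrational analysis.

Modes are the principal axes of the mass-weighted internal-coordinate
fluctuations of the sampled |psi|^2: with C the weighted covariance of the
reduced coordinates q and <G> the ensemble kinetic metric, the eigenvectors
P of <G>^{-1/2} C <G>^{-1/2} define mass-weighted vibrational coordinates

    v_MW = P^T <G>^{-1/2} (q - <q>)

whose weighted covariance is diag(lambda) (the mass-weighting is applied
before the rotation so the modes decorrelate exactly and carry unit
effective mass).  A fundamental is obtained by multiplying the ground state
by the first excitation polynomial f_l = v_MW,l - <v_MW,l>; the excitation
energy splits exactly into a potential gap

    dV_l = <V f_l^2>/<f_l^2> - <V>_0

and a kinetic gap estimated from the amplitude's moments

    dT_l = (hbar^2/2) <f_l^2> / (<f_l^4> - <f_l^2>^2),

so nu_l = dV_l + dT_l by construction.  IR intensities follow from the
point-charge transition moment, I_l ∝ nu_l |<mu f_l>|^2 / (<f_l^2><0|0>).

All expectations are amplitude-weighted (W_DW * w).  Modes are indexed in
descending order of covariance eigenvalue, which ranks them more stably
than frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import internal_coords as ic
from .dmc import Snapshot
from .landscape import eckart_frame
from .pes import Configuration, WaterSystem
from .units import HARTREE_TO_WAVENUMBER

__all__ = [
    "ModeResult", "SpectraResult", "covariance", "extract_modes",
    "mode_frequency", "effective_harmonic_frequency", "analyze_modes",
    "analyze", "spectrum",
]


@dataclass
class ModeResult:
    """One vibrational fundamental and its diagnostics."""

    index: int
    nu: float                 # fundamental, cm^-1 (nan if degenerate)
    dv: float                 # potential gap, cm^-1
    dt: float                 # kinetic gap, cm^-1
    eigenvalue: float         # covariance eigenvalue lambda_l (a.u.)
    intensity: float = 0.0    # relative IR intensity (max-normalized)
    chi: dict = field(default_factory=dict)   # per-class character chi_l
    label: str = ""
    degenerate: bool = False

    @property
    def nu_effective_harmonic(self) -> float:
        return effective_harmonic_frequency(self.eigenvalue)


def covariance(q: np.ndarray, weights: np.ndarray):
    """Weighted second-moments matrix about the weighted mean.

    Returns (C, q_mean) for q of shape (n, d).
    """
    w = weights / weights.sum()
    q_mean = w @ q
    dq = q - q_mean
    c = np.einsum("n,ni,nj->ij", w, dq, dq)
    return 0.5 * (c + c.T), q_mean


def extract_modes(c: np.ndarray, g_inv_sqrt: np.ndarray):
    """Eigenvectors/eigenvalues of <G>^{-1/2} C <G>^{-1/2}, descending.

    Returns (eigenvalues, P) with deterministic column signs.
    """
    a = g_inv_sqrt @ c @ g_inv_sqrt
    evals, vecs = np.linalg.eigh(0.5 * (a + a.T))
    order = np.argsort(evals)[::-1]
    return evals[order], ic._fix_signs(vecs[:, order])


def effective_harmonic_frequency(eigenvalue: float) -> float:
    """Frequency implied by the ground-state variance alone.

    For a harmonic mode the mass-weighted ground-state variance is
    hbar/(2 omega), so omega = hbar/(2 lambda); returned in cm^-1.
    """
    return 0.5 / eigenvalue * HARTREE_TO_WAVENUMBER


def mode_frequency(vmw_l: np.ndarray, v_pot: np.ndarray, weights: np.ndarray,
                   v0: float | None = None):
    """(dv, dt, nu) in hartree for one mode's mass-weighted samples.

    Returns (nan, nan, nan) when the excitation-moment denominator
    <f^4> - <f^2>^2 is not positive (insufficient sampling).
    """
    w = weights / weights.sum()
    f = vmw_l - w @ vmw_l
    f2 = f * f
    m2 = w @ f2
    m4 = w @ (f2 * f2)
    denom = m4 - m2 * m2
    if denom <= 0.0:
        return float("nan"), float("nan"), float("nan")
    if v0 is None:
        v0 = float(w @ v_pot)
    dv = float(w @ (f2 * v_pot) / m2 - v0)
    dt = float(0.5 * m2 / denom)
    return dv, dt, dv + dt


def _intensity(vmw_l, v_pot, weights, dipole, nu_au):
    w = weights
    f = vmw_l - (w @ vmw_l) / w.sum()
    num = np.einsum("n,n,nj->j", w, f, dipole)
    return float(nu_au * (num @ num) / ((w @ (f * f)) * w.sum()))


def analyze_modes(q: np.ndarray, weights: np.ndarray, v_pot: np.ndarray,
                  g: np.ndarray, dipole: np.ndarray | None = None):
    """Core GSPA pipeline on reduced coordinates q (n, d) with metric g (d, d).

    Returns (modes, P, g_inv_sqrt, vmw) where ``modes`` is a list of
    :class:`ModeResult` sorted by descending eigenvalue.  Intensities are
    max-normalized when a dipole array (n, 3) is given.
    """
    gis = ic.g_inv_sqrt(g)
    c, _ = covariance(q, weights)
    evals, p = extract_modes(c, gis)
    wn = weights / weights.sum()
    q_mean = wn @ q
    vmw = (q - q_mean) @ gis @ p
    v0 = float(wn @ v_pot)
    modes: list[ModeResult] = []
    for l in range(vmw.shape[1]):
        dv, dt, nu = mode_frequency(vmw[:, l], v_pot, weights, v0)
        mode = ModeResult(
            index=l,
            nu=nu * HARTREE_TO_WAVENUMBER if np.isfinite(nu) else float("nan"),
            dv=dv * HARTREE_TO_WAVENUMBER if np.isfinite(dv) else float("nan"),
            dt=dt * HARTREE_TO_WAVENUMBER if np.isfinite(dt) else float("nan"),
            eigenvalue=float(evals[l]),
            degenerate=not np.isfinite(nu))
        if dipole is not None and np.isfinite(nu):
            mode.intensity = _intensity(vmw[:, l], v_pot, weights, dipole, nu)
        modes.append(mode)
    peak = max((m.intensity for m in modes), default=0.0)
    if peak > 0:
        for m in modes:
            m.intensity /= peak
    return modes, p, gis, vmw


@dataclass
class SpectraResult:
    """Full GSPA analysis of a walker ensemble in one reduced basis."""

    modes: list[ModeResult]
    basis: list[ic.Descriptor]
    reduction: ic.ReductionU
    gmat: ic.GMatrix
    p: np.ndarray
    t: np.ndarray                 # T = P^T U^T
    cif: dict[str, float]
    mixing: float
    q_mean: np.ndarray
    vmw_mean: np.ndarray
    reference: Configuration
    zpe: float | None = None      # hartree, if supplied by the run

    def table(self) -> pd.DataFrame:
        rows = []
        for m in self.modes:
            rows.append({
                "mode": m.index, "nu_cm1": m.nu, "dV_cm1": m.dv, "dT_cm1": m.dt,
                "intensity": m.intensity, "lambda_au": m.eigenvalue,
                "chi_bond": m.chi.get("oh_bond", np.nan),
                "chi_angle": m.chi.get("hoh_angle", np.nan),
                "chi_inter": m.chi.get("inter", np.nan),
                "label": m.label,
            })
        return pd.DataFrame(rows)

    def intramolecular_modes(self) -> list[ModeResult]:
        """Modes whose dominant character is bond or angle."""
        out = []
        for m in self.modes:
            kinds = ("oh_bond", "hoh_angle", "inter")
            if max(kinds, key=lambda k: m.chi.get(k, 0.0)) != "inter":
                out.append(m)
        return out

    def lowest_bend(self) -> ModeResult:
        bends = [m for m in self.intramolecular_modes()
                 if m.chi.get("hoh_angle", 0) > m.chi.get("oh_bond", 0)]
        return min(bends, key=lambda m: m.nu)

    def lowest_stretch(self) -> ModeResult:
        st = [m for m in self.intramolecular_modes()
              if m.chi.get("oh_bond", 0) > m.chi.get("hoh_angle", 0)]
        return min(st, key=lambda m: m.nu)

    def _in_phase(self, kind: str) -> ModeResult | None:
        """Mode of class ``kind`` with the most sign-coherent descriptor
        weight: argmax of |sum_j T_lj| over the class columns.  The signed
        sum cancels for out-of-phase combinations and is maximal for the
        in-phase one; being an eigenvector property it carries none of the
        order-statistic noise bias of "lowest frequency of a near-degenerate
        pair"."""
        cols = np.array([j for j, d in enumerate(self.basis) if d.kind == kind])
        cands = [m for m in self.modes if np.isfinite(m.nu)]
        if not cands:
            return None
        return max(cands, key=lambda m: abs(float(self.t[m.index, cols].sum())))

    def in_phase_bend(self) -> ModeResult:
        """The in-phase donor/acceptor HOH bend (falls back to the lowest
        bend when no sign-coherent candidate exists)."""
        return self._in_phase("hoh_angle") or self.lowest_bend()

    def in_phase_stretch(self) -> ModeResult:
        """The in-phase symmetric OH stretch combination (falls back to the
        lowest stretch)."""
        return self._in_phase("oh_bond") or self.lowest_stretch()

    def dominant_bond_mode(self, bond_column: int) -> ModeResult:
        """Mode carrying the largest squared weight of one OH-bond
        descriptor (e.g. the hydrogen-bonded donor OH).  All modes compete:
        under the standard reduction the donor-OH mode can be
        intermolecular-dominated overall while still holding most of that
        bond's weight."""
        t2 = self.t * self.t
        return max(self.modes, key=lambda m: t2[m.index, bond_column])


def _auto_label(chi: dict[str, float], basis, t_row: np.ndarray) -> str:
    kind = max(("oh_bond", "hoh_angle", "inter"), key=lambda k: chi.get(k, 0.0))
    names = {"oh_bond": "OH stretch", "hoh_angle": "HOH bend", "inter": "intermolecular"}
    cols = np.argsort(t_row**2)[::-1][:2]
    detail = ",".join(f"{basis[c].kind}{basis[c].atoms}" for c in cols)
    return f"{names[kind]} (chi={chi.get(kind, 0.0):.2f}; {detail})"


def analyze(snapshots: list[Snapshot], system: WaterSystem,
            reference: Configuration, scheme: str = "chem_informed",
            level: str = "N2", inter_angle_rule: str = "bonded",
            zpe: float | None = None, sort_walkers: bool = True) -> SpectraResult:
    """GSPA analysis of DMC snapshots for a water cluster.

    Walkers from all snapshots are concatenated, Eckart-aligned to the
    reference (GM) structure, projected on the redundant basis, reduced by
    the requested scheme, and converted into fundamentals, intensities and
    character diagnostics.

    ``sort_walkers`` folds label-exchange symmetry out of the ensemble
    before the analysis (walker sorting): each walker is relabeled by the
    permutation variant best matching the reference.  The amplitude
    delocalizes freely over exchange-equivalent wells (e.g. the acceptor
    hydrogens of the dimer), and leaving it unsorted makes descriptor
    distributions multimodal and corrupts the mode moments.
    """
    from .landscape import canonicalize_permutations

    na = system.n_atoms
    xs = np.concatenate([s.x for s in snapshots]).reshape(-1, na, 3)
    weights = np.concatenate([s.amplitude_weights for s in snapshots])
    ref_bohr = reference.coords_bohr()
    if sort_walkers:
        xs = canonicalize_permutations(xs, reference, system.pes.masses_au)
    xs = eckart_frame(xs, ref_bohr, system.pes.masses_au)

    basis = ic.build_basis(system.template, level, inter_angle_rule)
    n_modes = 3 * na - 6
    b_ens = ic.ensemble_b(xs, weights, basis, np.repeat(system.pes.masses_au, 3))
    if scheme == "standard":
        red = ic.reduce_standard(b_ens, n_modes)
    elif scheme == "chem_informed":
        red = ic.reduce_chem_informed(b_ens, n_modes)
    else:
        raise ValueError(f"unknown reduction scheme {scheme!r}")
    gmat = ic.g_matrix(b_ens, red)

    r = ic.evaluate(xs, basis)
    q = r @ red.u
    v_pot = system.pes.potential(xs)
    dip = system.pes.dipole(xs)

    modes, p, gis, vmw = analyze_modes(q, weights, v_pot, gmat.g, dipole=dip)
    t = ic.transform_T(p, red.u)
    for m in modes:
        m.chi = {
            "oh_bond": ic.mode_character(t, basis, m.index, "oh_bond"),
            "hoh_angle": ic.mode_character(t, basis, m.index, "hoh_angle"),
            "inter": ic.mode_character(t, basis, m.index, "inter"),
        }
        m.label = _auto_label(m.chi, basis, t[m.index])

    wn = weights / weights.sum()
    return SpectraResult(
        modes=modes, basis=basis, reduction=red, gmat=gmat, p=p, t=t,
        cif=ic.cif_diagnostics(t, basis),
        mixing=ic.mixing_fraction(t, basis),
        q_mean=wn @ q, vmw_mean=wn @ vmw, reference=reference, zpe=zpe)


def match_modes(reference: SpectraResult, other: SpectraResult) -> np.ndarray:
    """One-to-one mode assignment between two analyses of one ensemble.

    Overlaps of the T-matrix rows are computed on the descriptor subset
    common to both bases (matched by kind and atom tuple) and the global
    assignment maximizing total |overlap| is solved, so each mode keeps its
    identity when the redundant basis is extended — including within
    near-degenerate groups where per-mode greedy matching can jump.
    Returns ``assign`` with ``assign[i]`` the index in ``other`` matching
    mode ``i`` of ``reference``.
    """
    from scipy.optimize import linear_sum_assignment

    key = {(d.kind, d.atoms): j for j, d in enumerate(other.basis)}
    cols_ref, cols_oth = [], []
    for j, d in enumerate(reference.basis):
        k = (d.kind, d.atoms)
        if k in key:
            cols_ref.append(j)
            cols_oth.append(key[k])
    overlap = np.abs(reference.t[:, cols_ref] @ other.t[:, cols_oth].T)
    rows, cols = linear_sum_assignment(-overlap)
    assign = np.empty(len(reference.modes), dtype=int)
    assign[rows] = cols
    return assign


def match_mode(reference: SpectraResult, other: SpectraResult,
               mode_index: int) -> ModeResult:
    """The mode of ``other`` matching one mode of ``reference``."""
    return other.modes[int(match_modes(reference, other)[mode_index])]


def spectrum(modes: list[ModeResult], fwhm: float = 10.0,
             grid: np.ndarray | None = None):
    """Stick list and Gaussian-broadened curve (integral of each Gaussian
    equals the stick intensity).  Returns (sticks DataFrame, grid, curve)."""
    live = [m for m in modes if np.isfinite(m.nu)]
    sticks = pd.DataFrame({"nu_cm1": [m.nu for m in live],
                           "intensity": [m.intensity for m in live]})
    if grid is None:
        hi = 1.2 * max([m.nu for m in live], default=4000.0)
        grid = np.linspace(0.0, max(hi, 100.0), 2000)
    sig = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    curve = np.zeros_like(grid)
    for m in live:
        curve += m.intensity * np.exp(-((grid - m.nu) ** 2) / (2 * sig**2)) / (
            sig * np.sqrt(2 * np.pi))
    return sticks, grid, curve
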