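"""Potential-landscape exploration and walker classification.

Provides the pieces the sampling analyses rest on: BFGS minimization on the
analytic surface, a Metropolis Monte Carlo isomer search (which doubles as
the repository's fixture generator — no external geometries are needed),
mass-weighted Eckart alignment, and classification of walkers into
(isomer, permutation) labels by the minimize-align-RMSD scheme.

A walker belongs to a given permutation variant of an isomer when its
minimized, Eckart-aligned structure has numerically zero mass-weighted RMSD
from that variant; the match tolerance here is 1e-3 Å, far below
inter-minimum distances and above optimizer noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize

from .pes import Configuration, QspcfwParams, WaterPES
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL, KB_HARTREE

__all__ = [
    "IsomerCatalog", "minimize", "isomer_search", "eckart_align",
    "mass_weighted_rmsd", "classify_walker", "isomer_fractions",
    "permutation_variants",
]

#: mass-weighted RMSD below which two aligned minima are the same structure (Å)
RMSD_MATCH_TOL = 1e-3
#: energy window used to pre-filter candidate isomers (kcal/mol)
ENERGY_MATCH_TOL = 1e-4


@dataclass
class IsomerCatalog:
    """Distinct minima of a cluster, sorted by energy (kcal/mol); index 0 = GM."""

    minima: list[Configuration]
    energies: list[float]
    params: QspcfwParams

    def __post_init__(self) -> None:
        order = np.argsort(self.energies)
        self.minima = [self.minima[i] for i in order]
        self.energies = [float(self.energies[i]) for i in order]

    @property
    def gm(self) -> Configuration:
        return self.minima[0]

    def __len__(self) -> int:
        return len(self.minima)


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------


def minimize(config: Configuration, params: QspcfwParams,
             gtol: float = 1e-9) -> tuple[Configuration, float]:
    """BFGS descent on the analytic surface; returns (minimum, energy kcal/mol).

    ``gtol`` is the max-component gradient threshold in hartree/bohr.
    """
    pes = WaterPES(config, params)
    x0 = config.coords_bohr().ravel()
    n = config.n_atoms

    def f(x):
        return float(pes.potential(x.reshape(n, 3)))

    def g(x):
        return pes.gradient(x.reshape(n, 3)).ravel()

    res = optimize.minimize(f, x0, jac=g, method="BFGS",
                            options={"gtol": gtol, "maxiter": 5000})
    out = config.with_coords_bohr(res.x.reshape(n, 3))
    return out, float(res.fun) * HARTREE_TO_KCALMOL


# ---------------------------------------------------------------------------
# Eckart alignment (mass-weighted Kabsch)
# ---------------------------------------------------------------------------


def _kabsch(x: np.ndarray, ref: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Batched proper rotation aligning x (..., na, 3) onto ref (na, 3)."""
    c = np.einsum("a,...ai,aj->...ij", masses, x, ref)
    u, _, vt = np.linalg.svd(c)
    det = np.linalg.det(np.einsum("...ij,...jk->...ik", u, vt))
    d = np.ones(det.shape + (3,))
    d[..., 2] = det
    return np.einsum("...ik,...k,...kj->...ij", u, d, vt)


def eckart_frame(x: np.ndarray, ref: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Translate/rotate coordinates into the Eckart frame of ``ref``.

    Works on a single geometry (na, 3) or a batch (..., na, 3).  The optimal
    mass-weighted Kabsch rotation satisfies the rotational Eckart condition
    sum_i m_i x_i^ref x x_i = 0 exactly.
    """
    mtot = masses.sum()
    ref0 = ref - np.einsum("a,ai->i", masses, ref) / mtot
    x0 = x - np.einsum("a,...ai->...i", masses, x)[..., None, :] / mtot
    rot = _kabsch(x0, ref0, masses)
    return np.einsum("...ai,...ij->...aj", x0, rot) + np.einsum(
        "a,ai->i", masses, ref) / mtot


def eckart_align(config: Configuration, reference: Configuration) -> Configuration:
    """Eckart-align a configuration to a reference structure."""
    aligned = eckart_frame(config.coords, reference.coords, config.masses)
    return Configuration(aligned, list(config.elements), config.masses.copy(),
                         config.mol_index.copy())


def mass_weighted_rmsd(a: np.ndarray, b: np.ndarray, masses: np.ndarray) -> float:
    """sqrt( sum m |a-b|^2 / sum m ), same units as the coordinates."""
    num = np.einsum("a,ai->", masses, (a - b) ** 2)
    return float(np.sqrt(num / masses.sum()))


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------


def permutation_variants(n_molecules: int) -> Iterator[np.ndarray]:
    """Index maps of the label-exchange group: (H-swap within each monomer)
    x (monomer relabelings); identity first.  Size 2^n * n!.

    Each map p sends slot i to original atom p[i]; element identity is
    preserved by construction (O stays in the O slot of each monomer).
    """
    base = np.arange(3 * n_molecules)
    for perm in permutations(range(n_molecules)):
        for swaps in product((False, True), repeat=n_molecules):
            p = np.empty_like(base)
            for slot, src in enumerate(perm):
                o = 3 * src
                p[3 * slot] = o
                p[3 * slot + 1] = o + 2 if swaps[slot] else o + 1
                p[3 * slot + 2] = o + 1 if swaps[slot] else o + 2
            yield p


def count_permutation_variants(n_molecules: int) -> int:
    import math

    return 2**n_molecules * math.factorial(n_molecules)


def donor_hydrogens(reference: Configuration, cutoff: float = 2.2) -> set[int]:
    """Atom indices of hydrogen-bond-donating H atoms in a structure
    (H with an intermolecular O contact below ``cutoff`` Å)."""
    x = reference.coords
    out = set()
    for h in range(reference.n_atoms):
        if reference.elements[h] != "H":
            continue
        for o in range(reference.n_atoms):
            if (reference.elements[o] == "O"
                    and reference.mol_index[o] != reference.mol_index[h]
                    and np.linalg.norm(x[h] - x[o]) < cutoff):
                out.add(h)
    return out


def permutation_changes_topology(perm: np.ndarray,
                                 reference: Configuration) -> bool:
    """Whether a label exchange alters the hydrogen-bond topology.

    Swapping two *free* hydrogens of one monomer is realized by an internal
    rotation whose barrier lies far below the zero-point level on this
    surface — the exchanged labelings belong to one vibrational well and
    the exchange is not a distinct permutation event.  Exchanges that move
    a donating hydrogen or relabel monomers do change the topology.
    """
    n_mol = reference.n_molecules
    mol_map = perm.reshape(n_mol, 3)[:, 0] // 3
    if not np.array_equal(mol_map, np.arange(n_mol)):
        return True
    donors = donor_hydrogens(reference)
    for slot in range(reference.n_atoms):
        src = perm[slot]
        if src != slot and (slot in donors or src in donors):
            return True
    return False


def canonicalize_hydrogens(xs: np.ndarray, reference: Configuration,
                           masses_au: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Fold facile within-monomer H exchanges out of a walker ensemble.

    Each walker is Eckart-aligned to the reference and, per monomer, its two
    hydrogens are assigned the labeling minimizing the mass-weighted
    distance to the reference; alignment and assignment are iterated.  This
    is the walker-sorting step that keeps a probability amplitude
    delocalized over topologically trivial label exchanges (e.g. the two
    free hydrogens of an H-bond acceptor, whose exchange barrier is far
    below the zero-point level) unimodal in descriptor space.

    ``xs`` has shape (n, n_atoms, 3) in bohr; the returned array is
    relabeled and expressed in the Eckart frame of the reference.
    """
    ref = reference.coords * ANGSTROM_TO_BOHR
    xs = xs.copy()
    h1s = []
    h2s = []
    elements = np.array(reference.elements)
    for m in range(reference.n_molecules):
        h = np.flatnonzero((reference.mol_index == m) & (elements == "H"))
        h1s.append(int(h[0]))
        h2s.append(int(h[1]))
    for _ in range(n_iter):
        xs = eckart_frame(xs, ref, masses_au)
        for h1, h2 in zip(h1s, h2s):
            d_keep = (np.sum((xs[:, h1] - ref[h1]) ** 2, axis=1)
                      + np.sum((xs[:, h2] - ref[h2]) ** 2, axis=1))
            d_swap = (np.sum((xs[:, h1] - ref[h2]) ** 2, axis=1)
                      + np.sum((xs[:, h2] - ref[h1]) ** 2, axis=1))
            mask = d_swap < d_keep
            xs[np.ix_(mask, [h1, h2])] = xs[np.ix_(mask, [h2, h1])]
    return xs


def canonicalize_permutations(xs: np.ndarray, reference: Configuration,
                              masses_au: np.ndarray,
                              max_variants: int = 1000) -> np.ndarray:
    """Full walker sorting: relabel each walker by the permutation variant
    minimizing its Eckart-aligned mass-weighted RMSD to the reference.

    This folds the entire label-exchange group (within-monomer H swaps and
    monomer relabelings) into one permutation cell, so an amplitude that is
    symmetrically delocalized over exchange-equivalent wells is analyzed as
    a single-well amplitude.  For clusters whose group exceeds
    ``max_variants`` only the 2^n within-monomer swaps are folded (via
    :func:`canonicalize_hydrogens`).

    ``xs`` is (n, n_atoms, 3) in bohr; returns relabeled coordinates in the
    Eckart frame of the reference.
    """
    n_mol = reference.n_molecules
    if count_permutation_variants(n_mol) > max_variants:
        return canonicalize_hydrogens(xs, reference, masses_au)
    ref = reference.coords * ANGSTROM_TO_BOHR
    best_rmsd = np.full(xs.shape[0], np.inf)
    best = np.empty_like(xs)
    m = masses_au
    mtot = m.sum()
    ref0 = ref - (m @ ref) / mtot
    for p in permutation_variants(n_mol):
        cand = xs[:, p]
        x0 = cand - np.einsum("a,nai->ni", m, cand)[:, None, :] / mtot
        rot = _kabsch(x0, ref0, m)
        ali = np.einsum("nai,nij->naj", x0, rot)
        rmsd = np.einsum("a,nai->n", m, (ali - ref0) ** 2)
        mask = rmsd < best_rmsd
        best_rmsd[mask] = rmsd[mask]
        best[mask] = ali[mask] + (m @ ref) / mtot
    return best


def permutation_probability(snapshots, template: Configuration,
                            catalog: IsomerCatalog, max_walkers: int = 700,
                            seed: int = 0) -> float:
    """Probability-amplitude share of walkers whose quenched structure
    matches a topology-changing permutation of its isomer (in percent).

    Weights are the |psi|^2 (descendant) weights — "probability" refers to
    the ground-state probability amplitude.  Topology-preserving exchanges
    (free-hydrogen swaps realized by facile internal rotation) are not
    counted; see :func:`permutation_changes_topology`.
    """
    xs = np.concatenate([s.x for s in snapshots])
    wts = np.concatenate([s.amplitude_weights for s in snapshots])
    if xs.shape[0] > max_walkers:
        idx = np.random.default_rng(seed).choice(xs.shape[0], max_walkers,
                                                 replace=False)
        xs, wts = xs[idx], wts[idx]
    labels = classify_ensemble(xs, template, catalog)
    variants = {}
    bad = 0.0
    for (iso, pid), w in zip(labels, wts):
        if iso < 0:
            bad += w
            continue
        if iso not in variants:
            variants[iso] = list(permutation_variants(
                catalog.minima[iso].n_molecules))
        if pid > 0 and permutation_changes_topology(
                variants[iso][pid], catalog.minima[iso]):
            bad += w
    return float(100.0 * bad / wts.sum())


# ---------------------------------------------------------------------------
# isomer search (Metropolis MC + minimization)
# ---------------------------------------------------------------------------


def _random_cluster(n_molecules: int, params: QspcfwParams,
                    rng: np.random.Generator) -> Configuration:
    """Random non-overlapping placement of rigid equilibrium monomers."""
    th, l = params.theta_eq, params.l_eq
    mono = np.array([[0.0, 0.0, 0.0],
                     [l * np.sin(th / 2), 0.0, l * np.cos(th / 2)],
                     [-l * np.sin(th / 2), 0.0, l * np.cos(th / 2)]])
    coords = []
    centers: list[np.ndarray] = []
    for _ in range(n_molecules):
        for _attempt in range(200):
            c = rng.uniform(-1.8 * n_molecules ** (1 / 3), 1.8 * n_molecules ** (1 / 3), 3)
            if all(np.linalg.norm(c - p) > 2.4 for p in centers):
                break
        centers.append(c)
        # random proper rotation via QR
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        coords.append(mono @ q.T + c)
    return Configuration.water(np.vstack(coords))


def isomer_search(n_molecules: int, params: QspcfwParams, mc_steps: int = 400,
                  temperature: float = 400.0, seed: int | np.random.SeedSequence = 0,
                  minimize_every: int = 20, n_starts: int = 4,
                  anneal: float = 0.995) -> IsomerCatalog:
    """Metropolis Monte Carlo with periodic minimization.

    Per-atom Gaussian moves (0.08 Å) at an annealed temperature; every
    ``minimize_every`` accepted batches the current walker is quenched and
    the minimum added to the catalog if it is new (no permutation variant of
    an existing entry matches within the RMSD tolerance).  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    minima: list[Configuration] = []
    energies: list[float] = []

    def _register(cand: Configuration, e: float) -> None:
        for known, ek in zip(minima, energies):
            if abs(e - ek) > ENERGY_MATCH_TOL:
                continue
            for p in permutation_variants(n_molecules):
                ref = Configuration(known.coords[p], list(known.elements),
                                    known.masses, known.mol_index)
                ali = eckart_align(cand, ref)
                if mass_weighted_rmsd(ali.coords, ref.coords, cand.masses) < RMSD_MATCH_TOL:
                    return
        minima.append(cand)
        energies.append(e)

    for _ in range(n_starts):
        cfg = _random_cluster(n_molecules, params, rng)
        cfg, e = minimize(cfg, params)
        _register(cfg, e)
        pes = WaterPES(cfg, params)
        x = cfg.coords_bohr()
        v = float(pes.potential(x))
        t = temperature
        for step in range(mc_steps):
            prop = x + rng.normal(0.0, 0.08 * ANGSTROM_TO_BOHR, x.shape)
            vp = float(pes.potential(prop))
            if vp < v or rng.random() < np.exp(-(vp - v) / (KB_HARTREE * t)):
                x, v = prop, vp
            t *= anneal
            if (step + 1) % minimize_every == 0:
                cand, e = minimize(cfg.with_coords_bohr(x), params)
                _register(cand, e)
    return IsomerCatalog(minima=minima, energies=energies, params=params)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_walker(config: Configuration, catalog: IsomerCatalog,
                    check_permutations: bool = True,
                    already_minimized: bool = False) -> tuple[int, int]:
    """Assign (isomer id, permutation id); (-1, -1) when unclassified.

    The walker is quenched, candidate isomers are pre-filtered by minimum
    energy, and the (isomer, permutation) label is fixed by the first
    permutation variant whose Eckart-aligned mass-weighted RMSD falls below
    the match tolerance (the identity permutation is tried first).
    """
    if already_minimized:
        mcfg = config
        e = None
    else:
        mcfg, e = minimize(config, catalog.params)
    for iso, ref in enumerate(catalog.minima):
        if e is not None and abs(e - catalog.energies[iso]) > 10 * ENERGY_MATCH_TOL:
            continue
        n_mol = ref.n_molecules
        for pid, p in enumerate(permutation_variants(n_mol)):
            variant = Configuration(ref.coords[p], list(ref.elements),
                                    ref.masses, ref.mol_index)
            ali = eckart_frame(mcfg.coords, variant.coords, mcfg.masses)
            if mass_weighted_rmsd(ali, variant.coords, mcfg.masses) < RMSD_MATCH_TOL:
                return iso, pid
            if not check_permutations:
                break
    return -1, -1


def classify_ensemble(x_bohr: np.ndarray, template: Configuration,
                      catalog: IsomerCatalog,
                      check_permutations: bool = True) -> np.ndarray:
    """Classify a stack of flat walker coordinates (n, 3*na); returns an
    (n, 2) array of (isomer id, permutation id)."""
    n = x_bohr.shape[0]
    out = np.empty((n, 2), dtype=int)
    na = template.n_atoms
    for i in range(n):
        cfg = template.with_coords_bohr(x_bohr[i].reshape(na, 3))
        out[i] = classify_walker(cfg, catalog, check_permutations)
    return out


def isomer_fractions(snapshots, template: Configuration, catalog: IsomerCatalog,
                     mode: str = "wavefunction", max_walkers: int | None = None,
                     seed: int = 0, check_permutations: bool = False) -> dict:
    """Share of (amplitude or wave-function) weight per isomer.

    Each walker is minimized and classified; fractions are weight shares and
    sum to 1 (the unclassified share is reported under key -1).  For large
    ensembles an unbiased uniform subsample of ``max_walkers`` walkers keeps
    the quench cost bounded.
    """
    xs = np.concatenate([s.x for s in snapshots])
    if mode == "wavefunction":
        wts = np.concatenate([s.psi_weights for s in snapshots])
    else:
        wts = np.concatenate([s.amplitude_weights for s in snapshots])
    if max_walkers is not None and xs.shape[0] > max_walkers:
        idx = np.random.default_rng(seed).choice(xs.shape[0], max_walkers, replace=False)
        xs, wts = xs[idx], wts[idx]
    labels = classify_ensemble(xs, template, catalog, check_permutations)
    frac: dict[int, float] = {}
    total = wts.sum()
    for iso in np.unique(labels[:, 0]):
        frac[int(iso)] = float(wts[labels[:, 0] == iso].sum() / total)
    return frac
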