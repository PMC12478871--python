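# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `aquavib`. It states no empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## The physical problem

Small water clusters are strongly anharmonic quantum systems: OH stretches,
HOH bends and the floppy intermolecular modes couple, and zero-point motion
spans geometries far from any minimum. `aquavib` predicts their
fundamental vibrational frequencies and relative IR intensities without a
harmonic expansion, by (i) sampling the exact nuclear ground state on an
analytic surface with diffusion Monte Carlo (DMC) and (ii) extracting modes
and excitation energies directly from the sampled ground-state probability
amplitude (GSPA).

## Potential energy surface

The q-SPC/Fw flexible point-charge water model: per monomer a harmonic
bond-stretch term (k_OH/2)(l − l_eq)² for each OH bond and a harmonic bend
(k_A/2)(θ − θ_eq)²; between molecules a Lennard-Jones term for every O–O
pair and Coulomb terms for all intermolecular atom pairs. There are no
intramolecular nonbonded terms. Parameters are read from a flat key/value
file (`src/aquavib/params/qspcfw.params`):

| parameter | value | units |
|---|---|---|
| k_OH | 1059.162 | kcal mol⁻¹ Å⁻² |
| l_eq | 1.0 | Å |
| k_A | 75.90 | kcal mol⁻¹ rad⁻² |
| θ_eq | 112.0 | deg |
| q_O / q_H | −0.84 / +0.42 | e |
| ε_OO / σ_OO | 0.1554253 / 3.165492 | kcal mol⁻¹ / Å |

Atomic masses are standard atomic weights (H 1.008, O 15.999 amu), not
isotopic masses. All internal computation uses Hartree atomic units
(ℏ = 1); I/O uses Å, amu, kcal/mol and cm⁻¹ with CODATA conversion factors
from scipy.

The local-mode harmonic wavenumbers implied by this parameter set are
√(k_OH/μ_OH)/2πc for the stretch and √(k_A/μ_A)/2πc for the bend, with
μ_OH = m_O m_H/(m_O+m_H) and μ_A = (l_eq²/2)/(1/m_H + (1−cos θ_eq)/m_O).
The stretch value is the package's analytic regression anchor. The bend
local-mode estimate and the monomer Hessian normal-mode bend agree with
each other to a fraction of a percent and are both exposed; no single
"bend harmonic" is privileged because the two definitions differ by the
curvilinear kinetic coupling.

A dipole surface is the point-charge sum μ = Σ q_i x_i; no polarization or
many-body dipole terms (a deliberate non-goal).

## Diffusion Monte Carlo

An ensemble of walkers (default: all initialized at the global minimum)
evolves in imaginary time with per-atom diffusion constant D_i = 1/(2 m_i)
and a branching/weighting term driven by E(R) − V_ref.

* **Weighting.** Discrete mode replicates walkers with expected
  multiplicity exp(−(E−V_ref)Δτ) (copies capped at 3 per step, a standard
  guard that affects only transients). Continuous mode keeps the
  population fixed and multiplies per-walker weights; walkers below weight
  0.01 are removed and the same number of highest-weight walkers split in
  two at half weight, conserving total weight. The protocol-level
  propagation uses the midpoint rule for the branching energy,
  E = ½(E(x_prev) + E(x_new)), the standard second-order splitting of the
  short-time Green's function; end-point branching carries a first-order
  time-step bias that is visible at Δτ = 1 for unguided runs.
* **Importance sampling.** The guide is the analytic product of ground-state
  Gaussians of the decoupled intramolecular stretch/bend problems (widths
  √(k μ)/ℏ). Guided moves add the drift 2DΔτ∇ln ψ_g and are accepted by a
  Metropolis test on ψ_g² with the drifted-Gaussian transition density, so
  the sampled density is exact regardless of Δτ. Guided branching uses the
  guide's local energy E_L = V + Σ_i (∇_i²S − |∇_i S|²)/(2m_i) (ψ_g = e^−S),
  the form that makes E_L exactly constant when the guide is the exact
  ground state; the engine's closed-form per-atom bond/angle Laplacians are
  finite-difference verified in the tests. E_L branching is the standard importance-sampled choice and the only
  one consistent with the zero-variance property.
* **V_ref update.** The feedback formula is a free implementation choice
  (only the long-time average matters); we use the weighted ensemble
  energy minus a logarithmic population-control term,
  V_ref = ⟨E⟩_w − α ln(W/W₀) (continuous) or ⟨E⟩ − α(N−N₀)/N₀ (discrete),
  with gain α = 1/Δτ. The ZPE estimate is the V_ref average over the
  collection window.
* **Protocol.** Default full-scale protocol: Δτ = 1, τ_total = 50 000,
  τ_eq = 30 000 with the first 50 steps diffusion-only, 20 snapshots at
  even intervals over the final 20 000. Imaginary times are in atomic
  units (the natural unit system under ℏ = 1; Δτ is configurable).
* **Descendant weighting.** Each snapshot is re-propagated for τ_DW
  (default 1000) in N_DW = 3 independent repetitions; an ancestor index is
  attached at the start and inherited through resampling, and
  W_DW = (summed final weights of the ancestor's descendants)/(ancestor
  weight at the start) — the weight-ratio definition made well-defined
  through resampling events. Amplitude (|ψ|²) expectations weight walkers
  by W_DW·w; wave-function-level expectations weight by w/ψ_g.

## GSPA spectral analysis

All walkers from all snapshots are concatenated, Eckart-aligned to the
global minimum (mass-weighted Kabsch rotation, which satisfies the Eckart
cross-product condition exactly), and projected on a redundant descriptor
basis:

* **r_N2** — all OH bond lengths and HOH angles plus every intermolecular
  atom-pair distance;
* **r_N3** — r_N2 plus intermolecular angles. "Intermolecular angle"
  admits several readings (all scale cubically); the package enumerates,
  behind the `inter_angle_rule` flag: triples with one covalent O–H arm
  and one intermolecular arm (default — the standard interfragment
  bending construction, containing every hydrogen-bond angle O–H···O and
  O···H–O), triples whose two arms are both intermolecular contacts, any
  triple not contained in one monomer, or strictly three-monomer triples.

The Wilson Jacobian B (analytic rows for distances and angles,
finite-difference verified) is ensemble-averaged with amplitude weights,
along with the kinetic kernel ⟨B Λ Bᵀ⟩ (Λ = diag(1/m)). Two reductions to
3N−6 coordinates:

* **standard** — leading left singular vectors of ⟨B⟩;
* **chemically informed** — the K = 3 n_mol intramolecular rows are pinned
  as exact coordinates (identity block); the intermolecular rows are
  projected onto the orthogonal complement of the intramolecular row space
  (QR of ⟨B⟩_fixedᵀ) and reduced by SVD to the remaining 3N−6−K columns.

Column signs follow a deterministic convention (largest-magnitude entry
positive, ties to the lowest row) so U is reproducible across platforms;
degenerate singular values at the retained cut trigger a warning and are
broken by column order.

Modes are eigenvectors P of ⟨G⟩^(−1/2) C ⟨G⟩^(−1/2), with C the weighted
covariance of q = Uᵀr and ⟨G⟩ = Uᵀ⟨BΛBᵀ⟩U. The mass-weighted mode
coordinates are computed as v_MW = Pᵀ⟨G⟩^(−1/2)(q − ⟨q⟩): the
mass-weighting is applied *before* the PCA rotation. (Some presentations
write the composition in the opposite order; only this order makes the
mode covariance diag(λ), gives each mode unit effective mass — the
assumption behind the kinetic-gap estimator — and, on a solvable harmonic
test problem, recovers the exact frequencies, so it is adopted
throughout.) Modes are indexed by descending covariance eigenvalue, which
ranks them more stably than frequency.

Fundamentals insert one node: f_l = v_MW,l − ⟨v_MW,l⟩ (centered across the
concatenated ensemble). The excitation energy is the sum of a potential
gap ΔV_l = ⟨V f²⟩/⟨f²⟩ − ⟨V⟩₀ and a kinetic gap
ΔT_l = (ℏ²/2)⟨f²⟩/(⟨f⁴⟩−⟨f²⟩²), an identity-by-construction split
(ν = ΔV + ΔT exactly). The kinetic estimator is exact for Gaussian
amplitudes and approximate otherwise; no higher-order correction is
attempted. A mode whose excitation-moment denominator is not positive
(insufficient sampling) is flagged degenerate and reports no frequency.
The variance-only effective-harmonic estimate ν_eff = ℏ/(2λ) is exposed
alongside for comparison; on a Morse oscillator the amplitude-based
fundamental is verifiably closer to the exact anharmonic gap.

Reported named modes (the in-phase bend, the in-phase symmetric stretch)
are identified by eigenvector sign coherence — the mode maximizing
|Σ_j T_lj| over its descriptor class — not by picking the lowest
frequency of a near-degenerate pair: under finite sampling the minimum of
two noisy, nearly equal frequencies is biased low by an order-statistic
effect, while the coherent sum is a property of the eigenvector and
carries no such bias. When two analyses of one ensemble are compared
(e.g. across redundant bases), modes are paired by a global assignment
maximizing the overlap of their T-rows on the shared descriptors. The
hydrogen-bonded donor OH mode of the standard reduction is identified as
the mode holding the largest squared weight of the donor OH descriptor
(its overall character is intermolecular-dominated, which is the
imbalance at issue).

IR intensities are I_l ∝ ν_l‖⟨μf⟩‖²/(⟨f²⟩⟨0|0⟩) with ⟨0|0⟩ the total
weight, reported relative to the strongest band (the model fixes no
absolute scale). Spectra are rendered as sticks plus a cosmetic Gaussian
broadening (FWHM 10 cm⁻¹ default; never asserted).

Character diagnostics come from T = PᵀUᵀ: per-class totals
χ = Σ T², imbalance factors CIF = (χ−K_class)/K_class (identically zero
for every class under the chemically informed scheme — a property the
tests assert at machine precision for arbitrary ensembles), the
inter→intra mixing fraction, and per-mode characters χ_l used for
automatic labeling. CIFs are invariant under Pᵀ (asserted), so imbalance
is a property of the reduction alone.

## Landscape and classification

Isomer search combines Metropolis Monte Carlo (per-atom Gaussian moves of
0.08 Å at an annealed temperature, default 400 K with factor 0.995/step)
with periodic BFGS quenches on the analytic gradient; distinct minima are
deduplicated by energy pre-filter plus Eckart-aligned mass-weighted RMSD
over atom-labeling permutation variants (the H-swap × monomer-relabeling
group, identity first). The match tolerance is 10⁻³ Å — far below
inter-minimum separations, above optimizer noise ("numerically zero").
Walker classification quenches a walker and assigns the first
(isomer, permutation) variant matching below tolerance; unmatched walkers
are counted as unclassified.

Not every label exchange is a permutation *event*. On this surface the
exchange of the two free hydrogens of an H-bond acceptor is realized by an
internal rotation whose barrier (0.13 kcal/mol for the dimer, measured
along the rigid rotation path — below the wag zero-point level) cannot
confine the amplitude: the sampled ground state delocalizes freely over
the two labelings, and quenches split between them. Such
topology-preserving exchanges belong to one vibrational well. The
package therefore (i) reports the *permutation probability* as the
probability-amplitude (|ψ|², descendant-weighted) share of
topology-**changing** exchanges only — those that move a donating
hydrogen or relabel monomers, which carry real barriers — and (ii)
canonicalizes the facile within-monomer hydrogen labels before any
spectral analysis ("walker sorting": per monomer, the H assignment
minimizing the Eckart-aligned mass-weighted distance to the reference,
iterated with the alignment). Without this canonicalization the
descriptor distributions of the soft intermolecular coordinates are
multimodal and the amplitude moments behind the kinetic-gap estimator are
corrupted — an effect directly observable as collapsing ΔT values on
unsorted ensembles. Basin-of-attraction classification can
misassign walkers near basin boundaries; the package therefore also emits
the O–O distance-distribution diagnostic per class, and does not invent a
geometric classifier. Transition-state finding (NEB) is out of scope.

## Reverse mapping

The forward map x → v_MW is rigid-motion invariant (all descriptors are),
so the reverse map minimizes err(x) = ‖v_MW(x) − target‖² by BFGS in plain
Cartesian coordinates with the analytic Jacobian Pᵀ⟨G⟩^(−1/2)UᵀB(x),
converging to err < 10⁻⁸, and Eckart-aligns the solution to the reference
once at the end — equivalent to per-iterate alignment for a
gauge-invariant objective, and simpler. Mode animations displace v_MW in
steps of δ = 0.25√λ_l (a quarter of the mode's ground-state spread;
configurable) for k_max = 8
steps each way, warm-starting every frame from its neighbor, starting
from the equilibrium solution v_MW⁻¹(0, x_GM).

## Problem sizes used in the shipped checks

The test suite and acceptance script run desk-scale versions of the full-scale
protocol, chosen to keep the whole suite within a coffee break while
leaving the stochastic tolerances meaningful: dimer spectroscopy uses
N_w = 2000–2500 with τ = 20 000 (τ_eq = 10 000), τ_DW = 1000, N_DW = 3 and
two concatenated repetitions (full scale: N_w = 10 000, τ = 50 000, five
repetitions); the guided/unguided comparison uses N_w = 5000 and five
seeds per arm; the trimer check uses N_w = 1500, τ = 10 000, τ_DW = 500;
the hexamer localization check uses N_w = 400, τ = 3000. The `scale`
knob of `RunConfig` reproduces these reductions declaratively.

## What the synthetic fixtures do and do not show

All geometries are generated internally (isomer search from random rigid
monomer placements); no external structures enter. The model oscillators
(separable harmonic, Morse) carry closed-form spectra and are the
engine's exactness oracles. A Cartesian-harmonic water-shaped test
Hamiltonian (exact normal modes known) exercises the *entire* curvilinear
analysis chain; it shows the stretch fundamentals recovered to ~0.3% while
the bend carries a percent-level positive offset intrinsic to describing a
rectilinear-harmonic bend through curvilinear internal coordinates — the
corresponding caveat applies to all GSPA bend values on real surfaces.
Passing tests demonstrate correctness of the sampling and analysis
machinery on the stated force field; they do not certify the force field
itself against experimental spectra (the q-SPC/Fw surface is deliberately
simple, and its predictions are red-shifted relative to measured OH
stretches).

## Numerical safeguards

* Coulomb distances are floored at 0.1 Å in batched evaluation (counted,
  never silently) and rejected in the scalar API.
* Near-linear bends (sin θ < 10⁻⁶) have regularized Jacobians; they do not
  occur for equilibrium clusters but can for distorted walkers.
* ⟨G⟩ inverse square roots clamp eigenvalues at a 10⁻¹² relative floor
  (warned).
* Discrete-mode population extinction aborts with a diagnostic rather
  than returning silent garbage.
* Every stochastic test fixes its seed; stochastic assertions use ~3σ
  tolerances.

## Known limitations

* Fundamentals only: no overtones, combination bands, Fermi resonances or
  rotational contours.
* Single fixed-parameter surface; no MB-pol / q-TIP4P/F, no ab initio.
* The kinetic-gap estimator is a Gaussian-moment approximation with no
  stated error model.
* Eckart alignment is unique up to degenerate-inertia cases (flagged by
  construction of the Kabsch problem); linear reference structures are not
  supported.
* The printed-source bend harmonic admits several computational readings
  that disagree by a few percent; the package exposes both the local-mode
  and Hessian definitions rather than privileging either.
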