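"""Diffusion Monte Carlo engine.

Imaginary-time propagation of an ensemble of walkers whose density converges
to the nuclear ground state.  The engine is generic: a *problem* object
provides per-degree-of-freedom masses and a batched ``potential``; if it also
provides ``log_guide`` / ``grad_log_guide`` / ``local_energy`` the run can be
guided (drift + Metropolis acceptance, branching on the guide's local
energy).  Everything is in atomic units (hbar = 1, default time step 1).

Two weighting schemes are implemented:

* discrete — walkers branch into an integer number of copies with expected
  multiplicity exp(-(E - V_ref) dtau);
* continuous — a fixed population carries multiplicative weights; walkers
  whose weight falls below a threshold (default 0.01) are removed and the
  same number of highest-weight walkers are split in two at half weight,
  conserving total weight.

Descendant weighting re-propagates a snapshot for an extra time tau_DW and
credits each ancestor with the summed final weight of its descendants
relative to its weight at the start (continuous), or its descendant count
(discrete).  Expectation values use the weights W_DW * w; wave-function-level
("psi") expectations instead use w / psi_guide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "DMCConfig", "Snapshot", "DMCResult", "run_dmc", "descendant_weights",
    "expectation", "effective_sample_fraction", "PopulationExtinctionError",
]


class PopulationExtinctionError(RuntimeError):
    """Discrete-weighting population died out."""


@runtime_checkable
class DMCProblem(Protocol):
    """Batched problem interface; coordinates are flat (n_walkers, dof)."""

    masses: np.ndarray  # (dof,) in electron masses

    def potential(self, x: np.ndarray) -> np.ndarray: ...


@dataclass
class DMCConfig:
    """Run protocol parameters (imaginary times in atomic units).

    The defaults follow the full-scale study protocol: total propagation
    tau_total = 50000 with tau_eq = 30000 of equilibration, branching
    disabled for the first 50 steps, 20 snapshots over the collection
    window, and descendant weighting with tau_dw = 1000 averaged over
    n_dw = 3 repetitions.
    """

    n_walkers: int = 2000
    d_tau: float = 1.0
    tau_total: float = 50_000.0
    tau_eq: float = 30_000.0
    diffusion_only_steps: int = 50
    n_snapshots: int = 20
    weighting: str = "continuous"       # "continuous" | "discrete"
    guided: bool = True
    resample_threshold: float = 0.01
    tau_dw: float = 1000.0
    n_dw: int = 3
    seed: int | np.random.SeedSequence = 0
    vref_damping: float | None = None   # population-control gain; default 1/d_tau
    max_branch: int = 3                 # discrete-mode copy cap per step
    dw_checkpoints: tuple[float, ...] = ()  # extra tau_DW values to record

    def __post_init__(self) -> None:
        if self.n_walkers < 2:
            raise ValueError("need at least two walkers")
        if not (0.0 < self.resample_threshold < 1.0):
            raise ValueError("resample threshold must lie in (0, 1)")
        if self.tau_eq >= self.tau_total:
            raise ValueError("tau_eq must be smaller than tau_total")
        if self.weighting not in ("continuous", "discrete"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    @property
    def alpha(self) -> float:
        return self.vref_damping if self.vref_damping is not None else 1.0 / self.d_tau


@dataclass
class Snapshot:
    """A wave-function sample: coordinates, weights, descendant weights."""

    x: np.ndarray                      # (n, dof)
    w: np.ndarray                      # continuous weights (ones in discrete mode)
    w_dw: np.ndarray | None = None     # descendant weights (None before DW)
    log_guide: np.ndarray | None = None
    tau: float = 0.0
    dw_profile: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def amplitude_weights(self) -> np.ndarray:
        """|psi|^2 sampling weights W_DW * w (Monte Carlo expectation weights)."""
        if self.w_dw is None:
            raise ValueError("descendant weights not computed for this snapshot")
        return self.w_dw * self.w

    @property
    def psi_weights(self) -> np.ndarray:
        """Wave-function-level weights w / psi_guide (w if unguided)."""
        if self.log_guide is None:
            return self.w
        return self.w * np.exp(-self.log_guide)


@dataclass
class DMCResult:
    vref: np.ndarray             # V_ref per iteration (hartree)
    taus: np.ndarray             # imaginary time per iteration
    zpe: float                   # mean V_ref over the collection window
    snapshots: list[Snapshot]
    acceptance_rate: float       # guided runs; nan otherwise
    config: DMCConfig

    def zpe_error_estimate(self, n_blocks: int = 10) -> float:
        """Blocked standard error of the collection-window V_ref mean."""
        v = self.vref[self.taus > self.config.tau_eq]
        blocks = np.array_split(v, n_blocks)
        means = np.array([b.mean() for b in blocks])
        return float(means.std(ddof=1) / np.sqrt(n_blocks))


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------


def diffusion_step(x: np.ndarray, masses: np.ndarray, d_tau: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Free diffusion: Gaussian displacement with variance 2 D_i dtau,
    D_i = 1/(2 m_i) (hbar = 1)."""
    sigma = np.sqrt(d_tau / masses)
    return x + rng.normal(size=x.shape) * sigma


def drift_metropolis_step(x: np.ndarray, problem, d_tau: float,
                          rng: np.random.Generator,
                          grad_cache: np.ndarray | None = None,
                          log_cache: np.ndarray | None = None):
    """Importance-sampled move: drift 2 D grad(log psi_g) dtau + diffusion,
    accepted per walker with the standard reversible-transition Metropolis
    ratio on psi_g^2.  Returns (x_new, accepted_mask, grad_new, log_new)."""
    d = 1.0 / (2.0 * problem.masses)
    var = 2.0 * d * d_tau
    g0 = problem.grad_log_guide(x) if grad_cache is None else grad_cache
    l0 = problem.log_guide(x) if log_cache is None else log_cache
    drift0 = 2.0 * d * d_tau * g0
    prop = x + drift0 + rng.normal(size=x.shape) * np.sqrt(var)

    g1 = problem.grad_log_guide(prop)
    l1 = problem.log_guide(prop)
    drift1 = 2.0 * d * d_tau * g1
    # log T(x->x') and T(x'->x) with the drifted Gaussian transition density
    fwd = -np.sum((prop - x - drift0) ** 2 / (2.0 * var), axis=1)
    bwd = -np.sum((x - prop - drift1) ** 2 / (2.0 * var), axis=1)
    log_acc = 2.0 * (l1 - l0) + bwd - fwd
    accept = np.log(rng.random(x.shape[0])) < log_acc

    x_new = np.where(accept[:, None], prop, x)
    g_new = np.where(accept[:, None], g1, g0)
    l_new = np.where(accept, l1, l0)
    return x_new, accept, g_new, l_new


def branch_discrete(x, energy, v_ref, d_tau, rng, ancestors=None, max_branch=3):
    """Integer branching: copies = floor(m) + Bernoulli(frac m),
    m = exp(-(E - V_ref) dtau), capped at ``max_branch``.
    Returns (x, ancestors, idx) with ``idx`` the parent index of each copy."""
    m = np.exp(-(energy - v_ref) * d_tau)
    n_copy = np.minimum(np.floor(m) + (rng.random(m.shape) < (m % 1.0)), max_branch)
    n_copy = n_copy.astype(int)
    if n_copy.sum() == 0:
        raise PopulationExtinctionError(
            "all walkers died; raise n_walkers or check V_ref feedback")
    idx = np.repeat(np.arange(x.shape[0]), n_copy)
    return x[idx], (ancestors[idx] if ancestors is not None else None), idx


def reweight_continuous(w, energy, v_ref, d_tau):
    """Multiplicative weight update w <- w exp(-(E - V_ref) dtau)."""
    return w * np.exp(-(energy - v_ref) * d_tau)


def resample(x, w, threshold, ancestors=None):
    """Remove walkers with w < threshold; split the same number of
    highest-weight walkers at half weight (total weight conserved)."""
    low = np.flatnonzero(w < threshold)
    if low.size == 0:
        return x, w, ancestors
    order = np.argsort(w)
    high = order[::-1][: low.size]
    x = x.copy()
    w = w.copy()
    x[low] = x[high]
    w[high] *= 0.5
    w[low] = w[high]
    if ancestors is not None:
        ancestors = ancestors.copy()
        ancestors[low] = ancestors[high]
    return x, w, ancestors


def update_vref(energy, w, alpha, total0, weighting, d_tau):
    """V_ref = weighted <E> minus population-control feedback."""
    if weighting == "continuous":
        total = w.sum()
        return float(np.average(energy, weights=w) - alpha * np.log(total / total0))
    n = energy.shape[0]
    return float(energy.mean() - alpha * (n - total0) / total0)


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------


def _walker_energy(problem, x, guided):
    if guided:
        return problem.local_energy(x)
    return problem.potential(x)


def _resample_idx(w: np.ndarray, threshold: float):
    """Index map implementing the remove-and-split rule; returns (idx, w_new)."""
    low = np.flatnonzero(w < threshold)
    idx = np.arange(w.shape[0])
    if low.size == 0:
        return idx, w
    order = np.argsort(w)
    high = order[::-1][: low.size]
    idx[low] = high
    w = w.copy()
    w[high] *= 0.5
    w[low] = w[high]
    return idx, w


def _step_eval(problem, x):
    """(V, log psi_g, grad log psi_g, E_L - V) via the problem's fused path
    or assembled from its parts."""
    if hasattr(problem, "step_eval"):
        return problem.step_eval(x)
    v = problem.potential(x)
    return (v, problem.log_guide(x), problem.grad_log_guide(x),
            problem.local_energy(x) - v)


def _propagate(problem, x, w, ancestors, n_steps, config, rng, v_ref,
               vref_out=None, diffusion_only=0, accept_stats=None,
               checkpoints=None, checkpoint_times=()):
    """Advance the ensemble ``n_steps``; mutates nothing, returns new state.

    Guided runs keep one fused (V, log psi_g, grad, E_L-V) evaluation per
    step: the proposal is evaluated once and the cached state is merged or
    reindexed through acceptance, resampling and branching.
    """
    d_tau = config.d_tau
    guided = config.guided
    total0 = float(config.n_walkers)
    d = 1.0 / (2.0 * problem.masses)
    var = 2.0 * d * d_tau
    sqrt_var = np.sqrt(var)
    state = None  # (v, log_g, grad, kin) aligned with x
    e_prev = None  # previous-step energies for the midpoint branching rule
    for step in range(n_steps):
        if step < diffusion_only:
            x = diffusion_step(x, problem.masses, d_tau, rng)
            state = None
            e_prev = None
            if vref_out is not None:
                v_ref = float(np.average(problem.potential(x), weights=w))
                vref_out.append(v_ref)
            continue
        if guided:
            if state is None:
                x = np.ascontiguousarray(x)
                state = tuple(np.ascontiguousarray(a)
                              for a in _step_eval(problem, x))
            if getattr(problem, "has_fused_step", False):
                noise = rng.standard_normal(x.shape)
                log_u = np.log(rng.random(x.shape[0]))
                frac = problem.fused_step(x, state, noise, log_u, d_tau)
                if accept_stats is not None:
                    accept_stats.append(frac)
                e = state[0] + state[3]
            else:
                v0, l0, g0, k0 = state
                noise = rng.standard_normal(x.shape)
                prop = x + var * g0 + noise * sqrt_var  # drift 2 D dt grad ln g
                v1, l1, g1, k1 = _step_eval(problem, prop)
                fwd = 0.5 * np.einsum("nd,nd->n", noise, noise)
                bwd = np.einsum("nd,d->n", (x - prop - var * g1) ** 2,
                                0.5 / var)
                log_acc = 2.0 * (l1 - l0) - bwd + fwd
                acc = np.log(rng.random(x.shape[0])) < log_acc
                if accept_stats is not None:
                    accept_stats.append(acc.mean())
                rej = np.flatnonzero(~acc)
                if rej.size:  # acceptance is high; copy back rejected rows
                    prop[rej] = x[rej]
                    v1[rej], l1[rej], g1[rej], k1[rej] = (
                        v0[rej], l0[rej], g0[rej], k0[rej])
                x = prop
                state = (v1, l1, g1, k1)
                e = v1 + k1
        else:
            x = diffusion_step(x, problem.masses, d_tau, rng)
            e = problem.potential(x)

        # midpoint (symmetric) branching energy: second order in d_tau
        e_branch = e if e_prev is None else 0.5 * (e_prev + e)
        if config.weighting == "continuous":
            w = reweight_continuous(w, e_branch, v_ref, d_tau)
            if np.any(w < config.resample_threshold):
                idx, w = _resample_idx(w, config.resample_threshold)
                x, e = x[idx], e[idx]
                if ancestors is not None:
                    ancestors = ancestors[idx]
                if state is not None:
                    state = tuple(a[idx] for a in state)
        else:
            x, ancestors, idx = branch_discrete(
                x, e_branch, v_ref, d_tau, rng, ancestors, config.max_branch)
            w = np.ones(x.shape[0])
            e = e[idx]
            if state is not None:
                state = tuple(a[idx] for a in state)
        e_prev = e
        v_ref = update_vref(e, w, config.alpha, total0, config.weighting, d_tau)
        if vref_out is not None:
            vref_out.append(v_ref)
        if checkpoints is not None:
            tau_now = (step + 1) * d_tau
            for t in checkpoint_times:
                if abs(tau_now - t) < 0.5 * d_tau and t not in checkpoints:
                    checkpoints[t] = (x.copy(), w.copy(),
                                      ancestors.copy() if ancestors is not None else None)
    return x, w, ancestors, v_ref


def descendant_weights(problem, snapshot: Snapshot, config: DMCConfig,
                       rng: np.random.Generator, v_ref: float) -> Snapshot:
    """Propagate a snapshot tau_dw further (n_dw independent repetitions) and
    attach per-walker descendant weights W_DW = w(tau+tau_dw)/w(tau), with
    descendants credited to ancestors through the resampling bookkeeping.
    Intermediate checkpoint profiles are recorded for the requested
    ``config.dw_checkpoints``."""
    n = snapshot.x.shape[0]
    n_steps = int(round(config.tau_dw / config.d_tau))
    times = tuple(t for t in config.dw_checkpoints if t < config.tau_dw)
    acc = np.zeros(n)
    profile = {t: np.zeros(n) for t in times}
    for _ in range(max(config.n_dw, 1)):
        checkpoints: dict = {}
        x, w, anc, _ = _propagate(
            problem, snapshot.x.copy(), snapshot.w.copy(), np.arange(n),
            n_steps, config, rng, v_ref, checkpoints=checkpoints,
            checkpoint_times=times)
        acc += _credit(anc, w, n, snapshot.w, config.weighting)
        for t, (xc, wc, ac) in checkpoints.items():
            profile[t] += _credit(ac, wc, n, snapshot.w, config.weighting)
    acc /= max(config.n_dw, 1)
    snapshot.w_dw = acc
    snapshot.dw_profile = {t: p / max(config.n_dw, 1) for t, p in profile.items()}
    return snapshot


def _credit(ancestors, w_final, n, w_start, weighting):
    summed = np.bincount(ancestors, weights=w_final, minlength=n)
    if weighting == "continuous":
        return summed / w_start
    return summed  # descendant count


def run_dmc(problem, initial: np.ndarray, config: DMCConfig,
            initial_fractions: Sequence[float] | None = None) -> DMCResult:
    """Full protocol: initialization, diffusion-only burn-in, equilibration,
    snapshot collection with descendant weighting, ZPE from the collection
    window's V_ref average.

    ``initial`` is one flat geometry (dof,) or a stack (k, dof) distributed
    across walkers according to ``initial_fractions`` (equal shares by
    default), mirroring single-minimum or isomer-mixture initialization.
    """
    rng = np.random.default_rng(config.seed)
    initial = np.atleast_2d(np.asarray(initial, dtype=float))
    k = initial.shape[0]
    frac = (np.full(k, 1.0 / k) if initial_fractions is None
            else np.asarray(initial_fractions, dtype=float))
    counts = np.round(frac / frac.sum() * config.n_walkers).astype(int)
    counts[-1] = config.n_walkers - counts[:-1].sum()
    x = np.repeat(initial, counts, axis=0)
    w = np.ones(config.n_walkers)

    guided = config.guided
    e = _walker_energy(problem, x, guided)
    v_ref = float(np.average(e, weights=w))

    n_eq = int(round(config.tau_eq / config.d_tau))
    n_total = int(round(config.tau_total / config.d_tau))
    n_coll = n_total - n_eq

    vref_trace: list[float] = []
    accept: list[float] = []
    x, w, _, v_ref = _propagate(
        problem, x, w, None, n_eq, config, rng, v_ref, vref_out=vref_trace,
        diffusion_only=config.diffusion_only_steps, accept_stats=accept)

    # snapshots at even intervals over the collection window
    snap_steps = np.linspace(n_coll / config.n_snapshots, n_coll,
                             config.n_snapshots).round().astype(int)
    snapshots: list[Snapshot] = []
    done = 0
    for target in snap_steps:
        x, w, _, v_ref = _propagate(
            problem, x, w, None, target - done, config, rng, v_ref,
            vref_out=vref_trace, accept_stats=accept)
        done = target
        log_g = problem.log_guide(x) if guided else None
        snap = Snapshot(x=x.copy(), w=w.copy(), log_guide=log_g,
                        tau=config.tau_eq + done * config.d_tau)
        if config.tau_dw > 0:
            descendant_weights(problem, snap, config, rng, v_ref)
        else:
            snap.w_dw = np.ones(x.shape[0])
        snapshots.append(snap)

    vref = np.asarray(vref_trace)
    taus = np.arange(1, vref.size + 1) * config.d_tau
    zpe = float(vref[taus > config.tau_eq].mean())
    return DMCResult(
        vref=vref, taus=taus, zpe=zpe, snapshots=snapshots,
        acceptance_rate=float(np.mean(accept)) if accept else float("nan"),
        config=config)


# ---------------------------------------------------------------------------
# expectations and diagnostics
# ---------------------------------------------------------------------------


def expectation(snapshots: Sequence[Snapshot],
                observable: Callable[[np.ndarray], np.ndarray] | np.ndarray,
                mode: str = "amplitude"):
    """Weighted ensemble average of an observable over one or more snapshots.

    ``mode='amplitude'`` uses W_DW * w (probability-amplitude expectations);
    ``mode='wavefunction'`` uses w / psi_guide (psi-level projections).
    ``observable`` is a callable on (n, dof) coordinates or a pre-evaluated
    array aligned with the concatenated walkers.
    """
    snapshots = list(snapshots)
    if mode == "amplitude":
        wts = np.concatenate([s.amplitude_weights for s in snapshots])
    elif mode == "wavefunction":
        wts = np.concatenate([s.psi_weights for s in snapshots])
    else:
        raise ValueError(f"unknown expectation mode {mode!r}")
    if callable(observable):
        vals = np.concatenate([np.asarray(observable(s.x)) for s in snapshots])
    else:
        vals = np.asarray(observable)
    return np.einsum("n,n...->...", wts, vals) / wts.sum()


def effective_sample_fraction(snapshot: Snapshot, tau_dw: float | None = None,
                              threshold: float = 1e-7) -> float:
    """Fraction of walkers with numerically nonzero descendant weight."""
    if tau_dw is not None and snapshot.dw_profile and tau_dw in snapshot.dw_profile:
        w_dw = snapshot.dw_profile[tau_dw]
    else:
        w_dw = snapshot.w_dw
    return float(np.mean(w_dw > threshold))
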