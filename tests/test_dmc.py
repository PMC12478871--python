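"""DMC engine: elementary steps, weighting schemes, descendant weighting."""

from __future__ import annotations

import numpy as np
import pytest

from aquavib.dmc import (DMCConfig, PopulationExtinctionError, Snapshot,
                         branch_discrete, descendant_weights, diffusion_step,
                         drift_metropolis_step, effective_sample_fraction,
                         expectation, resample, reweight_continuous, run_dmc,
                         update_vref)
from aquavib.models import HarmonicOscillator


class TestDiffusion:
    def test_zero_time_step_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 4))
        np.testing.assert_array_equal(
            diffusion_step(x, np.ones(4), 0.0, rng), x)

    def test_variance_growth_follows_diffusion_law(self):
        rng = np.random.default_rng(1)
        masses = np.array([1.0, 4.0])
        x = np.zeros((20000, 2))
        n, dt = 10, 0.3
        for _ in range(n):
            x = diffusion_step(x, masses, dt, rng)
        # var = 2 D dtau n = dtau n / m per dof
        expected = dt * n / masses
        assert np.allclose(x.var(axis=0), expected, rtol=0.05)

    def test_heavier_dof_diffuses_less(self):
        rng = np.random.default_rng(2)
        m_ratio = 15.999 / 1.008
        x = np.zeros((40000, 2))
        for _ in range(5):
            x = diffusion_step(x, np.array([1.0, m_ratio]), 0.5, rng)
        assert x.var(axis=0)[0] / x.var(axis=0)[1] == pytest.approx(
            m_ratio, rel=0.05)


class TestDriftMetropolis:
    def test_constant_guide_reduces_to_diffusion(self):
        class Flat:
            masses = np.ones(3)

            def log_guide(self, x):
                return np.zeros(x.shape[0])

            def grad_log_guide(self, x):
                return np.zeros_like(x)

        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        x = np.random.default_rng(0).normal(size=(100, 3))
        x1, acc, *_ = drift_metropolis_step(x.copy(), Flat(), 0.1, rng1)
        x2 = diffusion_step(x.copy(), np.ones(3), 0.1, rng2)
        assert acc.all()
        np.testing.assert_allclose(x1, x2)

    def test_stationary_density_is_guide_squared(self):
        """With the exact HO ground state as guide, drift+Metropolis alone
        samples psi_g^2 — a Gaussian with variance hbar/(2 m w)."""
        ho = HarmonicOscillator([1.3], [2.0])
        rng = np.random.default_rng(4)
        x = np.zeros((20000, 1))
        for _ in range(300):
            x, *_ = drift_metropolis_step(x, ho, 0.1, rng)
        sigma2 = ho.ground_state_variance()[0]  # psi^2 variance = sigma^2/...
        # psi_g^2 has variance hbar/(2 m w)
        assert x.var() == pytest.approx(sigma2, rel=0.05)
        assert abs(x.mean()) < 0.02

    def test_detailed_balance_on_two_states(self):
        """pi(x) T(x->y) A(x->y) = pi(y) T(y->x) A(y->x) for the drifted
        Gaussian kernel with pi = psi_g^2, checked numerically at two
        arbitrary points."""
        ho = HarmonicOscillator([0.7], [1.5])
        d_tau = 0.2
        d = 1.0 / (2.0 * ho.masses[0])
        var = 2 * d * d_tau

        def t_log(a, b):
            drift = var * ho.grad_log_guide(np.array([[a]]))[0, 0]
            return -((b - a - drift) ** 2) / (2 * var)

        def pi_log(a):
            return 2 * ho.log_guide(np.array([[a]]))[0]

        xa, xb = 0.37, -0.81
        ratio = (pi_log(xa) + t_log(xa, xb)) - (pi_log(xb) + t_log(xb, xa))
        acc_fwd = min(0.0, -ratio)   # log acceptance x_a -> x_b
        acc_bwd = min(0.0, ratio)
        lhs = pi_log(xa) + t_log(xa, xb) + acc_fwd
        rhs = pi_log(xb) + t_log(xb, xa) + acc_bwd
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestBranching:
    def test_neutral_potential_keeps_population(self):
        rng = np.random.default_rng(5)
        x = np.zeros((5000, 1))
        e = np.zeros(5000)
        x2, _, idx = branch_discrete(x, e, 0.0, 1.0, rng)
        assert x2.shape[0] == 5000

    def test_exact_factor_two_duplicates(self):
        rng = np.random.default_rng(6)
        x = np.array([[1.0]])
        e = np.array([-np.log(2.0)])  # exp(-(E-0)*1) = 2 exactly
        x2, _, idx = branch_discrete(x, e, 0.0, 1.0, rng)
        assert x2.shape[0] == 2

    def test_mean_growth_matches_exponential(self):
        rng = np.random.default_rng(7)
        e = np.full(20000, -0.3)
        x = np.zeros((20000, 1))
        x2, *_ = branch_discrete(x, e, 0.0, 1.0, rng)
        assert x2.shape[0] / 20000 == pytest.approx(np.exp(0.3), rel=0.02)

    def test_extinction_raises(self):
        rng = np.random.default_rng(8)
        e = np.full(10, 50.0)
        with pytest.raises(PopulationExtinctionError):
            branch_discrete(np.zeros((10, 1)), e, 0.0, 1.0, rng)


class TestContinuousWeighting:
    def test_multiplicative_update(self):
        w = np.array([1.0, 0.5])
        e = np.array([0.2, -0.1])
        np.testing.assert_allclose(
            reweight_continuous(w, e, 0.0, 1.0),
            w * np.exp(-e))

    def test_resampling_rule_conserves_weight_and_count(self):
        """A walker below threshold is replaced by a half-weight copy of the
        heaviest walker, whose own weight is halved."""
        x = np.arange(10, dtype=float)[:, None]
        w = np.ones(10)
        w[3] = 0.005
        w[7] = 3.0
        x2, w2, _ = resample(x, w, 0.01)
        assert x2.shape[0] == 10
        assert w2.sum() == pytest.approx(w.sum() - 0.005 + 1.5 + 1.5 - 3.0)
        assert x2[3, 0] == 7.0 and w2[3] == 1.5 and w2[7] == 1.5

    def test_no_resampling_above_threshold(self):
        x = np.arange(4, dtype=float)[:, None]
        w = np.array([0.5, 1.0, 2.0, 0.02])
        x2, w2, _ = resample(x, w, 0.01)
        np.testing.assert_array_equal(x2, x)
        np.testing.assert_array_equal(w2, w)

    def test_repeated_resampling_bounds_weight_ratio(self):
        ho = HarmonicOscillator([1.0])
        cfg = DMCConfig(n_walkers=500, d_tau=0.1, tau_total=60, tau_eq=30,
                        n_snapshots=2, tau_dw=0, guided=False, seed=9)
        res = run_dmc(ho, np.zeros(1), cfg)
        for s in res.snapshots:
            assert s.w.max() / s.w.min() < 1e4


class TestVref:
    def test_on_target_population_gives_plain_average(self):
        e = np.array([0.1, 0.3])
        w = np.ones(2)
        assert update_vref(e, w, 1.0, 2.0, "continuous", 1.0) == pytest.approx(0.2)

    def test_constant_potential_converges_to_constant(self):
        ho = HarmonicOscillator([1.0])

        class Const:
            masses = np.ones(1)

            def potential(self, x):
                return np.full(x.shape[0], 0.7)

        cfg = DMCConfig(n_walkers=300, d_tau=0.1, tau_total=40, tau_eq=20,
                        n_snapshots=2, tau_dw=0, guided=False, seed=10)
        res = run_dmc(Const(), np.zeros(1), cfg)
        assert res.zpe == pytest.approx(0.7, abs=1e-6)


class TestFullProtocol:
    @pytest.mark.parametrize("weighting,guided", [
        ("continuous", False), ("discrete", False),
        ("continuous", True), ("discrete", True)])
    def test_harmonic_zpe_recovery(self, weighting, guided):
        ho = HarmonicOscillator([1.0])
        cfg = DMCConfig(n_walkers=2000, d_tau=0.05, tau_total=300, tau_eq=150,
                        n_snapshots=4, tau_dw=0, weighting=weighting,
                        guided=guided, seed=11)
        res = run_dmc(ho, np.zeros(1), cfg)
        tol = 3 * max(res.zpe_error_estimate(), 1e-4)
        assert res.zpe == pytest.approx(0.5, abs=max(tol, 0.01))

    def test_separable_3d_zpe(self):
        ho = HarmonicOscillator([0.8, 1.0, 1.7])
        cfg = DMCConfig(n_walkers=2000, d_tau=0.05, tau_total=300, tau_eq=150,
                        n_snapshots=4, tau_dw=0, guided=True, seed=12)
        res = run_dmc(ho, np.zeros(3), cfg)
        assert res.zpe == pytest.approx(ho.zpe, abs=0.01)

    def test_exact_guide_gives_zero_variance_vref(self):
        ho = HarmonicOscillator([1.0])
        cfg = DMCConfig(n_walkers=500, d_tau=0.05, tau_total=60, tau_eq=30,
                        n_snapshots=2, tau_dw=0, guided=True, seed=13)
        res = run_dmc(ho, np.zeros(1), cfg)
        coll = res.vref[res.taus > cfg.tau_eq]
        assert np.abs(coll - 0.5).max() < 1e-10

    def test_zpe_bias_decreases_with_walker_count(self):
        ho = HarmonicOscillator([1.0])
        biases = []
        for nw in (50, 3200):
            reps = []
            for seed in range(4):
                cfg = DMCConfig(n_walkers=nw, d_tau=0.05, tau_total=240,
                                tau_eq=120, n_snapshots=2, tau_dw=0,
                                guided=False, seed=seed, weighting="continuous")
                reps.append(run_dmc(ho, np.zeros(1), cfg).zpe)
            biases.append(abs(np.mean(reps) - 0.5))
        assert biases[1] < biases[0]

    def test_guided_variance_reduction(self):
        ho = HarmonicOscillator([1.0])
        out = {}
        for guided in (False, True):
            cfg = DMCConfig(n_walkers=1000, d_tau=0.05, tau_total=200,
                            tau_eq=100, n_snapshots=2, tau_dw=0,
                            guided=guided, seed=14)
            res = run_dmc(ho, np.zeros(1), cfg)
            out[guided] = res.vref[res.taus > cfg.tau_eq].var()
        assert out[True] < out[False]

    def test_mixture_initialization_split(self):
        ho = HarmonicOscillator([1.0, 1.0])
        cfg = DMCConfig(n_walkers=100, d_tau=0.05, tau_total=10, tau_eq=5,
                        diffusion_only_steps=0, n_snapshots=1, tau_dw=0,
                        guided=False, seed=15)
        # two starting points, 3:1 split
        res = run_dmc(ho, np.array([[0.0, 0.0], [5.0, 5.0]]), cfg,
                      initial_fractions=[0.75, 0.25])
        assert res.snapshots[0].x.shape[1] == 2


class TestDescendantWeighting:
    def test_zero_tau_dw_gives_unit_weights(self):
        ho = HarmonicOscillator([1.0])
        cfg = DMCConfig(n_walkers=200, d_tau=0.05, tau_total=20, tau_eq=10,
                        n_snapshots=1, tau_dw=0, guided=False, seed=16)
        res = run_dmc(ho, np.zeros(1), cfg)
        np.testing.assert_array_equal(res.snapshots[0].w_dw, 1.0)

    def test_constant_potential_equal_weights(self):
        class Const:
            masses = np.ones(1)

            def potential(self, x):
                return np.full(x.shape[0], 0.3)

        cfg = DMCConfig(n_walkers=100, d_tau=0.1, tau_total=30, tau_eq=10,
                        n_snapshots=1, tau_dw=10, n_dw=1, guided=False, seed=17)
        res = run_dmc(Const(), np.zeros(1), cfg)
        w_dw = res.snapshots[0].w_dw
        np.testing.assert_allclose(w_dw, w_dw[0], rtol=1e-10)

    def test_harmonic_second_moment_from_amplitude(self):
        """<x^2> over |psi_0|^2 = hbar/(2 m w) via descendant weighting."""
        ho = HarmonicOscillator([1.0])
        cfg = DMCConfig(n_walkers=4000, d_tau=0.05, tau_total=400, tau_eq=200,
                        n_snapshots=5, tau_dw=30, n_dw=3, guided=True, seed=18)
        res = run_dmc(ho, np.zeros(1), cfg)
        x2 = expectation(res.snapshots, lambda x: x[:, 0] ** 2, "amplitude")
        assert x2 == pytest.approx(0.5, rel=0.05)


class TestExpectation:
    def test_uniform_weights_reduce_to_plain_mean(self):
        x = np.random.default_rng(0).normal(size=(100, 2))
        s = Snapshot(x=x, w=np.ones(100), w_dw=np.ones(100))
        assert expectation([s], lambda x: x[:, 0]) == pytest.approx(x[:, 0].mean())

    def test_single_nonzero_weight_selects_walker(self):
        x = np.arange(10, dtype=float)[:, None]
        w_dw = np.zeros(10)
        w_dw[4] = 2.0
        s = Snapshot(x=x, w=np.ones(10), w_dw=w_dw)
        assert expectation([s], lambda x: x[:, 0]) == pytest.approx(4.0)

    def test_agreement_with_bruteforce_weighted_sum(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 1))
        w = rng.uniform(0.5, 2.0, 50)
        w_dw = rng.uniform(0.0, 1.0, 50)
        s = Snapshot(x=x, w=w, w_dw=w_dw)
        expected = np.sum(w * w_dw * x[:, 0] ** 2) / np.sum(w * w_dw)
        assert expectation([s], lambda x: x[:, 0] ** 2) == pytest.approx(expected)

    def test_walker_duplication_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 1))
        w = rng.uniform(0.5, 2.0, 30)
        s1 = Snapshot(x=x, w=w, w_dw=np.ones(30))
        s2 = Snapshot(x=np.vstack([x, x]), w=np.concatenate([w / 2, w / 2]),
                      w_dw=np.ones(60))
        f = lambda x: np.abs(x[:, 0])
        assert expectation([s1], f) == pytest.approx(expectation([s2], f))


class TestEffectiveSampleFraction:
    def test_unit_weights_give_one(self):
        s = Snapshot(x=np.zeros((10, 1)), w=np.ones(10), w_dw=np.ones(10))
        assert effective_sample_fraction(s) == 1.0

    def test_monotone_in_tau_dw(self):
        ho = HarmonicOscillator([1.0])
        cfg = DMCConfig(n_walkers=500, d_tau=0.05, tau_total=60, tau_eq=30,
                        n_snapshots=1, tau_dw=30, n_dw=2, guided=False,
                        seed=19, dw_checkpoints=(10.0, 20.0))
        res = run_dmc(ho, np.zeros(1), cfg)
        s = res.snapshots[0]
        fr = [effective_sample_fraction(s, t) for t in (10.0, 20.0, None)]
        assert fr[0] >= fr[1] >= fr[2]


class TestWeightingSchemeAgreement:
    def test_continuous_and_discrete_zpe_indistinguishable(self):
        """Two-sample check on the 1-D oscillator: the weighting scheme does
        not shift the ZPE estimate."""
        ho = HarmonicOscillator([1.0])
        out = {}
        for scheme in ("continuous", "discrete"):
            zpes = []
            for seed in range(5):
                cfg = DMCConfig(n_walkers=600, d_tau=0.05, tau_total=200,
                                tau_eq=100, n_snapshots=2, tau_dw=0,
                                weighting=scheme, guided=False, seed=30 + seed)
                zpes.append(run_dmc(ho, np.zeros(1), cfg).zpe)
            out[scheme] = np.array(zpes)
        pooled = np.sqrt(out["continuous"].var(ddof=1) / 5 +
                         out["discrete"].var(ddof=1) / 5)
        diff = abs(out["continuous"].mean() - out["discrete"].mean())
        assert diff < 3.5 * pooled + 1e-3
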