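"""Redundant bases, Wilson B/G machinery, reductions, CIF diagnostics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquavib import internal_coords as ic
from aquavib import pes
from aquavib.fixtures import make_monomer
from aquavib.units import AMU_TO_ME


def _dimer_ensemble(dimer_catalog, n=12, seed=0, spread=0.06):
    rng = np.random.default_rng(seed)
    x = np.repeat(dimer_catalog.gm.coords_bohr()[None], n, axis=0)
    x += rng.normal(0, spread, x.shape)
    w = rng.uniform(0.5, 2.0, n)
    return x, w


class TestBasisConstruction:
    def test_monomer_has_three_descriptors(self, monomer):
        basis = ic.build_basis(monomer, "N2")
        assert len(basis) == 3
        assert ic.n_fixed(basis) == 3

    def test_dimer_n2_counts(self, dimer_catalog):
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        kinds = [d.kind for d in basis]
        assert len(basis) == 15  # 4 bonds + 2 angles + 9 cross pairs
        assert kinds[:4] == ["oh_bond"] * 4
        assert kinds[4:6] == ["hoh_angle"] * 2
        assert kinds[6:] == ["inter_distance"] * 9

    @pytest.mark.parametrize("n_mol,expected", [(2, 9), (3, 27), (4, 54)])
    def test_intermolecular_distance_scaling(self, params, n_mol, expected):
        # 9 n (n-1) / 2 cross pairs
        rng = np.random.default_rng(1)
        from aquavib.landscape import _random_cluster

        cfg = _random_cluster(n_mol, params, rng)
        basis = ic.build_basis(cfg, "N2")
        n_inter = sum(1 for d in basis if d.kind == "inter_distance")
        assert n_inter == expected

    def test_n3_angle_rules(self, dimer_catalog):
        gm = dimer_catalog.gm
        count = {rule: sum(1 for d in ic.build_basis(gm, "N3", rule)
                           if d.kind == "inter_angle")
                 for rule in ("bonded", "arms", "any", "strict")}
        # bonded: 12 n (n-1) covalent-arm/intermolecular-arm triples
        assert count == {"bonded": 24, "arms": 18, "any": 54, "strict": 0}

    def test_intra_block_leads_ordering(self, trimer_catalog):
        basis = ic.build_basis(trimer_catalog.gm, "N3")
        k = ic.n_fixed(basis)
        assert k == 9
        assert all(d.is_intra for d in basis[:k])
        assert not any(d.is_intra for d in basis[k:])


class TestWilsonB:
    def test_distance_row_closed_form(self, dimer_catalog):
        gm = dimer_catalog.gm
        basis = ic.build_basis(gm, "N2")
        x = gm.coords_bohr()
        b = ic.wilson_b(x, basis)
        d0 = basis[0]  # O-H bond
        a_idx, b_idx = d0.atoms
        u = (x[a_idx] - x[b_idx]) / np.linalg.norm(x[a_idx] - x[b_idx])
        np.testing.assert_allclose(b[0, 3 * a_idx:3 * a_idx + 3], u, atol=1e-12)
        np.testing.assert_allclose(b[0, 3 * b_idx:3 * b_idx + 3], -u, atol=1e-12)
        others = np.delete(np.arange(18).reshape(6, 3),
                           [a_idx, b_idx], axis=0).ravel()
        assert np.abs(b[0, others]).max() == 0.0

    def test_angle_rows_match_finite_differences(self, dimer_catalog):
        gm = dimer_catalog.gm
        basis = ic.build_basis(gm, "N3")
        rng = np.random.default_rng(0)
        x = gm.coords_bohr() + rng.normal(0, 0.05, (6, 3))
        b = ic.wilson_b(x, basis)
        h = 1e-6
        rows = [i for i, d in enumerate(basis) if d.is_angle][:6]
        for row in rows:
            for j in rng.choice(18, 5, replace=False):
                xp, xm = x.ravel().copy(), x.ravel().copy()
                xp[j] += h
                xm[j] -= h
                fd = (ic.evaluate(xp.reshape(6, 3), basis)[row]
                      - ic.evaluate(xm.reshape(6, 3), basis)[row]) / (2 * h)
                assert b[row, j] == pytest.approx(fd, abs=1e-7)

    def test_rows_obey_translational_sum_rule(self, dimer_catalog):
        basis = ic.build_basis(dimer_catalog.gm, "N3")
        x = dimer_catalog.gm.coords_bohr()
        b = ic.wilson_b(x, basis).reshape(len(basis), 6, 3)
        np.testing.assert_allclose(b.sum(axis=1), 0.0, atol=1e-12)


class TestGMatrix:
    def test_monomer_bond_element_is_inverse_reduced_mass(self, monomer, guiding):
        basis = ic.build_basis(monomer, "N2")
        x = monomer.coords_bohr()[None]
        masses = np.repeat(monomer.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, np.ones(1), basis, masses)
        # identity reduction on the 3-descriptor monomer
        red = ic.ReductionU(u=np.eye(3), singular_values=np.ones(3),
                            scheme="standard")
        g = ic.g_matrix(be, red)
        mu_oh_au = guiding.mu_oh * AMU_TO_ME
        assert g.g[0, 0] == pytest.approx(1.0 / mu_oh_au, rel=1e-10)

    def test_vectorized_equals_elementwise_definition(self, dimer_catalog):
        """<G> = U^T <B Lambda B^T> U must equal the element-wise sum
        <sum_k dq_i/dx_k (1/m_k) dq_j/dx_k> computed walker by walker."""
        x, w = _dimer_ensemble(dimer_catalog, n=10)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        red = ic.reduce_standard(be, 12)
        g_fast = (red.u.T @ be.blbt_mean @ red.u)

        g_slow = np.zeros((12, 12))
        for xi, wi in zip(x, w):
            b = ic.wilson_b(xi, basis)
            dq = red.u.T @ b  # dq_i/dx_k
            g_w = np.zeros((12, 12))
            for i in range(12):
                for j in range(12):
                    g_w[i, j] = np.sum(dq[i] * dq[j] / masses)
            g_slow += wi * g_w
        g_slow /= w.sum()
        np.testing.assert_allclose(g_fast, g_slow, atol=1e-12)

    def test_identity_reduction_returns_kernel(self, dimer_catalog):
        x, w = _dimer_ensemble(dimer_catalog, n=5, seed=3)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        red = ic.ReductionU(u=np.eye(15), singular_values=np.ones(15),
                            scheme="standard")
        g = ic.g_matrix(be, red)
        np.testing.assert_allclose(g.g, be.blbt_mean, atol=1e-14)


class TestReductions:
    def test_standard_orthonormal_and_ordered(self, dimer_catalog):
        x, w = _dimer_ensemble(dimer_catalog)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        red = ic.reduce_standard(be, 12)
        np.testing.assert_allclose(red.u.T @ red.u, np.eye(12), atol=1e-10)
        assert np.all(np.diff(red.singular_values) <= 1e-12)

    def test_svd_residual_optimality_spot_check(self, dimer_catalog):
        """The retained left-singular subspace beats a random rank-12
        column subspace at reconstructing <B>."""
        x, w = _dimer_ensemble(dimer_catalog, seed=5)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        red = ic.reduce_standard(be, 12)

        def resid(u):
            return np.linalg.norm(be.b_mean - u @ (u.T @ be.b_mean))

        rng = np.random.default_rng(0)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(15, 12)))
            assert resid(red.u) <= resid(q) + 1e-12

    def test_chem_informed_block_structure(self, dimer_catalog):
        x, w = _dimer_ensemble(dimer_catalog, seed=7)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        red = ic.reduce_chem_informed(be, 12)
        np.testing.assert_allclose(red.u[:6, :6], np.eye(6), atol=0)
        np.testing.assert_allclose(red.u[6:, :6], 0.0, atol=0)
        np.testing.assert_allclose(red.u[:6, 6:], 0.0, atol=0)
        np.testing.assert_allclose(red.u.T @ red.u, np.eye(12), atol=1e-10)
        # intramolecular descriptors pass through unchanged
        r = ic.evaluate(x, basis)
        q = r @ red.u
        np.testing.assert_allclose(q[:, :6], r[:, :6], atol=1e-12)

    def test_chem_informed_free_rows_orthogonal_to_fixed(self, dimer_catalog):
        x, w = _dimer_ensemble(dimer_catalog, seed=9)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        red = ic.reduce_chem_informed(be, 12)
        q_f, _ = np.linalg.qr(be.b_mean[:6].T)
        b_free = be.b_mean[6:]
        proj = b_free - (b_free @ q_f) @ q_f.T
        assert np.abs(q_f.T @ proj.T).max() < 1e-10

    def test_forward_map_has_full_rank(self, dimer_catalog):
        x, w = _dimer_ensemble(dimer_catalog, seed=11)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        for red in (ic.reduce_standard(be, 12), ic.reduce_chem_informed(be, 12)):
            jac = be.b_mean.T @ red.u  # 3N x (3N-6)
            assert np.linalg.matrix_rank(jac, tol=1e-10) == 12


class TestDiagnostics:
    def test_transform_identity(self):
        assert np.allclose(ic.transform_T(np.eye(4), np.eye(4)), np.eye(4))

    def test_transform_rows_unit_norm(self, dimer_catalog):
        x, w = _dimer_ensemble(dimer_catalog, seed=13)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        red = ic.reduce_standard(be, 12)
        rng = np.random.default_rng(0)
        p, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        t = ic.transform_T(p, red.u)
        np.testing.assert_allclose(np.linalg.norm(t, axis=1), 1.0, atol=1e-10)
        v = rng.normal(size=15)
        np.testing.assert_allclose(t @ v, p.T @ (red.u.T @ v), atol=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=15, derandomize=True)
    def test_chem_informed_cifs_identically_zero(self, dimer_catalog, seed):
        """For any ensemble and any orthonormal P, the chemically informed
        reduction has CIF_intra = CIF_bond = CIF_angle = 0 exactly."""
        rng = np.random.default_rng(seed)
        x = np.repeat(dimer_catalog.gm.coords_bohr()[None], 8, axis=0)
        x += rng.normal(0, 0.08, x.shape)
        w = rng.uniform(0.1, 3.0, 8)
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        for level in ("N2", "N3"):
            basis = ic.build_basis(dimer_catalog.gm, level)
            be = ic.ensemble_b(x, w, basis, masses)
            red = ic.reduce_chem_informed(be, 12)
            p, _ = np.linalg.qr(rng.normal(size=(12, 12)))
            cif = ic.cif_diagnostics(ic.transform_T(p, red.u), basis)
            assert cif["cif_intra"] == pytest.approx(0.0, abs=1e-12)
            assert cif["cif_bond"] == pytest.approx(0.0, abs=1e-12)
            assert cif["cif_angle"] == pytest.approx(0.0, abs=1e-12)

    def test_cifs_invariant_under_p_rotation(self, dimer_catalog):
        x, w = _dimer_ensemble(dimer_catalog, seed=17)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        red = ic.reduce_standard(be, 12)
        rng = np.random.default_rng(3)
        p, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        with_p = ic.cif_diagnostics(ic.transform_T(p, red.u), basis)
        without = ic.cif_diagnostics(red.u.T, basis)
        for key in with_p:
            assert with_p[key] == pytest.approx(without[key], abs=1e-10)

    def test_all_intra_basis_has_zero_cif(self, monomer):
        basis = ic.build_basis(monomer, "N2")  # K = M = 3
        t = np.eye(3)
        cif = ic.cif_diagnostics(t, basis)
        assert cif["cif_intra"] == 0.0

    def test_mixing_fraction_bounds_and_block_diagonal_case(self, dimer_catalog):
        x, w = _dimer_ensemble(dimer_catalog, seed=19)
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        masses = np.repeat(dimer_catalog.gm.masses * AMU_TO_ME, 3)
        be = ic.ensemble_b(x, w, basis, masses)
        red = ic.reduce_chem_informed(be, 12)
        # block-diagonal T (P = identity) has zero inter->intra mixing
        assert ic.mixing_fraction(red.u.T, basis) == pytest.approx(0.0, abs=1e-14)
        rng = np.random.default_rng(4)
        p, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        f = ic.mixing_fraction(ic.transform_T(p, red.u), basis)
        assert 0.0 <= f <= 1.0 + 1e-12

    def test_monomer_mixing_is_zero(self, monomer):
        basis = ic.build_basis(monomer, "N2")
        assert ic.mixing_fraction(np.eye(3), basis) == 0.0

    def test_mode_character_bounds_and_pure_mode(self, dimer_catalog):
        basis = ic.build_basis(dimer_catalog.gm, "N2")
        t = np.zeros((12, 15))
        t[0, 0] = 1.0  # mode aligned with one OH bond descriptor
        assert ic.mode_character(t, basis, 0, "oh_bond") == 1.0
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(15, 12)))
        for l in range(12):
            chi = ic.mode_character(q.T, basis, l, "oh_bond")
            assert 0.0 <= chi <= 1.0 + 1e-12


class TestGInvSqrt:
    def test_identity(self):
        np.testing.assert_allclose(ic.g_inv_sqrt(np.eye(4)), np.eye(4))

    def test_diagonal(self):
        np.testing.assert_allclose(ic.g_inv_sqrt(np.diag([4.0, 9.0])),
                                   np.diag([0.5, 1.0 / 3.0]))

    def test_inverse_square_root_property(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(7, 7))
        g = a @ a.T + 0.5 * np.eye(7)
        gis = ic.g_inv_sqrt(g)
        np.testing.assert_allclose(gis @ g @ gis, np.eye(7), atol=1e-10)
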