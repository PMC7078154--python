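"""Unit tests for the LVC core: coordinates, potentials, transforms."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvcdyn.constants import AMU_TO_ME, BOHR_TO_ANGSTROM, CM1_TO_HARTREE, EV_PER_CM1
from lvcdyn.core import (
    ElectronicBasis,
    HarmonicReference,
    LVCModel,
    LVCParameters,
    adiabatize,
    build_diagonal,
    electronic_structure,
    evaluate_potential,
    from_normal_coordinates,
    mch_gradient_and_nac,
    mch_gradients,
    time_overlap,
    to_normal_coordinates,
    transform_properties,
    truncate_model,
)
from lvcdyn.factory import ManifoldSpec, generate_synthetic_model
from lvcdyn.io import write_model

from conftest import make_reference, single_mode_reference


# ---------------------------------------------------------------- coordinates
class TestNormalCoordinates:
    def test_reference_geometry_maps_to_zero(self, toy_reference):
        q = to_normal_coordinates(toy_reference, toy_reference.r_ref)
        np.testing.assert_allclose(q, 0.0, atol=1e-12)

    def test_unit_mode_displacement(self, toy_reference):
        ref = toy_reference
        for j in range(ref.n_modes):
            e = np.zeros(ref.n_modes)
            e[j] = 1.0
            r = from_normal_coordinates(ref, e)
            q = to_normal_coordinates(ref, r)
            np.testing.assert_allclose(q, e, atol=1e-8)

    def test_matches_brute_force_summation(self):
        """Independent term-by-term evaluation of the transform formula."""
        ref = make_reference(3, 4, seed=7)
        rng = np.random.default_rng(11)
        r = ref.r_ref + rng.normal(0, 0.05, ref.r_ref.shape)
        expected = np.zeros(ref.n_modes)
        for i in range(ref.n_modes):
            omega_au = ref.omega[i] * CM1_TO_HARTREE
            acc = 0.0
            for a in range(ref.n_atoms):
                m_au = ref.masses[a] * AMU_TO_ME
                for x in range(3):
                    dr_bohr = (r[a, x] - ref.r_ref[a, x]) / BOHR_TO_ANGSTROM
                    acc += ref.K[3 * a + x, i] * np.sqrt(m_au) * dr_bohr
            expected[i] = np.sqrt(omega_au) * acc
        np.testing.assert_allclose(
            to_normal_coordinates(ref, r), expected, rtol=1e-12, atol=1e-14
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_property(self, seed):
        ref = make_reference(3, 4, seed=seed % 97)
        rng = np.random.default_rng(seed)
        q = rng.normal(0, 1.0, ref.n_modes)
        q2 = to_normal_coordinates(ref, from_normal_coordinates(ref, q))
        np.testing.assert_allclose(q2, q, atol=1e-10)

    def test_atom_count_mismatch(self, toy_reference):
        with pytest.raises(ValueError, match="shape"):
            to_normal_coordinates(toy_reference, np.zeros((5, 3)))

    def test_invariants_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            HarmonicReference(
                r_ref=[[0, 0, 0]], masses=[2.0], omega=[500.0], K=[[2.0], [0], [0]]
            )
        with pytest.raises(ValueError, match="frequencies"):
            HarmonicReference(
                r_ref=[[0, 0, 0]], masses=[2.0], omega=[-500.0], K=[[1.0], [0], [0]]
            )


# ------------------------------------------------------------------ potential
class TestEvaluatePotential:
    def test_zero_geometry(self, small_model):
        ev = evaluate_potential(small_model, np.zeros(small_model.reference.n_modes))
        assert ev.V0 == 0.0
        np.testing.assert_allclose(np.diag(ev.V), small_model.params.epsilon)
        off = ev.V - np.diag(np.diag(ev.V))
        np.testing.assert_allclose(off, 0.0)

    def test_one_mode_two_state_closed_form(self):
        basis = ElectronicBasis(3, 0)
        ref = single_mode_reference(800.0)
        p = LVCParameters.zeros(basis, 1)
        p.epsilon = np.array([0.0, 0.0, 1.0])
        p.lam[1, 2, 0] = p.lam[2, 1, 0] = 0.1
        model = LVCModel(ref, p)
        ev = evaluate_potential(model, np.array([2.0]))
        assert ev.V[1, 2] == pytest.approx(0.2)
        hw = 800.0 * EV_PER_CM1
        assert ev.V0 == pytest.approx(hw * 4.0 / 2.0)

    def test_fixture_lowest_excited_singlet(self):
        from lvcdyn.factory import load_table1_fixture

        fx = load_table1_fixture(n_modes=1)
        ref = single_mode_reference()
        model = LVCModel(ref, fx.params)
        ev = evaluate_potential(model, np.zeros(1))
        e, _ = adiabatize(ev, fx.params.basis)
        singlet_e = np.sort(e[: fx.params.basis.n_singlets])
        assert singlet_e[1] == pytest.approx(2.71)

    def test_multiplicity_blocks_never_couple(self, small_model):
        rng = np.random.default_rng(0)
        mult = small_model.basis.multiplicities
        cross = mult[:, None] != mult[None, :]
        for _ in range(5):
            q = rng.normal(0, 1, small_model.reference.n_modes)
            ev = evaluate_potential(small_model, q)
            assert np.all(ev.V[cross] == 0.0)


# ----------------------------------------------------------------- adiabatize
def _eig_oracle(v):
    """Independent eigensolver: characteristic-polynomial roots + SVD
    null-space eigenvectors (never touches np.linalg.eigh)."""
    n = v.shape[0]
    coeffs = np.poly(v)
    roots = np.sort(np.roots(coeffs).real)
    vecs = np.zeros((n, n))
    for k, lam in enumerate(roots):
        _, s, vh = np.linalg.svd(v - lam * np.eye(n))
        vecs[:, k] = vh[-1]
    return roots, vecs


class TestAdiabatize:
    def test_diagonal_input(self):
        basis = ElectronicBasis(3, 0)
        ev = evaluate_potential(
            _model_from_eps(basis, [0.0, 1.0, 2.0]), np.zeros(1)
        )
        e, u = adiabatize(ev, basis)
        np.testing.assert_allclose(u, np.eye(3))
        np.testing.assert_allclose(e, [0.0, 1.0, 2.0])

    def test_symmetric_two_level(self):
        basis = ElectronicBasis(2, 0)
        p = LVCParameters.zeros(basis, 1)
        p.lam[0, 1, 0] = p.lam[1, 0, 0] = 0.3
        model = LVCModel(single_mode_reference(), p)
        ev = evaluate_potential(model, np.array([1.0]))
        e, u = adiabatize(ev, basis)
        c = 0.3
        hw = 1200.0 * EV_PER_CM1 / 2.0
        np.testing.assert_allclose(e, [hw - c, hw + c], atol=1e-12)
        # 45 degree mixing
        np.testing.assert_allclose(np.abs(u), np.full((2, 2), 1 / np.sqrt(2)), atol=1e-12)

    def test_against_characteristic_polynomial_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(5, 5))
        v = (a + a.T) / 2
        basis = ElectronicBasis(5, 0)
        ev_like = type("E", (), {"V": v})()
        e, u = adiabatize(ev_like, basis)
        e_ref, u_ref = _eig_oracle(v)
        np.testing.assert_allclose(e, e_ref, atol=1e-10)
        # compare eigenvectors up to sign
        for k in range(5):
            overlap = abs(np.dot(u[:, k], u_ref[:, k]))
            assert overlap == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_relabeling_invariance(self):
        basis = ElectronicBasis(4, 0)
        p = LVCParameters.zeros(basis, 2)
        p.epsilon = np.array([0.0, 2.0, 2.0, 3.0])
        rng = np.random.default_rng(3)
        p.kappa = rng.normal(0, 0.05, (4, 2))
        p.kappa[1] = p.kappa[2]  # keep states 1, 2 degenerate everywhere
        lam = rng.normal(0, 0.02, 2)
        for (i, j) in [(1, 3), (2, 3)]:
            p.lam[i, j] = p.lam[j, i] = lam
        ref = make_reference(3, 2, seed=4)
        model = LVCModel(ref, p)
        q = rng.normal(0, 0.5, 2)
        e1, _ = adiabatize(evaluate_potential(model, q), basis)
        # swap the two degenerate diabatic states consistently
        perm = [0, 2, 1, 3]
        p2 = LVCParameters(
            basis=basis,
            epsilon=p.epsilon[perm],
            kappa=p.kappa[perm],
            lam=p.lam[np.ix_(perm, perm)],
            soc=p.soc,
            dipoles=p.dipoles,
        )
        e2, _ = adiabatize(evaluate_potential(LVCModel(ref, p2), q), basis)
        np.testing.assert_allclose(e1, e2, atol=1e-12)


def _model_from_eps(basis, eps, n_modes=1):
    p = LVCParameters.zeros(basis, n_modes)
    p.epsilon = np.asarray(eps, dtype=float)
    return LVCModel(single_mode_reference(), p)


# ------------------------------------------------------------------ gradients
class TestGradientsAndNAC:
    def test_lambda_free_gradient_and_nac(self):
        basis = ElectronicBasis(2, 0)
        p = LVCParameters.zeros(basis, 1)
        p.epsilon = np.array([0.0, 2.0])
        p.kappa[1, 0] = 0.3
        model = LVCModel(single_mode_reference(), p)
        q = np.array([0.7])
        ev = evaluate_potential(model, q)
        e, u = adiabatize(ev, basis)
        hw = 1200.0 * EV_PER_CM1
        g = mch_gradients(ev, u)
        assert g[0, 0] == pytest.approx(hw * 0.7)
        assert g[1, 0] == pytest.approx(hw * 0.7 + 0.3)
        out = mch_gradient_and_nac(ev, e, u, 0, m=1)
        np.testing.assert_allclose(out["nac"], 0.0, atol=1e-14)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_finite_difference_property(self, seed):
        spec = ManifoldSpec(seed=seed % 211, n_modes=4)
        spec.singlet_counts = {"CS": 1, "MLCT": 1}
        spec.triplet_counts = {"CS": 1}
        model = generate_synthetic_model(spec)
        rng = np.random.default_rng(seed)
        q = rng.normal(0, 0.5, 4)
        ev = evaluate_potential(model, q)
        _, u = adiabatize(ev, model.basis)
        g = mch_gradients(ev, u)
        h = 1e-5
        for i in range(4):
            dq = np.zeros(4)
            dq[i] = h
            ep, _ = adiabatize(evaluate_potential(model, q + dq), model.basis)
            em, _ = adiabatize(evaluate_potential(model, q - dq), model.basis)
            np.testing.assert_allclose((ep - em) / (2 * h), g[:, i], atol=1e-6)

    def test_nac_antisymmetry(self, small_model):
        q = np.random.default_rng(1).normal(0, 0.4, small_model.reference.n_modes)
        ev = evaluate_potential(small_model, q)
        e, u = adiabatize(ev, small_model.basis)
        a = mch_gradient_and_nac(ev, e, u, 1, m=2)["nac"]
        b = mch_gradient_and_nac(ev, e, u, 2, m=1)["nac"]
        np.testing.assert_allclose(a, -b, atol=1e-12)


# ----------------------------------------------------------------- properties
class TestTransformProperties:
    def test_identity_transform(self, small_model):
        p = small_model.params
        soc, dip = transform_properties(
            np.eye(p.n_states), small_model.basis, soc=p.soc, dipoles=p.dipoles
        )
        np.testing.assert_allclose(soc, p.soc)
        np.testing.assert_allclose(dip, p.dipoles)

    def test_spectrum_invariant_under_extra_unitary(self, small_model):
        """Rotating the diabatic basis must not change the total spectrum."""
        basis = small_model.basis
        p = small_model.params
        q = np.random.default_rng(2).normal(0, 0.3, small_model.reference.n_modes)
        _, mch = electronic_structure(small_model, q)
        e_ref = np.linalg.eigvalsh(mch.H_diag_inputs)
        # random block-orthogonal rotation of the diabatic basis
        rng = np.random.default_rng(9)
        mult = basis.multiplicities
        r = np.zeros((p.n_states, p.n_states))
        for m in np.unique(mult):
            sel = np.where(mult == m)[0]
            a = rng.normal(size=(sel.size, sel.size))
            qm, _ = np.linalg.qr(a)
            r[np.ix_(sel, sel)] = qm
        ev = evaluate_potential(small_model, q)
        v_rot = r.T @ ev.V @ r
        r_exp = basis.expand_matrix(r)
        soc_rot = r_exp.conj().T @ p.soc @ r_exp
        e_rot, u_rot = np.linalg.eigh(basis.expand_matrix(v_rot) + soc_rot)
        np.testing.assert_allclose(np.sort(e_rot), np.sort(e_ref), atol=1e-10)

    def test_dipole_trace_conserved(self, small_model):
        q = np.random.default_rng(3).normal(0, 0.3, small_model.reference.n_modes)
        _, u = adiabatize(evaluate_potential(small_model, q), small_model.basis)
        _, dip = transform_properties(u, small_model.basis, dipoles=small_model.params.dipoles)
        for comp in range(3):
            assert np.trace(dip[comp]) == pytest.approx(
                np.trace(small_model.params.dipoles[comp]), abs=1e-12
            )

    def test_non_hermitian_rejected(self, small_model):
        bad = small_model.params.soc.copy()
        bad[0, 1] += 1.0
        with pytest.raises(ValueError, match="Hermitian"):
            transform_properties(
                np.eye(small_model.params.n_states), small_model.basis, soc=bad
            )


# ------------------------------------------------------------------- diagonal
class TestBuildDiagonal:
    def test_zero_soc_equals_sorted_mch(self, small_model):
        model = small_model
        model.params.soc = np.zeros_like(model.params.soc)
        q = np.random.default_rng(4).normal(0, 0.4, model.reference.n_modes)
        _, mch = electronic_structure(model, q)
        expected = np.sort(model.basis.expand_vector(mch.E_mch))
        np.testing.assert_allclose(mch.E_diag, expected, atol=1e-12)

    def test_two_level_avoided_crossing_gap(self):
        basis = ElectronicBasis(1, 1)
        p = LVCParameters.zeros(basis, 1)
        p.epsilon = np.array([2.0, 2.0])
        v = 0.03 + 0.04j
        p.soc[0, 2] = v  # singlet with the M_S=0 triplet component
        p.soc[2, 0] = np.conj(v)
        model = LVCModel(single_mode_reference(), p)
        _, mch = electronic_structure(model, np.zeros(1))
        coupled = [0, 2]
        gaps = mch.E_diag.max() - mch.E_diag.min()
        assert gaps == pytest.approx(2 * abs(v), abs=1e-12)

    def test_eigenvector_norms(self, small_model):
        q = np.random.default_rng(6).normal(0, 0.4, small_model.reference.n_modes)
        _, mch = electronic_structure(small_model, q)
        norms = np.linalg.norm(mch.U_diag, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)


# -------------------------------------------------------------------- overlap
class TestTimeOverlap:
    def test_identity(self):
        u = np.linalg.qr(np.random.default_rng(0).normal(size=(4, 4)))[0]
        np.testing.assert_allclose(time_overlap(u, u), np.eye(4), atol=1e-12)

    def test_sign_flip_recovered(self):
        u = np.linalg.qr(np.random.default_rng(1).normal(size=(4, 4)))[0]
        u2 = u.copy()
        u2[:, 2] *= -1
        np.testing.assert_allclose(time_overlap(u, u2), np.eye(4), atol=1e-12)

    def test_orthonormalized(self):
        rng = np.random.default_rng(2)
        u1 = np.linalg.qr(rng.normal(size=(5, 5)))[0]
        u2 = np.linalg.qr(rng.normal(size=(5, 5)))[0]
        s = time_overlap(u1, u2)
        np.testing.assert_allclose(s.T @ s, np.eye(5), atol=1e-10)


# ------------------------------------------------------------------- truncate
class TestTruncateModel:
    def test_frequency_cutoff_192_to_158(self):
        """34 modes below 300 cm^-1 removed from a 192-mode model."""
        rng = np.random.default_rng(0)
        n_atoms = 66
        masses = rng.uniform(1, 20, n_atoms)
        raw = rng.standard_normal((3 * n_atoms, 192))
        qm, _ = np.linalg.qr(raw)
        k = qm[:, :192]
        omega = np.concatenate(
            [rng.uniform(30, 299, 34), rng.uniform(301, 3500, 158)]
        )
        order = np.argsort(omega)
        ref = HarmonicReference(
            r_ref=rng.normal(size=(n_atoms, 3)), masses=masses,
            omega=omega[order], K=k[:, order],
        )
        basis = ElectronicBasis(2, 0)
        model = LVCModel(ref, LVCParameters.zeros(basis, 192))
        out = truncate_model(model, omega_cut=300.0)
        assert out.reference.n_modes == 158

    def test_state_removal_30_30_to_20_17(self):
        basis = ElectronicBasis(30, 30)
        model = LVCModel(
            make_reference(13, 6, seed=3), LVCParameters.zeros(basis, 6)
        )
        remove = [f"S{i}" for i in range(20, 30)]
        remove += ["T16", "T18"] + [f"T{i}" for i in range(20, 31)]
        out = truncate_model(model, remove_states=remove, drop_s0_soc=True)
        assert out.basis.n_singlets == 20
        assert out.basis.n_triplets == 17
        assert np.all(out.params.soc[0, :] == 0)
        assert np.all(out.params.soc[:, 0] == 0)

    def test_identity_truncation_roundtrips(self, small_model, tmp_path):
        out = truncate_model(small_model, omega_cut=0.0)
        write_model(small_model, tmp_path / "a.lvc")
        write_model(out, tmp_path / "b.lvc")
        assert (tmp_path / "a.lvc").read_bytes() == (tmp_path / "b.lvc").read_bytes()

    def test_errors(self, small_model):
        with pytest.raises(ValueError, match="every normal mode"):
            truncate_model(small_model, omega_cut=1e6)
        with pytest.raises(ValueError, match="unknown state labels"):
            truncate_model(small_model, remove_states=["X9"])
        all_excited = [l for l in small_model.basis.labels if l != "S0"]
        with pytest.raises(ValueError, match="every excited state"):
            truncate_model(small_model, remove_states=all_excited)
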