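import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soomp.pursuit import (
    DegenerateAtomError,
    NoSelectableAtomError,
    SignalSet,
    extend_orthogonal_basis,
    oomp,
    select_atom_somp,
    select_atom_soomp,
    somp,
    soomp,
    update_duals,
    update_residuals,
)
from soomp.synthetic import gaussian_dictionary, make_joint_sparse

from conftest import lstsq_projection


class TestSignalSet:
    def test_uniform_default_weights(self):
        ss = SignalSet(np.ones((8, 4)))
        assert np.allclose(ss.weights, 0.25)

    def test_rejects_bad_weights(self):
        with pytest.raises(ValueError):
            SignalSet(np.ones((8, 2)), weights=[0.7, 0.7])
        with pytest.raises(ValueError):
            SignalSet(np.ones((8, 2)), weights=[-0.5, 1.5])


class TestSelection:
    def test_first_selection_is_weighted_energy_argmax(self, gauss_dict):
        rng = np.random.default_rng(0)
        F = rng.standard_normal((64, 3))
        p = np.array([0.5, 0.3, 0.2])
        idx = select_atom_soomp(F, gauss_dict, np.empty((64, 0)), [], p)
        scores = ((gauss_dict.atoms.T @ F) ** 2) @ p
        assert idx == int(np.argmax(scores))

    def test_hand_worked_two_atom_example(self):
        # d1 = e1, d2 = (e1+e2)/sqrt(2), f = e2, Gamma = {1}:
        # criterion value for d2 is |<d2,f>|^2 / (1 - 1/2) = 1
        atoms = np.column_stack([[1.0, 0.0], [1 / np.sqrt(2), 1 / np.sqrt(2)]])
        f = np.array([[0.0], [1.0]])
        wt = np.array([[1.0], [0.0]])  # w~1 = d1
        residual = f - wt * (wt.T @ f)
        idx = select_atom_soomp(residual, atoms, wt, [0], np.array([1.0]))
        assert idx == 1

    def test_somp_agrees_on_orthonormal_dictionary(self):
        atoms = np.eye(8)
        rng = np.random.default_rng(1)
        F = rng.standard_normal((8, 2))
        p = np.array([0.5, 0.5])
        selected = []
        R = F.copy()
        Wt = np.empty((8, 0))
        for _ in range(4):
            a = select_atom_soomp(R, atoms, Wt, selected, p)
            b = select_atom_somp(R, atoms, selected, p, ortho_normalized=Wt)
            assert a == b
            Wt = np.column_stack([Wt, atoms[:, a]])
            R = R - np.outer(atoms[:, a], atoms[:, a] @ R)
            selected.append(a)

    def test_all_atoms_in_span_raises(self):
        atoms = np.column_stack([[1.0, 0.0], [-1.0, 0.0]])
        wt = np.array([[1.0], [0.0]])
        with pytest.raises(NoSelectableAtomError):
            select_atom_soomp(np.array([[0.0], [1.0]]), atoms, wt, [0], np.array([1.0]))


class TestOrthogonalization:
    def test_first_vector_is_the_atom(self):
        d = np.array([0.6, 0.8, 0.0])
        w = extend_orthogonal_basis(np.empty((3, 0)), d)
        assert np.array_equal(w, d)

    def test_orthogonal_atom_passes_through(self):
        W = np.array([[1.0], [0.0], [0.0]])
        d = np.array([0.0, 1.0, 0.0])
        assert np.allclose(extend_orthogonal_basis(W, d), d)

    def test_nearly_dependent_atom_stays_orthogonal(self):
        # atom at angle ~1e-5 rad from the current span
        rng = np.random.default_rng(7)
        W = np.linalg.qr(rng.standard_normal((40, 5)))[0]
        in_span = W @ rng.standard_normal(5)
        in_span /= np.linalg.norm(in_span)
        perp = rng.standard_normal(40)
        perp -= W @ (W.T @ perp)
        perp /= np.linalg.norm(perp)
        atom = in_span + 1e-5 * perp
        atom /= np.linalg.norm(atom)
        w = extend_orthogonal_basis(W, atom)
        overlap = np.max(np.abs(W.T @ w)) / np.linalg.norm(w)
        assert overlap <= 1e-10

    def test_dependent_atom_raises(self):
        W = np.array([[1.0], [0.0]])
        with pytest.raises(DegenerateAtomError):
            extend_orthogonal_basis(W, np.array([2.0, 0.0]))


class TestDuals:
    def test_single_atom_dual_is_the_atom(self):
        d = np.array([1.0, 0.0, 0.0])
        B = update_duals(np.empty((3, 0)), d, d)
        assert np.allclose(B[:, 0], d)

    def test_biorthogonality_and_pseudoinverse(self, gauss_dict):
        rng = np.random.default_rng(3)
        idx = rng.choice(gauss_dict.n_atoms, 6, replace=False)
        A = gauss_dict.atoms[:, idx]
        W = np.empty((64, 0))
        B = np.empty((64, 0))
        for j in range(6):
            w = extend_orthogonal_basis(W, A[:, j])
            B = update_duals(B, w, A[:, j])
            W = np.column_stack([W, w])
        assert np.allclose(B.T @ A, np.eye(6), atol=1e-8)
        assert np.allclose(B.T, np.linalg.pinv(A), atol=1e-8)


class TestResidualUpdate:
    def test_signal_in_span_gets_zero_residual(self):
        atoms = np.eye(4)[:, :2]
        f = np.array([[3.0], [4.0], [0.0], [0.0]])
        ss = SignalSet(f)
        R = update_residuals(ss, f.copy(), atoms[:, 0])
        R = update_residuals(ss, R, atoms[:, 1])
        assert np.linalg.norm(R) <= 1e-10

    def test_error_decrement_identity(self):
        # each step removes exactly sum_q p(q) |<w,f{q}>|^2 / ||w||^2
        rng = np.random.default_rng(5)
        F = rng.standard_normal((16, 3))
        ss = SignalSet(F)
        w = rng.standard_normal(16)
        R = update_residuals(ss, F.copy(), w)
        before = ss.weights @ np.linalg.norm(F, axis=0) ** 2
        after = ss.weights @ np.linalg.norm(R, axis=0) ** 2
        removed = ss.weights @ (w @ F) ** 2 / (w @ w)
        assert before - after == pytest.approx(removed, abs=1e-8)


class TestSoomp:
    def test_single_signal_equals_oomp(self, gauss_dict):
        rng = np.random.default_rng(11)
        f = rng.standard_normal(64)
        a = oomp(f, gauss_dict, max_atoms=6)
        b = soomp(SignalSet(f[:, None]), gauss_dict, max_atoms=6)
        assert a.selected_indices == b.selected_indices
        assert np.allclose(a.coefficients, b.coefficients)

    def test_standard_basis_selects_largest_mean_square_coordinates(self):
        atoms = np.eye(8)
        F = np.column_stack([np.arange(8.0), np.arange(8.0)[::-1]])
        res = soomp(SignalSet(F), atoms, max_atoms=3)
        mean_sq = np.mean(F**2, axis=1)
        expected = list(np.argsort(-mean_sq, kind="stable")[:3])
        assert res.selected_indices == expected
        # residual = signals with the selected coordinates zeroed
        zeroed = F.copy()
        zeroed[res.selected_indices] = 0.0
        assert np.allclose(res.residuals, zeroed)

    def test_exact_reconstruction_with_complete_dictionary(self, gauss_dict):
        rng = np.random.default_rng(2)
        F = rng.standard_normal((64, 3))
        res = soomp(SignalSet(F), gauss_dict, tolerance=0.0, max_atoms=64)
        assert np.max(np.linalg.norm(res.residuals, axis=0)) <= 1e-8

    def test_noiseless_support_and_coefficient_recovery(self, joint_sparse_set):
        ss, truth = joint_sparse_set
        res = soomp(ss, gaussian_dictionary(64, 128, seed=1234),
                    tolerance=1e-18, max_atoms=10)
        assert res.n_atoms == len(truth.atom_indices)
        assert sorted(res.selected_indices) == list(truth.atom_indices)
        order = np.argsort(res.selected_indices)
        assert np.allclose(res.coefficients[:, order], truth.coefficients, atol=1e-8)

    def test_approximation_matches_projection_oracle(self, trig_small):
        rng = np.random.default_rng(13)
        F = rng.standard_normal((16, 4))
        ss = SignalSet(F)
        res = soomp(ss, trig_small, max_atoms=8)
        A = trig_small.atoms[:, res.selected_indices]
        proj = lstsq_projection(A, F)
        approx = res.approximations(ss)
        assert np.linalg.norm(approx - proj) <= 1e-8 * np.linalg.norm(proj)

    def test_error_trace_non_increasing(self, trig_small):
        rng = np.random.default_rng(17)
        ss = SignalSet(rng.standard_normal((16, 2)))
        res = soomp(ss, trig_small, max_atoms=12)
        assert np.all(np.diff(res.error_trace) <= 1e-12)

    def test_dimension_mismatch_rejected(self, gauss_dict):
        with pytest.raises(ValueError):
            soomp(SignalSet(np.ones((32, 2))), gauss_dict)

    def test_unreachable_tolerance_flags_not_errors(self):
        atoms = np.eye(8)[:, :3]  # rank-3 dictionary cannot span R^8
        labels_ok = soomp(SignalSet(np.ones((8, 1))), atoms, tolerance=1e-12,
                          max_atoms=8)
        assert not labels_ok.tolerance_reached
        assert labels_ok.stop_reason in ("no_selectable_atom", "max_atoms")


class TestSompComparison:
    def test_first_selection_identical(self, trig_small):
        # with an empty selection the SOOMP denominator is 1, so both
        # criteria coincide on the first atom
        rng = np.random.default_rng(0)
        ss = SignalSet(rng.standard_normal((16, 3)))
        a = soomp(ss, trig_small, max_atoms=1)
        b = somp(ss, trig_small, max_atoms=1)
        assert a.selected_indices == b.selected_indices

    def test_soomp_one_step_decrement_is_maximal(self, trig_small):
        # from any common state, the SOOMP pick reduces the weighted MSE
        # at least as much as the SOMP pick would
        from soomp.synthetic import make_correlated_multichannel

        for seed in range(5):
            ss = make_correlated_multichannel(16, n_components=6, seed=seed)
            a = soomp(ss, trig_small, max_atoms=4)
            for k in range(a.n_atoms):
                prefix = a.selected_indices[:k]
                A = trig_small.atoms[:, prefix] if prefix else np.empty((16, 0))
                Wt = np.linalg.qr(A)[0] if prefix else np.empty((16, 0))
                R = ss.signals - lstsq_projection(A, ss.signals) if prefix else ss.signals.copy()
                pick_soomp = select_atom_soomp(R, trig_small, Wt, prefix, ss.weights)
                pick_somp = select_atom_somp(R, trig_small, prefix, ss.weights,
                                             ortho_normalized=Wt)

                def err_after(n):
                    cols = prefix + [n]
                    P = lstsq_projection(trig_small.atoms[:, cols], ss.signals)
                    return ss.weights @ np.linalg.norm(ss.signals - P, axis=0) ** 2

                assert err_after(pick_soomp) <= err_after(pick_somp) + 1e-10

    def test_soomp_needs_no_more_atoms_at_fixed_quality(self, trig_small):
        # the sparsity-gain direction: at a fixed target error the
        # optimized selection never spends more atoms than SOMP
        from soomp.synthetic import make_correlated_multichannel

        for seed in range(5):
            ss = make_correlated_multichannel(16, n_components=6, seed=seed)
            tol = 1e-3 * float(ss.weights @ np.linalg.norm(ss.signals, axis=0) ** 2)
            a = soomp(ss, trig_small, tolerance=tol)
            b = somp(ss, trig_small, tolerance=tol)
            assert a.tolerance_reached and b.tolerance_reached
            assert a.n_atoms <= b.n_atoms


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    q=st.integers(1, 5),
    k=st.integers(1, 8),
)
def test_pursuit_invariants_random_instances(seed, q, k):
    """Orthonormality of w~, biorthogonality of duals, projection
    equivalence and monotone error hold on random joint-sparse inputs."""
    rng = np.random.default_rng(seed)
    D = gaussian_dictionary(32, 64, seed=seed)
    ss, _ = make_joint_sparse(q, 32, D, support_size=6, noise_sd=0.1, seed=seed)
    res = soomp(ss, D, max_atoms=k)
    Wt = res.ortho_normalized
    assert np.allclose(Wt.T @ Wt, np.eye(res.n_atoms), atol=1e-8)
    A = D.atoms[:, res.selected_indices]
    assert np.allclose(res.duals.T @ A, np.eye(res.n_atoms), atol=1e-8)
    proj = lstsq_projection(A, ss.signals)
    assert np.allclose(res.approximations(ss), proj, atol=1e-8)
    assert np.all(np.diff(res.error_trace) <= 1e-10)
    # full column rank of the selected atoms at the final iteration
    s = np.linalg.svd(A, compute_uv=False)
    assert s[-1] > 1e-10
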