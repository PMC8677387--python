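from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from liverseg.sparse_dictionary import (
    Dictionary,
    KSVDConfig,
    ksvd_train,
    load_dictionary,
    normalize_dictionary,
    omp,
    reconstruction_error,
    save_dictionary,
)


def brute_force_residual(atoms, y, T0):
    """Minimal residual over every support of size <= T0 (exhaustive LS)."""
    best = np.linalg.norm(y)
    t = atoms.shape[1]
    for k in range(1, T0 + 1):
        for support in combinations(range(t), k):
            sub = atoms[:, support]
            coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
            best = min(best, np.linalg.norm(y - sub @ coef))
    return best


class TestNormalize:
    def test_columns_scaled_to_unit_norm(self):
        D = np.diag([1.0, 2.0, 3.0]) @ np.random.default_rng(0).normal(size=(3, 4))
        out = normalize_dictionary(D)
        assert np.allclose(np.linalg.norm(out.atoms, axis=0), 1.0, atol=1e-12)

    def test_idempotent(self):
        D = normalize_dictionary(np.random.default_rng(1).normal(size=(5, 8))).atoms
        again = normalize_dictionary(D).atoms
        assert np.allclose(D, again, atol=1e-12)

    def test_zero_column_rejected_unless_replaced(self):
        D = np.eye(3, 4)
        D[:, 3] = 0
        with pytest.raises(ValueError, match="zero column"):
            normalize_dictionary(D)
        out = normalize_dictionary(D, replace_unused_atoms=True, rng=np.random.default_rng(0))
        assert np.allclose(np.linalg.norm(out.atoms, axis=0), 1.0)


class TestOMP:
    def test_single_atom_identity(self):
        D = normalize_dictionary(np.random.default_rng(0).normal(size=(6, 10)))
        x = omp(D, D.atoms[:, 3], T0=1)
        assert np.flatnonzero(x).tolist() == [3]
        assert abs(x[3] - 1.0) < 1e-10

    def test_orthonormal_exact_recovery(self):
        D = Dictionary(np.eye(4))
        y = 2.0 * D.atoms[:, 0] + 3.0 * D.atoms[:, 1]
        x = omp(D, y, T0=2)
        assert np.allclose(x, [2, 3, 0, 0], atol=1e-12)
        assert np.linalg.norm(y - D.atoms @ x) < 1e-12

    def test_residual_orthogonal_to_selected_atoms(self):
        rng = np.random.default_rng(2)
        D = normalize_dictionary(rng.normal(size=(8, 16)))
        y = rng.normal(size=8)
        x = omp(D, y, T0=3)
        residual = y - D.atoms @ x
        support = np.flatnonzero(x)
        assert np.abs(D.atoms[:, support].T @ residual).max() < 1e-8

    def test_never_beats_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            D = normalize_dictionary(rng.normal(size=(6, 10)))
            y = rng.normal(size=6)
            x = omp(D, y, T0=2)
            r_omp = np.linalg.norm(y - D.atoms @ x)
            assert r_omp >= brute_force_residual(D.atoms, y, 2) - 1e-10

    def test_matches_sklearn_omp(self):
        sklearn_omp = pytest.importorskip("sklearn.linear_model").OrthogonalMatchingPursuit
        rng = np.random.default_rng(4)
        D = normalize_dictionary(rng.normal(size=(12, 20)))
        y = rng.normal(size=12)
        x = omp(D, y, T0=3)
        ref = sklearn_omp(n_nonzero_coefs=3, fit_intercept=False).fit(D.atoms, y).coef_
        assert np.allclose(x, ref, atol=1e-8)

    def test_sparsity_budget_validation(self):
        D = Dictionary(np.eye(4))
        with pytest.raises(ValueError, match="exceeds"):
            omp(D, np.ones(4), T0=5)
        with pytest.raises(ValueError, match="mismatch"):
            omp(D, np.ones(5), T0=2)


class TestKSVD:
    def test_rank_one_data_recovered(self):
        u = np.random.default_rng(0).normal(size=8)
        u /= np.linalg.norm(u)
        Y = np.tile(u[:, None], 50)
        res = ksvd_train(Y, KSVDConfig(t=2, T0=1, n_iterations=5, seed=0))
        err = np.linalg.norm(Y - res.dictionary.atoms @ res.codes.codes)
        assert err < 1e-10
        cosines = np.abs(res.dictionary.atoms.T @ u)
        assert cosines.max() > 1 - 1e-10

    def test_objective_monotone_and_more_iterations_not_worse(self):
        rng = np.random.default_rng(5)
        Dt = normalize_dictionary(rng.normal(size=(8, 12))).atoms
        X = np.zeros((12, 100))
        for i in range(100):
            X[rng.integers(12), i] = rng.uniform(1, 2)
        Y = Dt @ X + 0.01 * rng.normal(size=(8, 100))
        res1 = ksvd_train(Y, KSVDConfig(t=12, T0=1, n_iterations=1, seed=1))
        res10 = ksvd_train(Y, KSVDConfig(t=12, T0=1, n_iterations=10, seed=1))
        hist = res10.objective_history
        assert np.all(np.diff(hist) <= 1e-9 * max(1.0, hist[0]))
        assert hist[-1] <= res1.objective_history[-1] + 1e-9

    def test_codes_respect_sparsity_and_atoms_stay_normalized(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(10, 80))
        res = ksvd_train(Y, KSVDConfig(t=16, T0=3, n_iterations=5, seed=2))
        assert np.allclose(np.linalg.norm(res.dictionary.atoms, axis=0), 1.0, atol=1e-8)
        assert np.count_nonzero(res.codes.codes, axis=0).max() <= 3

    def test_all_zero_training_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            ksvd_train(np.zeros((5, 20)), KSVDConfig(t=8, T0=1, n_iterations=1, seed=0))

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(6, 40))
        a = ksvd_train(Y, KSVDConfig(t=10, T0=2, n_iterations=3, seed=9))
        b = ksvd_train(Y, KSVDConfig(t=10, T0=2, n_iterations=3, seed=9))
        assert np.array_equal(a.dictionary.atoms, b.dictionary.atoms)
        assert np.array_equal(a.codes.codes, b.codes.codes)


class TestReconstructionError:
    def test_atom_reconstructs_exactly(self):
        D = normalize_dictionary(np.random.default_rng(0).normal(size=(6, 9)))
        assert reconstruction_error(D, D.atoms[:, 4], T0=1) < 1e-10

    def test_orthogonal_complement_keeps_full_norm(self):
        D = Dictionary(np.eye(4)[:, :2])  # incomplete orthonormal sub-dictionary
        y = np.array([0.0, 0.0, 3.0, 4.0])
        assert abs(reconstruction_error(D, y, T0=2) - 5.0) < 1e-12

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(8)
        D = normalize_dictionary(rng.normal(size=(7, 12)))
        y = rng.normal(size=7)
        x = omp(D, y, T0=3)
        assert abs(reconstruction_error(D, y, 3) - np.linalg.norm(y - D.atoms @ x)) < 1e-12

    def test_never_exceeds_input_norm(self):
        rng = np.random.default_rng(9)
        D = normalize_dictionary(rng.normal(size=(5, 8)))
        for _ in range(20):
            y = rng.normal(size=5) * rng.uniform(0.1, 10)
            assert reconstruction_error(D, y, 2) <= np.linalg.norm(y) + 1e-12


_finite_vec = arrays(
    float, 5, elements=st.floats(-10, 10, allow_nan=False, allow_infinity=False)
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(y=_finite_vec)
def test_reconstruction_error_never_exceeds_input_norm_property(y):
    """The zero code is always feasible, so L(y) <= ||y|| for any input."""
    D = normalize_dictionary(np.random.default_rng(0).normal(size=(5, 8)))
    assert reconstruction_error(D, y, T0=2) <= np.linalg.norm(y) + 1e-9


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    M=arrays(float, (4, 6), elements=st.floats(-5, 5, allow_nan=False, allow_infinity=False))
)
def test_normalization_yields_unit_columns_property(M):
    norms = np.linalg.norm(M, axis=0)
    if (norms < 1e-6).any():
        return  # zero columns are a documented error, covered elsewhere
    out = normalize_dictionary(M)
    assert np.allclose(np.linalg.norm(out.atoms, axis=0), 1.0, atol=1e-10)


def test_hdf5_roundtrip(tmp_path):
    rng = np.random.default_rng(10)
    Y = rng.normal(size=(6, 40))
    res = ksvd_train(Y, KSVDConfig(t=10, T0=2, n_iterations=3, seed=0))
    path = str(tmp_path / "dict.h5")
    save_dictionary(res, path)
    back = load_dictionary(path)
    assert np.allclose(back.atoms, res.dictionary.atoms)
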