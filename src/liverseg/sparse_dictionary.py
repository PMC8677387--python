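"""Overcomplete dictionary learning (K-SVD) and sparse coding (OMP).

The boundary detector represents each patch feature vector ``y ∈ R^m`` as
a sparse combination ``y ≈ D x`` of at most ``T0`` atoms from an
overcomplete, column-normalized dictionary ``D ∈ R^{m×t}``.  The
dictionary is trained on liver-boundary patches by K-SVD:

1. *Sparse coding* — with ``D`` fixed, each training column is coded by
   orthogonal matching pursuit (OMP): greedily select the atom with the
   largest absolute inner product with the current residual, then re-solve
   the coefficients by least squares on the selected support.
2. *Dictionary update* — for each atom ``k``, restrict the residual
   matrix (with atom k's contribution added back) to the samples whose
   codes use atom k, and replace atom and coefficient row by the leading
   rank-1 SVD factors.

The residual norm of a test patch's best ``T0``-sparse approximation —
its reconstruction error — is the boundary score: patches resembling the
trained boundary texture reconstruct well and score low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "Dictionary",
    "SparseCodeMatrix",
    "KSVDConfig",
    "KSVDResult",
    "normalize_dictionary",
    "omp",
    "ksvd_train",
    "reconstruction_error",
    "reconstruction_errors",
    "save_dictionary",
    "load_dictionary",
]

_NORM_TOL = 1e-10


@dataclass
class Dictionary:
    """Column-normalized atom matrix ``D`` of shape (m, t)."""

    atoms: np.ndarray

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be an (m, t) matrix")
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("dictionary columns must be unit L2 norm; use normalize_dictionary")

    @property
    def m(self) -> int:
        return self.atoms.shape[0]

    @property
    def t(self) -> int:
        return self.atoms.shape[1]


@dataclass
class SparseCodeMatrix:
    """Sparse coefficients ``X`` (t, N); every column has ≤ T0 nonzeros."""

    codes: np.ndarray
    sparsity_bound: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a (t, N) matrix")
        nnz = np.count_nonzero(self.codes, axis=0)
        if nnz.size and nnz.max() > self.sparsity_bound:
            raise ValueError(f"a code column has {nnz.max()} nonzeros > T0={self.sparsity_bound}")


@dataclass
class KSVDConfig:
    """K-SVD hyper-parameters.

    ``t`` atoms, sparsity ``T0``, iteration budget, RNG seed for the
    initial dictionary (a random subset of training columns), and whether
    atoms that go unused in an iteration are replaced by the currently
    worst-reconstructed training sample.
    """

    t: int = 64
    T0: int = 4
    n_iterations: int = 30
    seed: int = 0
    replace_unused_atoms: bool = True
    tol: float = 1e-6  # relative objective change for early stop

    def __post_init__(self) -> None:
        if not (0 < self.T0 <= self.t):
            raise ValueError(f"need 0 < T0 <= t, got T0={self.T0}, t={self.t}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class KSVDResult:
    dictionary: Dictionary
    codes: SparseCodeMatrix
    objective_history: np.ndarray  # ||Y - DX||_F^2 after each iteration
    n_iterations_run: int


def normalize_dictionary(
    D: np.ndarray,
    replace_unused_atoms: bool = False,
    rng: np.random.Generator | None = None,
) -> Dictionary:
    """Scale every column of ``D`` to unit L2 norm.

    Zero columns are an error unless ``replace_unused_atoms`` is set, in
    which case they are replaced by random unit vectors.
    """
    D = np.array(D, dtype=float)
    norms = np.linalg.norm(D, axis=0)
    zero = norms < _NORM_TOL
    if zero.any():
        if not replace_unused_atoms:
            raise ValueError(f"{int(zero.sum())} zero column(s) in dictionary")
        rng = np.random.default_rng() if rng is None else rng
        repl = rng.standard_normal((D.shape[0], int(zero.sum())))
        D[:, zero] = repl
        norms = np.linalg.norm(D, axis=0)
    return Dictionary(atoms=D / norms)


def omp(
    D: Dictionary,
    y: np.ndarray,
    T0: int,
    residual_tol: float = 0.0,
) -> np.ndarray:
    """Orthogonal matching pursuit; returns a dense length-t code vector.

    At each step the atom maximizing |<residual, atom>| is added to the
    support (ties broken by lowest atom index, numpy argmax order) and the
    coefficients are re-solved by least squares on the support, which
    leaves the residual orthogonal to all selected atoms.  Stops when T0
    atoms are selected, the residual norm drops to ``residual_tol``, or no
    atom correlates with the residual.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != D.m:
        raise ValueError(f"dimension mismatch: y has length {y.shape[0]}, dictionary m={D.m}")
    if T0 > D.t:
        raise ValueError(f"T0={T0} exceeds atom count t={D.t}")
    A = D.atoms
    support: list[int] = []
    x = np.zeros(D.t)
    residual = y.copy()
    selected = np.zeros(D.t, dtype=bool)
    for _ in range(T0):
        if np.linalg.norm(residual) <= residual_tol:
            break
        corr = np.abs(A.T @ residual)
        corr[selected] = -1.0
        j = int(np.argmax(corr))
        if corr[j] <= 1e-12:
            break
        support.append(j)
        selected[j] = True
        sub = A[:, support]
        coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
        residual = y - sub @ coef
    if support:
        x[support] = coef
    return x


def reconstruction_error(D: Dictionary, y: np.ndarray, T0: int, residual_tol: float = 0.0) -> float:
    """Residual norm ``||y − D·omp(D, y, T0)||_2`` of the best sparse fit."""
    x = omp(D, y, T0, residual_tol)
    return float(np.linalg.norm(np.asarray(y, dtype=float).ravel() - D.atoms @ x))


def reconstruction_errors(D: Dictionary, Y: np.ndarray, T0: int) -> np.ndarray:
    """Per-column reconstruction errors of a feature matrix (m, N)."""
    Y = np.asarray(Y, dtype=float)
    return np.array([reconstruction_error(D, Y[:, i], T0) for i in range(Y.shape[1])])


def _code_all(D: Dictionary, Y: np.ndarray, T0: int) -> np.ndarray:
    return np.column_stack([omp(D, Y[:, i], T0) for i in range(Y.shape[1])])


def ksvd_train(Y: np.ndarray, config: KSVDConfig) -> KSVDResult:
    """Train a dictionary on training features ``Y`` (m, N) by K-SVD.

    The objective ||Y − DX||_F² is recorded after every full iteration
    (coding + atom updates) and is non-increasing; training stops after
    ``config.n_iterations`` or when the relative objective change falls
    below ``config.tol``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be an (m, N) matrix")
    if not np.isfinite(Y).all():
        raise ValueError("training matrix contains non-finite values")
    if not np.any(Y):
        raise ValueError("training matrix is all zero")
    m, N = Y.shape
    if N < config.t:
        warnings.warn(
            f"fewer training samples (N={N}) than atoms (t={config.t}); "
            "the dictionary will be underdetermined",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    # init: random subset of training columns (nonzero ones preferred)
    col_norms = np.linalg.norm(Y, axis=0)
    candidates = np.flatnonzero(col_norms > _NORM_TOL)
    take = min(config.t, candidates.size)
    init_cols = rng.choice(candidates, size=take, replace=False)
    D0 = np.empty((m, config.t))
    D0[:, :take] = Y[:, init_cols]
    if take < config.t:
        D0[:, take:] = rng.standard_normal((m, config.t - take))
    D = normalize_dictionary(D0, replace_unused_atoms=True, rng=rng)

    history: list[float] = []
    X = np.zeros((config.t, N))
    for iteration in range(config.n_iterations):
        X = _code_all(D, Y, config.T0)
        A = D.atoms.copy()
        for k in range(config.t):
            used = np.flatnonzero(X[k])
            if used.size == 0:
                continue
            # restricted error with atom k's contribution added back
            E = Y[:, used] - A @ X[:, used] + np.outer(A[:, k], X[k, used])
            U, S, Vt = np.linalg.svd(E, full_matrices=False)
            u, v = U[:, 0], S[0] * Vt[0]
            # deterministic sign convention
            pivot = int(np.argmax(np.abs(u)))
            if u[pivot] < 0:
                u, v = -u, -v
            A[:, k] = u
            X[k, used] = v
        if config.replace_unused_atoms:
            unused = np.flatnonzero(~np.any(X, axis=1))
            if unused.size:
                errs = np.linalg.norm(Y - A @ X, axis=0)
                worst = np.argsort(errs)[::-1]
                for k, w in zip(unused, worst):
                    if errs[w] > _NORM_TOL:
                        A[:, k] = Y[:, w] / np.linalg.norm(Y[:, w])
        D = normalize_dictionary(A, replace_unused_atoms=True, rng=rng)
        obj = float(np.linalg.norm(Y - D.atoms @ X) ** 2)
        history.append(obj)
        if iteration > 0 and history[-2] > 0:
            if abs(history[-2] - obj) / max(history[-2], 1e-30) < config.tol:
                break

    codes = SparseCodeMatrix(codes=X, sparsity_bound=config.T0)
    return KSVDResult(
        dictionary=D,
        codes=codes,
        objective_history=np.asarray(history),
        n_iterations_run=len(history),
    )


def save_dictionary(result_or_dict: Dictionary | KSVDResult, path: str) -> None:
    """Persist dictionary (and codes, if available) to HDF5."""
    with h5py.File(path, "w") as fh:
        if isinstance(result_or_dict, KSVDResult):
            fh.create_dataset("atoms", data=result_or_dict.dictionary.atoms)
            fh.create_dataset("codes", data=result_or_dict.codes.codes)
            fh.create_dataset("objective_history", data=result_or_dict.objective_history)
            fh.attrs["T0"] = result_or_dict.codes.sparsity_bound
        else:
            fh.create_dataset("atoms", data=result_or_dict.atoms)


def load_dictionary(path: str) -> Dictionary:
    with h5py.File(path, "r") as fh:
        atoms = np.asarray(fh["atoms"])
    return Dictionary(atoms=atoms)
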