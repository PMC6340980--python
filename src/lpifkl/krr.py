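"""Two-step Kronecker kernel ridge regression over a bipartite network.

Given fused kernels K_lnc (m×m) and K_pro (n×n), regularisers lambda_l and
lambda_p and the masked training adjacency F, the score matrix is the closed
form

    F* = K_lnc (K_lnc + lambda_l I)^{-1}  F  (K_pro + lambda_p I)^{-1} K_pro

computed via one eigendecomposition per side (so sweeping a regulariser grid
costs only diagonal rescalings). The same predictor arises from the two-step
view — smooth each lncRNA row through the lncRNA-side ridge, then each
resulting row through the protein-side ridge — and from the Kronecker-product
formulation, in which the pairwise kernel

    Xi = (K_pro ⊗ K_lnc)(lambda_l lambda_p I + lambda_p I ⊗ K_lnc
                         + lambda_l K_pro ⊗ I)^{-1}

defines the ridge smoother vec(F*) = Xi (Xi + I)^{-1} vec(F). The Kronecker
route is materialised only as a small-problem oracle.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

KRON_ORACLE_LIMIT = 2000


def _check_kernel(K: np.ndarray, name: str) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if not np.isfinite(K).all():
        raise ValueError(f"{name} contains non-finite entries")
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"{name} must be square")
    return 0.5 * (K + K.T)


class KroneckerKernelRidge(BaseEstimator):
    """Kernel ridge regression on pairs, factorised over the two spaces.

    Parameters
    ----------
    lambda_l : float, default 1.0
        Ridge regulariser on the lncRNA side (must be > 0).
    lambda_p : float, default 1.0
        Ridge regulariser on the protein side (must be > 0).

    Attributes
    ----------
    F_train_ : ndarray of shape (m, n)
        The training adjacency seen at fit time.
    eig_lnc_, eig_pro_ : (eigenvalues, eigenvectors)
        Spectral decompositions of the two kernels, reused across
        regulariser sweeps via :meth:`set_params` + :meth:`predict`.
    """

    def __init__(self, lambda_l: float = 1.0, lambda_p: float = 1.0):
        self.lambda_l = lambda_l
        self.lambda_p = lambda_p

    def _validate(self) -> None:
        if self.lambda_l <= 0 or self.lambda_p <= 0:
            raise ValueError("regularisers lambda_l and lambda_p must be positive")

    def fit(self, K_lnc: np.ndarray, K_pro: np.ndarray, F_train: np.ndarray):
        self._validate()
        K_lnc = _check_kernel(K_lnc, "K_lnc")
        K_pro = _check_kernel(K_pro, "K_pro")
        F = np.asarray(F_train, dtype=float)
        if F.shape != (K_lnc.shape[0], K_pro.shape[0]):
            raise ValueError(
                f"adjacency shape {F.shape} does not match kernels "
                f"{K_lnc.shape[0]}x{K_pro.shape[0]}"
            )
        self.K_lnc_, self.K_pro_, self.F_train_ = K_lnc, K_pro, F
        self.eig_lnc_ = np.linalg.eigh(K_lnc)
        self.eig_pro_ = np.linalg.eigh(K_pro)
        return self

    # -- closed form -------------------------------------------------------
    def predict(self) -> np.ndarray:
        """Score matrix F* from the closed form, via the cached spectra."""
        self._validate()
        wl, Ul = self.eig_lnc_
        wp, Up = self.eig_pro_
        left = (Ul * (wl / (wl + self.lambda_l))) @ Ul.T
        right = (Up * (wp / (wp + self.lambda_p))) @ Up.T
        return left @ self.F_train_ @ right

    # -- two-step view ------------------------------------------------------
    def smooth_rows(self) -> np.ndarray:
        """Step 1: intermediate rows f_{i,.} = k_lnc,i^T (K_lnc+lambda_l I)^{-1} F."""
        self._validate()
        wl, Ul = self.eig_lnc_
        return (Ul * (wl / (wl + self.lambda_l))) @ Ul.T @ self.F_train_

    def two_step_predict(self) -> np.ndarray:
        """Step 2 applied to step 1: algebraically identical to :meth:`predict`."""
        F1 = self.smooth_rows()
        wp, Up = self.eig_pro_
        return F1 @ (Up * (wp / (wp + self.lambda_p))) @ Up.T

    # -- Kronecker oracle ---------------------------------------------------
    def kron_operator(self) -> np.ndarray:
        """Materialise the pairwise kernel Xi (test oracle; m*n <= 2000)."""
        m, n = self.F_train_.shape
        if m * n > KRON_ORACLE_LIMIT:
            raise ValueError(
                f"Kronecker oracle limited to m*n <= {KRON_ORACLE_LIMIT}; got {m * n}"
            )
        G = np.kron(self.K_pro_, self.K_lnc_)
        D = (
            self.lambda_l * self.lambda_p * np.eye(m * n)
            + self.lambda_p * np.kron(np.eye(n), self.K_lnc_)
            + self.lambda_l * np.kron(self.K_pro_, np.eye(m))
        )
        return G @ np.linalg.inv(D)

    def kron_oracle_predict(self) -> np.ndarray:
        """vec(F*) = Xi (Xi + I)^{-1} vec(F), unvectorised back to m×n.

        This minimises sum_{i,j} (f_{i,j} - f*_{i,j})^2 + vec(F*)^T Xi^{-1}
        vec(F*) over all entries of the training view, and agrees with the
        closed form.
        """
        m, n = self.F_train_.shape
        Xi = self.kron_operator()
        vecF = self.F_train_.reshape(-1, order="F")
        vec_star = Xi @ np.linalg.solve(Xi + np.eye(m * n), vecF)
        return vec_star.reshape((m, n), order="F")

    # -- zero-shot ----------------------------------------------------------
    def predict_new_protein(self, k_pro_vec: np.ndarray) -> np.ndarray:
        """Scores over all lncRNAs for an unseen protein described by its
        kernel evaluations against the n training proteins."""
        k = np.asarray(k_pro_vec, dtype=float).ravel()
        if k.shape[0] != self.F_train_.shape[1]:
            raise ValueError(
                f"kernel vector length {k.shape[0]} != {self.F_train_.shape[1]} proteins"
            )
        wp, Up = self.eig_pro_
        return self.smooth_rows() @ (Up * (1.0 / (wp + self.lambda_p))) @ Up.T @ k

    def predict_new_lncrna(self, k_lnc_vec: np.ndarray) -> np.ndarray:
        """Symmetric zero-shot scores for an unseen lncRNA."""
        k = np.asarray(k_lnc_vec, dtype=float).ravel()
        if k.shape[0] != self.F_train_.shape[0]:
            raise ValueError(
                f"kernel vector length {k.shape[0]} != {self.F_train_.shape[0]} lncRNAs"
            )
        wl, Ul = self.eig_lnc_
        wp, Up = self.eig_pro_
        row = (Ul * (1.0 / (wl + self.lambda_l))) @ Ul.T @ self.F_train_
        return k @ row @ (Up * (wp / (wp + self.lambda_p))) @ Up.T


def fit_predict(
    K_lnc: np.ndarray,
    K_pro: np.ndarray,
    F_train: np.ndarray,
    lambda_l: float,
    lambda_p: float,
) -> np.ndarray:
    """One-shot closed-form score matrix."""
    model = KroneckerKernelRidge(lambda_l, lambda_p).fit(K_lnc, K_pro, F_train)
    return model.predict()


def two_step_predict(K_lnc, K_pro, F_train, lambda_l, lambda_p) -> np.ndarray:
    model = KroneckerKernelRidge(lambda_l, lambda_p).fit(K_lnc, K_pro, F_train)
    return model.two_step_predict()


def kron_oracle_predict(K_lnc, K_pro, F_train, lambda_l, lambda_p) -> np.ndarray:
    model = KroneckerKernelRidge(lambda_l, lambda_p).fit(K_lnc, K_pro, F_train)
    return model.kron_oracle_predict()
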