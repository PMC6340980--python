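"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: O(d^2) dynamic programming with
explicit loops, O(P*N) pairwise counting, and dense simplex grids. None of it
shares code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np


def sw_score_oracle(
    s1: str,
    s2: str,
    sub,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Affine-gap Smith-Waterman by the Gotoh recurrences, every cell enumerated.

    ``sub(a, b)`` returns the substitution score; a gap of length L costs
    gap_open + (L - 1) * gap_extend.
    """
    n1, n2 = len(s1), len(s2)
    H = np.zeros((n1 + 1, n2 + 1))
    E = np.full((n1 + 1, n2 + 1), -np.inf)  # gap in s1 (move along s2)
    F = np.full((n1 + 1, n2 + 1), -np.inf)  # gap in s2
    best = 0.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + sub(s1[i - 1], s2[j - 1])
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return best


def auc_pairwise_oracle(scores, labels) -> float:
    """AUC by enumerating every (positive, negative) pair; ties count 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def simplex_grid_min(A: np.ndarray, b: np.ndarray, lambda_: float, step: float = 0.001):
    """Minimum of w^T (A + lambda I) w - 2 b^T w over a step-resolution grid of
    the 3-simplex. Returns (best_objective, best_w)."""
    assert A.shape == (3, 3)
    H = A + lambda_ * np.eye(3)
    n = int(round(1.0 / step))
    ticks = np.arange(n + 1)
    i, j = np.meshgrid(ticks, ticks, indexing="ij")
    keep = (i + j) <= n
    w1 = i[keep] * step
    w2 = j[keep] * step
    W = np.stack([w1, w2, 1.0 - w1 - w2], axis=1)
    obj = np.einsum("ki,ij,kj->k", W, H, W) - 2.0 * W @ b
    best = int(np.argmin(obj))
    return float(obj[best]), W[best]


def krr_direct_oracle(K_lnc, K_pro, F, lambda_l, lambda_p) -> np.ndarray:
    """Closed-form score matrix via explicit matrix inverses (no spectra)."""
    m, n = F.shape
    left = K_lnc @ np.linalg.inv(K_lnc + lambda_l * np.eye(m))
    right = np.linalg.inv(K_pro + lambda_p * np.eye(n)) @ K_pro
    return left @ F @ right
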