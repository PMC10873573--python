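"""Nonnegative double singular value decomposition (NNDSVD).

Deterministic SVD-based initialization of the NMF factor pair (W0, H0).
The leading singular triplet of a nonnegative matrix is nonnegative up to a
global sign (Perron-Frobenius) and is used directly; every later triplet is
split into its positive and negative sections, the section pair carrying
more energy is kept, and the pair is rescaled so the rank-1 term preserves
its singular value. No random state enters anywhere, which is what makes
the downstream blind factorization reproducible run to run.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .imagestack import ImageMatrix

__all__ = ["nndsvd"]


def _pos(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, 0.0)


def _neg(x: np.ndarray) -> np.ndarray:
    return np.where(x < 0, -x, 0.0)


def nndsvd(
    X: ImageMatrix | np.ndarray,
    r: int,
    zero_fill: float | str = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """NNDSVD initial factors for ``X ~= W0 @ H0``.

    Parameters
    ----------
    X
        Nonnegative ``m x n`` matrix (or ImageMatrix).
    r
        Number of components, ``1 <= r <= min(m, n)``.
    zero_fill
        Value replacing exact zeros in the output. ``0.0`` keeps the plain
        NNDSVD factors; the string ``"mean"`` fills zeros with
        ``mean(X) / 100``, which avoids the multiplicative-update pathology
        of entries locked at exactly zero.

    Returns
    -------
    (W0, H0)
        Nonnegative ``m x r`` and ``r x n`` arrays; deterministic — repeated
        calls are bit-identical.
    """
    A = X.values if isinstance(X, ImageMatrix) else np.asarray(X, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.any(A < 0):
        raise ValueError("X must be nonnegative")
    m, n = A.shape
    if not 1 <= r <= min(m, n):
        raise ValueError(f"r must satisfy 1 <= r <= min(m, n) = {min(m, n)}")

    U, s, Vt = scipy.linalg.svd(A, full_matrices=False)
    U, s, Vt = U[:, :r], s[:r], Vt[:r]

    W = np.zeros((m, r))
    H = np.zeros((r, n))

    # leading triplet: nonnegative up to a global sign; flip so entries >= 0
    u0, v0 = U[:, 0], Vt[0]
    if u0.sum() < 0:
        u0, v0 = -u0, -v0
    W[:, 0] = np.sqrt(s[0]) * np.abs(u0)
    H[0] = np.sqrt(s[0]) * np.abs(v0)

    for k in range(1, r):
        if s[k] <= 1e-12 * s[0]:  # below numerical rank: leave component zero
            continue
        u, v = U[:, k], Vt[k]
        # fix the SVD sign indeterminacy: make the positive section dominate;
        # exact ties break toward the positive section
        if np.linalg.norm(_pos(u)) * np.linalg.norm(_pos(v)) < np.linalg.norm(
            _neg(u)
        ) * np.linalg.norm(_neg(v)):
            u, v = -u, -v
        up, un = _pos(u), _neg(u)
        vp, vn = _pos(v), _neg(v)
        up_n, un_n = np.linalg.norm(up), np.linalg.norm(un)
        vp_n, vn_n = np.linalg.norm(vp), np.linalg.norm(vn)
        mp = up_n * vp_n
        mn = un_n * vn_n
        if mp >= mn:  # after the flip mp >= mn always holds; kept for clarity
            if mp == 0:
                continue  # degenerate triplet: leave component at zero
            sigma = s[k] * mp
            W[:, k] = np.sqrt(sigma) * up / up_n
            H[k] = np.sqrt(sigma) * vp / vp_n
        else:
            sigma = s[k] * mn
            W[:, k] = np.sqrt(sigma) * un / un_n
            H[k] = np.sqrt(sigma) * vn / vn_n

    if zero_fill == "mean":
        fill = A.mean() / 100.0
        W[W == 0] = fill
        H[H == 0] = fill
    elif zero_fill:
        W[W == 0] = float(zero_fill)
        H[H == 0] = float(zero_fill)
    return W, H
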