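"""Weighted least squares with the Moore-Penrose pseudoinverse.

The network design matrices are rank deficient by construction (the
Laplacian X'WX of a connected network has rank n-1), so every solve goes
through the pseudoinverse with a fixed relative singular-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: singular values below RTOL * s_max are treated as zero
RTOL = 1e-10


def pinv(a: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(a, rcond=RTOL)


def matrix_rank(a: np.ndarray) -> int:
    if a.size == 0:
        return 0
    s = np.linalg.svd(a, compute_uv=False)
    return int(np.sum(s > RTOL * s[0]))


def row_space_projector(X: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the row space of X (acts on coefficient
    vectors; v is estimable iff the projector leaves it unchanged)."""
    return pinv(X) @ X


def is_estimable(v: np.ndarray, X: np.ndarray, tol: float = RTOL) -> bool:
    v = np.asarray(v, dtype=float)
    resid = v - row_space_projector(X) @ v
    return bool(np.linalg.norm(resid) <= tol * max(1.0, np.linalg.norm(v)))


@dataclass(frozen=True)
class WlsResult:
    """One weighted least squares projection d -> X beta."""

    coef: np.ndarray        # (X'WX)^+ X'W d
    cov_coef: np.ndarray    # (X'WX)^+
    fitted: np.ndarray      # X coef = H d
    cov_fitted: np.ndarray  # X (X'WX)^+ X'
    H: np.ndarray           # hat matrix X (X'WX)^+ X'W
    Q: float                # (d - fitted)' W (d - fitted)
    rank: int               # rank of X


def wls_fit(X: np.ndarray, d: np.ndarray, w: np.ndarray) -> WlsResult:
    """Fit d = X beta by WLS with diagonal weights w (a vector).

    Uses the pseudoinverse of the information matrix X'WX, so rank
    deficient designs yield the minimum-norm solution; estimable linear
    combinations of ``coef`` are invariant to that choice.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=float)
    w = np.asarray(w, dtype=float)
    XtW = X.T * w
    L = XtW @ X
    Lplus = pinv(L)
    coef = Lplus @ XtW @ d
    H = X @ Lplus @ XtW
    fitted = X @ coef
    resid = d - fitted
    Q = float(resid @ (w * resid))
    return WlsResult(
        coef=coef,
        cov_coef=Lplus,
        fitted=fitted,
        cov_fitted=X @ Lplus @ X.T,
        H=H,
        Q=max(Q, 0.0),
        rank=matrix_rank(X),
    )
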