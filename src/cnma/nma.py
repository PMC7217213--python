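"""Standard (full-interaction) network meta-analysis.

Every distinct treatment is its own node; the model is d = B theta + eps
with B the edge-vertex incidence matrix. Estimation is weighted least
squares through the Moore-Penrose pseudoinverse of the graph Laplacian
B'WB:

    delta_hat = B (B'WB)^+ B'W d = H d

Heterogeneity/inconsistency is summarized by Cochran's
Q = (d - delta_hat)' W (d - delta_hat) on n_a - k - (n-1) degrees of
freedom, and the between-study variance tau^2 by a multivariate method of
moments. A random-effects fit adds tau^2 to each raw sampling variance,
re-runs the multi-arm adjustment, and refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._linalg import wls_fit
from .errors import ConnectivityError, StructuralError, ValidationError
from .network import Network, adjust_multiarm, build_incidence

__all__ = ["NmaFit", "fit_nma", "q_statistic", "estimate_tau2", "i_squared"]


@dataclass(frozen=True)
class NmaFit:
    """Result of a standard NMA.

    ``delta_hat``, ``cov_delta`` and ``H`` are at the estimation weights
    (random-effects weights when ``effects_model="random"``); the
    heterogeneity statistics ``Q``, ``df_Q``, ``p_Q`` and the
    common-effect quantities ``delta_hat_common``/``H_common``/``w_common``
    always refer to the common-effect fit, which is where Q-based model
    comparisons live.
    """

    network: Network
    effects_model: str
    reference: str
    B: np.ndarray
    delta_hat: np.ndarray
    cov_delta: np.ndarray
    H: np.ndarray
    theta_hat: np.ndarray
    cov_theta: np.ndarray
    Q: float
    df_Q: int
    p_Q: float
    tau2: float
    I2: float
    w: np.ndarray
    w_common: np.ndarray
    delta_hat_common: np.ndarray
    H_common: np.ndarray

    @property
    def rank(self) -> int:
        return self.network.n - 1

    @property
    def model_tag(self) -> str:
        return "standard"

    def theta_se(self) -> np.ndarray:
        """Standard errors of theta_hat vs the reference treatment."""
        i_ref = self.network.treatments.index(self.reference)
        var = (
            np.diag(self.cov_theta)
            + self.cov_theta[i_ref, i_ref]
            - 2.0 * self.cov_theta[:, i_ref]
        )
        return np.sqrt(np.clip(var, 0.0, None))


def _chi2_sf(q: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    return float(stats.chi2.sf(q, df))


def df_q(network: Network, rank: int) -> int:
    """Residual degrees of freedom n_a - k - rank for a design of the
    given rank (rank = n-1 for the standard model)."""
    return network.n_arms_total - network.k - rank


def q_statistic(network: Network, delta_hat: np.ndarray, W: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q for fitted consistent contrasts, with its chi-square
    degrees of freedom and p-value.

    ``W`` must be the common-effect (tau^2 = 0) weight matrix; the df are
    n_a - k - (n-1).
    """
    w = np.diag(W) if W.ndim == 2 else np.asarray(W)
    resid = network.effects - np.asarray(delta_hat)
    Q = float(resid @ (w * resid))
    df = df_q(network, network.n - 1)
    if df < 0:
        raise StructuralError(
            f"negative degrees of freedom ({df}): the network is over-parameterized"
        )
    return max(Q, 0.0), df, _chi2_sf(Q, df)


def _block_U(network: Network, B: np.ndarray) -> np.ndarray:
    """Block-diagonal heterogeneity structure matrix U.

    Start from 0.5 * B B' (diagonal 1; entry +-0.5 where two contrasts
    share an arm) and keep, for each p-arm study, its
    p(p-1)/2 x p(p-1)/2 block of contrast rows, zeroing everything
    off-block. For two-arm-only networks U is the identity.
    """
    U = 0.5 * (B @ B.T)
    sid = network.study_index()
    same_study = sid[:, None] == sid[None, :]
    return U * same_study


def estimate_tau2(
    network: Network,
    H: np.ndarray,
    Q: float,
    df: int,
    w: np.ndarray,
    B: np.ndarray | None = None,
) -> float:
    """Method-of-moments between-study variance.

        tau2_hat = max( (Q - df) / tr((I - H) U W), 0 )

    with Q, df, H and the weights w all from the same common-effect fit,
    and U the block-diagonal structure from :func:`_block_U`. For a
    two-arm-only network this reduces to the generalized
    DerSimonian-Laird denominator sum w_j (1 - h_jj).
    """
    if Q <= df:
        # truncation max(.,0) fires regardless of the denominator; this also
        # covers saturated designs where tr((I-H)UW) = 0 and Q = df = 0
        return 0.0
    if B is None:
        B = build_incidence(network)
    U = _block_U(network, B)
    w = np.asarray(w, dtype=float)
    m = network.m
    denom = float(np.trace((np.eye(m) - H) @ U @ np.diag(w)))
    if denom <= 0:
        raise StructuralError(
            f"tr((I-H)UW) = {denom:.3g} <= 0: degenerate design, tau2 not estimable"
        )
    return max((Q - df) / denom, 0.0)


def i_squared(Q: float, df: int) -> float:
    """Higgins' I^2 = max(0, (Q - df)/Q); NaN when df = 0 (saturated)."""
    if df <= 0:
        return float("nan")
    if Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q)


def fit_nma(
    network: Network,
    effects_model: str = "common",
    reference: str | None = None,
) -> NmaFit:
    """Fit the standard NMA model by weighted least squares.

    Parameters
    ----------
    network
        A connected contrast network (use the ``disconnected`` module
        otherwise).
    effects_model
        ``"common"`` or ``"random"``. The random-effects fit estimates
        tau^2 by the method of moments from the common-effect fit, adds it
        to every raw sampling variance, re-adjusts multi-arm standard
        errors and refits.
    reference
        Treatment against which ``theta_hat`` is expressed (set to zero);
        defaults to the first treatment in network order.
    """
    if effects_model not in ("common", "random"):
        raise ValidationError(f"effects_model must be 'common' or 'random', got {effects_model!r}")
    if not network.is_connected():
        raise ConnectivityError(
            "the network is disconnected; use cnma.disconnected.fit_disconnected"
        )
    if reference is None:
        reference = network.treatments[0]
    if reference not in network.treatments:
        raise ValidationError(f"reference {reference!r} is not a network treatment")

    B = build_incidence(network)
    d = network.effects

    adjusted = adjust_multiarm(network)
    w_common = 1.0 / adjusted.se_adjusted**2
    common = wls_fit(B, d, w_common)
    df = df_q(network, network.n - 1)
    if df < 0:
        raise StructuralError(
            f"negative degrees of freedom ({df}): the network is over-parameterized"
        )
    Q = common.Q
    tau2 = estimate_tau2(network, common.H, Q, df, w_common, B=B)

    if effects_model == "random":
        adj_r = adjust_multiarm(network, tau2=tau2)
        w = 1.0 / adj_r.se_adjusted**2
        fit = wls_fit(B, d, w)
    else:
        w = w_common
        fit = common

    theta = fit.coef
    i_ref = network.treatments.index(reference)
    theta = theta - theta[i_ref]

    return NmaFit(
        network=network,
        effects_model=effects_model,
        reference=reference,
        B=B,
        delta_hat=fit.fitted,
        cov_delta=fit.cov_fitted,
        H=fit.H,
        theta_hat=theta,
        cov_theta=fit.cov_coef,
        Q=Q,
        df_Q=df,
        p_Q=_chi2_sf(Q, df),
        tau2=tau2,
        I2=i_squared(Q, df),
        w=w,
        w_common=w_common,
        delta_hat_common=common.fitted,
        H_common=common.H,
    )
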