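"""Component network meta-analysis: additive and interaction models.

The additive model replaces the treatment-level design B with
X_a = B C, where C maps treatments to their components, so a
combination's effect is the sum of its components' effects (product of
odds ratios on the OR scale):

    beta_hat  = (X_a' W X_a)^+ X_a' W d      (component effects)
    theta_hat = C beta_hat                   (treatment effects)
    delta_hat = X_a beta_hat                 (consistent contrasts)

Interaction models append columns to C (one per interacting component
set) and are fitted identically. Because the CNMA projection H_a and the
standard-NMA projection H commute (H_a H = H_a = H H_a), the residual sum
of squares decomposes Pythagorean-style,
Q_a = Q + (delta_a - delta_nma)' W (delta_a - delta_nma), which yields a
chi-square test of the additivity assumption on n - 1 - r degrees of
freedom (r = rank of X_a).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._linalg import RTOL, is_estimable, wls_fit
from .components import ComponentStructure
from .errors import (
    ConnectivityError,
    IdentificationError,
    StructuralError,
    UsageError,
    ValidationError,
)
from .network import Network, adjust_multiarm, build_incidence
from .nma import NmaFit, df_q, estimate_tau2, i_squared, _chi2_sf

__all__ = [
    "CnmaFit",
    "ModelComparison",
    "fit_cnma",
    "q_cnma",
    "additivity_test",
    "compare_nested",
]


@dataclass(frozen=True)
class CnmaFit:
    """Result of an additive or interaction CNMA.

    Component effects ``beta_hat`` are relative to the inactive reference
    (all-zero row of C). As in :class:`~cnma.nma.NmaFit`, the headline
    estimates are at the estimation weights while ``Q``/``df``/``p`` and
    the ``*_common`` fields are common-effect quantities.
    """

    network: Network
    comps: ComponentStructure
    effects_model: str
    model_tag: str
    B: np.ndarray
    Xa: np.ndarray
    rank: int
    beta_hat: np.ndarray
    cov_beta: np.ndarray
    theta_hat: np.ndarray
    cov_theta: np.ndarray
    delta_hat: np.ndarray
    cov_delta: np.ndarray
    Ha: np.ndarray
    Q: float
    df: int
    p: float
    tau2: float
    I2: float
    w: np.ndarray
    w_common: np.ndarray
    delta_hat_common: np.ndarray
    Ha_common: np.ndarray

    @property
    def C(self) -> np.ndarray:
        return self._C_aligned

    def __post_init__(self):
        object.__setattr__(self, "_C_aligned", _align_C(self.network, self.comps))

    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))

    def theta_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_theta), 0.0, None))


@dataclass(frozen=True)
class ModelComparison:
    """Chi-square comparison of two nested fits via their Q difference."""

    Q_diff: float
    df_diff: int
    p: float
    models: tuple[str, str]  # (richer, sparser)
    weights: str = "common"


def _align_C(network: Network, comps: ComponentStructure) -> np.ndarray:
    missing = [t for t in network.treatments if t not in comps.treatments]
    if missing:
        raise ValidationError(
            f"component structure lacks treatments {missing}; build it from the "
            "network's treatment list"
        )
    rows = [comps.treatments.index(t) for t in network.treatments]
    return comps.C[rows]


def _non_identified(Xa: np.ndarray, components: tuple[str, ...]) -> list[str]:
    return [
        comp
        for j, comp in enumerate(components)
        if not is_estimable(np.eye(len(components))[j], Xa)
    ]


def fit_cnma(
    network: Network,
    comps: ComponentStructure,
    effects_model: str = "common",
    allow_rank_deficient: bool = False,
    require_connected: bool = True,
    model_tag: str | None = None,
) -> CnmaFit:
    """Fit an additive (or, with interaction columns in ``comps``,
    interaction) CNMA model.

    By default the design must have full column rank ``c``; otherwise an
    :class:`~cnma.errors.IdentificationError` names the non-identified
    components. Pass ``allow_rank_deficient=True`` to fit anyway and work
    in the estimable subspace (the route taken for disconnected
    networks).
    """
    if effects_model not in ("common", "random"):
        raise ValidationError(f"effects_model must be 'common' or 'random', got {effects_model!r}")
    if require_connected and not network.is_connected():
        raise ConnectivityError(
            "the network is disconnected; use cnma.disconnected.fit_disconnected"
        )
    C = _align_C(network, comps)
    B = build_incidence(network)
    Xa = B @ C
    dead = [comps.components[j] for j in range(comps.c) if not Xa[:, j].any()]
    if dead:
        raise IdentificationError(
            f"component(s) {dead} never differ between compared treatments; "
            "the corresponding X_a column is all zero",
            non_identified=dead,
        )
    d = network.effects

    adjusted = adjust_multiarm(network)
    w_common = 1.0 / adjusted.se_adjusted**2
    common = wls_fit(Xa, d, w_common)
    r = common.rank
    if r < comps.c and not allow_rank_deficient:
        raise IdentificationError(
            f"design matrix X_a has rank {r} < c = {comps.c}; non-identified "
            f"components: {_non_identified(Xa, comps.components)}",
            non_identified=_non_identified(Xa, comps.components),
        )
    df = df_q(network, r)
    if df < 0:
        raise StructuralError(
            f"negative residual degrees of freedom ({df}) for the CNMA design"
        )
    Q = common.Q
    tau2 = estimate_tau2(network, common.H, Q, df, w_common, B=B)

    if effects_model == "random":
        adj_r = adjust_multiarm(network, tau2=tau2)
        w = 1.0 / adj_r.se_adjusted**2
        fit = wls_fit(Xa, d, w)
    else:
        w = w_common
        fit = common

    if model_tag is None:
        extra = [c for c in comps.components if "*" in c]
        model_tag = f"interaction({','.join(extra)})" if extra else "additive"

    return CnmaFit(
        network=network,
        comps=comps,
        effects_model=effects_model,
        model_tag=model_tag,
        B=B,
        Xa=Xa,
        rank=r,
        beta_hat=fit.coef,
        cov_beta=fit.cov_coef,
        theta_hat=C @ fit.coef,
        cov_theta=C @ fit.cov_coef @ C.T,
        delta_hat=fit.fitted,
        cov_delta=fit.cov_fitted,
        Ha=fit.H,
        Q=Q,
        df=df,
        p=_chi2_sf(Q, df),
        tau2=tau2,
        I2=i_squared(Q, df),
        w=w,
        w_common=w_common,
        delta_hat_common=common.fitted,
        Ha_common=common.H,
    )


def q_cnma(network: Network, fit: CnmaFit) -> tuple[float, int, float]:
    """(Q_a, df_a, p) for a CNMA fit: the common-effect residual quadratic
    form on n_a - k - r degrees of freedom."""
    if fit.network is not network:
        resid = network.effects - fit.delta_hat_common
        Q = float(resid @ (fit.w_common * resid))
    else:
        Q = fit.Q
    df = df_q(network, fit.rank)
    if df < 0:
        raise StructuralError(f"negative degrees of freedom ({df})")
    return Q, df, _chi2_sf(Q, df)


def _check_same_weights(a, b) -> None:
    if a.network is not b.network and a.network.m != b.network.m:
        raise UsageError("fits are not on the same network")
    if not np.allclose(a.w_common, b.w_common, rtol=1e-12, atol=0.0):
        raise UsageError("fits use different common-effect weights")


def additivity_test(
    standard: NmaFit, cnma: CnmaFit, weights: str = "common"
) -> ModelComparison:
    """Test additivity by comparing the sparser CNMA fit against the
    richer standard NMA fit.

    With ``weights="common"`` (the default) the statistic is the
    difference of the common-effect heterogeneity statistics,
    Q_a - Q = (delta_a - delta_nma)' W (delta_a - delta_nma), on
    n - 1 - r degrees of freedom. Note this statistic also absorbs
    between-study heterogeneity; with ``weights="random"`` both
    projections are recomputed on shared random-effects weights (tau^2
    from the standard fit), which keeps the test near its nominal level
    when tau^2 > 0.
    """
    if not standard.network.is_connected():
        raise UsageError(
            "additivity is not testable on a disconnected network: no standard "
            "NMA model exists for comparison"
        )
    _check_same_weights(standard, cnma)
    df = (standard.network.n - 1) - cnma.rank
    if weights == "common":
        Q_diff = cnma.Q - standard.Q
        diff = cnma.delta_hat_common - standard.delta_hat_common
        qf = float(diff @ (standard.w_common * diff))
        if abs(qf - Q_diff) > 1e-8 * max(1.0, abs(Q_diff)):
            raise UsageError(
                f"Pythagorean identity violated (|{qf:.6g} - {Q_diff:.6g}| too "
                "large); the fits were not computed on identical weights"
            )
    elif weights == "random":
        adj = adjust_multiarm(standard.network, tau2=standard.tau2)
        w = 1.0 / adj.se_adjusted**2
        d = standard.network.effects
        fit_std = wls_fit(standard.B, d, w)
        fit_add = wls_fit(cnma.Xa, d, w)
        Q_diff = fit_add.Q - fit_std.Q
    else:
        raise UsageError(f"weights must be 'common' or 'random', got {weights!r}")
    return ModelComparison(
        Q_diff=max(Q_diff, 0.0),
        df_diff=df,
        p=_chi2_sf(max(Q_diff, 0.0), df),
        models=(standard.model_tag, cnma.model_tag),
        weights=weights,
    )


def _column_space_nested(sparse_X: np.ndarray, rich_X: np.ndarray) -> bool:
    proj = rich_X @ np.linalg.pinv(rich_X, rcond=RTOL)
    resid = sparse_X - proj @ sparse_X
    scale = max(1.0, float(np.linalg.norm(sparse_X)))
    return bool(np.linalg.norm(resid) <= 1e-8 * scale)


def compare_nested(rich: CnmaFit, sparse: CnmaFit) -> ModelComparison:
    """Q test of a sparser CNMA model against a richer one whose column
    space contains it (e.g. additive vs interaction)."""
    _check_same_weights(rich, sparse)
    if not _column_space_nested(sparse.Xa, rich.Xa):
        raise UsageError(
            f"model {sparse.model_tag!r} is not nested in {rich.model_tag!r}: "
            "its design columns leave the richer column space"
        )
    Q_diff = max(sparse.Q - rich.Q, 0.0)
    df = rich.rank - sparse.rank
    return ModelComparison(
        Q_diff=Q_diff,
        df_diff=df,
        p=_chi2_sf(Q_diff, df),
        models=(rich.model_tag, sparse.model_tag),
    )
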