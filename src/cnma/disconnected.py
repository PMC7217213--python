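"""CNMA for disconnected networks.

A network is disconnected when the treatments split into subsets with no
comparing study between them. A standard NMA cannot estimate across
subnets, but the additive CNMA design X_a = B C can "reconnect" them
whenever subnets share treatment components: any component contrast in
the row space of X_a remains estimable. This module detects subnets,
characterises the estimable subspace, and fits the component model on it.

On a disconnected network the additivity assumption itself is not
testable — there is no standard NMA model to compare against — so no
additivity test is offered here, and :func:`cnma.cnma.additivity_test`
refuses such fits explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._linalg import matrix_rank, row_space_projector
from .cnma import CnmaFit, fit_cnma
from .components import ComponentStructure
from .errors import EstimabilityError, ValidationError
from .network import Network, build_incidence

__all__ = [
    "SubnetReport",
    "detect_subnets",
    "fit_disconnected",
    "estimate_contrast",
    "component_contrast",
]

ADDITIVITY_NOT_TESTABLE = (
    "not testable: in a disconnected network no standard NMA model exists "
    "for comparison"
)


@dataclass(frozen=True)
class SubnetReport:
    """Connected-component structure and estimability of a network."""

    n_subnets: int
    membership: dict[str, int]
    rank_Xa: int | None
    components: tuple[str, ...] | None
    estimable_contrasts: list[np.ndarray] | None
    reference: str | None = None

    def to_json(self) -> str:
        payload = {
            "n_subnets": self.n_subnets,
            "membership": self.membership,
            "rank_Xa": self.rank_Xa,
            "components": list(self.components) if self.components else None,
            "estimable_contrasts": [
                np.round(v, 12).tolist() for v in self.estimable_contrasts
            ]
            if self.estimable_contrasts is not None
            else None,
            "reference": self.reference,
        }
        return json.dumps(payload, indent=2)


def detect_subnets(
    network: Network,
    comps: ComponentStructure | None = None,
    reference: str | None = None,
) -> SubnetReport:
    """Partition the comparison graph into connected subnets.

    Subnet ids are assigned in order of each subnet's lexicographically
    smallest treatment. When a component structure is supplied, the
    report also carries the rank of X_a and an orthonormal basis of its
    row space (the estimable component contrasts).
    """
    comps_graph = sorted(
        (sorted(cc) for cc in nx.connected_components(network.graph())),
        key=lambda cc: cc[0],
    )
    membership = {t: i for i, cc in enumerate(comps_graph) for t in cc}

    rank = basis = labels = None
    if comps is not None:
        C = comps.C[[comps.treatments.index(t) for t in network.treatments]]
        Xa = build_incidence(network) @ C
        rank = matrix_rank(Xa)
        # orthonormal row-space basis via SVD
        _, s, vt = np.linalg.svd(Xa)
        basis = [vt[i] for i in range(rank)]
        labels = comps.components
    return SubnetReport(
        n_subnets=len(comps_graph),
        membership=membership,
        rank_Xa=rank,
        components=labels,
        estimable_contrasts=basis,
        reference=reference,
    )


def _resolve_reference_component(
    comps: ComponentStructure, reference: str
) -> str:
    """Map a reference given as component or single-component treatment
    onto the component column to drop."""
    if reference in comps.components:
        return reference
    if reference in comps.treatments:
        row = comps.row(reference)
        nz = np.flatnonzero(row)
        if len(nz) == 1:
            return comps.components[nz[0]]
        raise ValidationError(
            f"reference treatment {reference!r} is not a single component; "
            "name the component to use as reference"
        )
    raise ValidationError(f"reference {reference!r} is neither a component nor a treatment")


def fit_disconnected(
    network: Network,
    comps: ComponentStructure,
    reference: str | None = None,
    effects_model: str = "common",
) -> CnmaFit:
    """Fit the additive CNMA model without requiring connectivity.

    With ``reference`` given, that component's column is dropped from C
    (and hence X_a) before solving; the remaining coefficients are then
    read relative to the reference under the additivity assumption, and
    the reduced design is invertible whenever its rank equals its column
    count. Without a reference, the full design is solved through the
    pseudoinverse and only row-space (estimable) contrasts should be
    interpreted — use :func:`estimate_contrast`.

    On a connected network with a full-rank design this reproduces
    :func:`cnma.cnma.fit_cnma` exactly.
    """
    if reference is not None:
        comp_ref = _resolve_reference_component(comps, reference)
        comps = comps.drop_component(comp_ref)
        tag = f"disconnected-additive(ref={comp_ref})"
    else:
        tag = None
    fit = fit_cnma(
        network,
        comps,
        effects_model=effects_model,
        allow_rank_deficient=True,
        require_connected=False,
        model_tag=tag,
    )
    return fit


def estimate_contrast(fit: CnmaFit, v: np.ndarray) -> tuple[float, float]:
    """Estimate and standard error of the component contrast v' beta.

    ``v`` is a coefficient vector over ``fit.comps.components``. The
    contrast must lie in the row space of X_a (residual norm below the
    rank tolerance after projection), otherwise it is not estimable and
    an :class:`~cnma.errors.EstimabilityError` reports the offending
    direction.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (fit.comps.c,):
        raise ValidationError(
            f"contrast vector has length {v.shape}, expected c = {fit.comps.c}"
        )
    resid = v - row_space_projector(fit.Xa) @ v
    if np.linalg.norm(resid) > 1e-10 * max(1.0, np.linalg.norm(v)):
        offending = {
            comp: round(float(x), 6)
            for comp, x in zip(fit.comps.components, resid)
            if abs(x) > 1e-10
        }
        raise EstimabilityError(
            f"contrast {v.tolist()} is not estimable: its projection residual "
            f"{offending} lies outside the row space of X_a"
        )
    est = float(v @ fit.beta_hat)
    se = float(np.sqrt(max(v @ fit.cov_beta @ v, 0.0)))
    return est, se


def component_contrast(fit: CnmaFit, plus: str, minus: str | None = None) -> tuple[float, float]:
    """Convenience wrapper for the contrast beta[plus] - beta[minus]
    (or beta[plus] alone)."""
    v = np.zeros(fit.comps.c)
    try:
        v[fit.comps.components.index(plus)] = 1.0
        if minus is not None:
            v[fit.comps.components.index(minus)] -= 1.0
    except ValueError as exc:
        raise ValidationError(f"unknown component in contrast: {exc}") from exc
    return estimate_contrast(fit, v)
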