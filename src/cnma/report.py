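"""Tabular result writers: league tables, component tables, text forest
tables, and model-comparison tables.

All estimates live on the additive (log) scale internally; tables report
both that scale and the exponentiated scale (odds ratios when the input
effects are log odds ratios). Confidence intervals are Wald intervals
with normal quantiles and no multiplicity adjustment. For a CNMA fit the
exponentiated effect of a combination row equals the product of its
components' exponentiated effects exactly, because theta = C beta.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cnma import CnmaFit, ModelComparison
from .nma import NmaFit

__all__ = [
    "league_table",
    "treatment_table",
    "component_table",
    "comparison_table",
    "forest_text",
]

_Z = float(stats.norm.ppf(0.975))


def _pairwise(theta: np.ndarray, cov: np.ndarray, labels: Sequence[str]):
    rows = []
    for i, t1 in enumerate(labels):
        for j, t2 in enumerate(labels):
            if i >= j:
                continue
            est = theta[i] - theta[j]
            var = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
            rows.append((t1, t2, est, np.sqrt(max(var, 0.0))))
    return rows


def league_table(fit: NmaFit | CnmaFit, exp_scale: bool = True) -> pd.DataFrame:
    """All pairwise treatment contrasts with Wald 95% CIs."""
    labels = fit.network.treatments
    rows = _pairwise(fit.theta_hat, fit.cov_theta, labels)
    df = pd.DataFrame(rows, columns=["treat1", "treat2", "estimate", "se"])
    df["ci_low"] = df["estimate"] - _Z * df["se"]
    df["ci_high"] = df["estimate"] + _Z * df["se"]
    if exp_scale:
        for col in ("estimate", "ci_low", "ci_high"):
            df[f"exp_{col}"] = np.exp(df[col])
    return df


def _vs_reference(fit: NmaFit | CnmaFit, reference: str):
    labels = list(fit.network.treatments)
    theta, cov = fit.theta_hat, fit.cov_theta
    i_ref = labels.index(reference)
    est = theta - theta[i_ref]
    var = np.diag(cov) + cov[i_ref, i_ref] - 2.0 * cov[:, i_ref]
    return labels, est, np.sqrt(np.clip(var, 0.0, None))


def _default_reference(fit: NmaFit | CnmaFit) -> str:
    if isinstance(fit, CnmaFit):
        return fit.comps.inactive or fit.network.treatments[0]
    return fit.reference


def treatment_table(
    fit: NmaFit | CnmaFit, reference: str | None = None, exp_scale: bool = True
) -> pd.DataFrame:
    """Per-treatment effects vs a reference (for a CNMA fit the inactive
    treatment by default, so combination rows multiply component rows on
    the exponentiated scale)."""
    reference = reference or _default_reference(fit)
    labels, est, se = _vs_reference(fit, reference)
    df = pd.DataFrame({"treatment": labels, "estimate": est, "se": se})
    df["ci_low"] = df["estimate"] - _Z * df["se"]
    df["ci_high"] = df["estimate"] + _Z * df["se"]
    if exp_scale:
        for col in ("estimate", "ci_low", "ci_high"):
            df[f"exp_{col}"] = np.exp(df[col])
    df.attrs["reference"] = reference
    return df


def component_table(fit: CnmaFit, exp_scale: bool = True) -> pd.DataFrame:
    """Component effects beta_hat vs the inactive reference."""
    se = fit.beta_se()
    df = pd.DataFrame(
        {"component": list(fit.comps.components), "estimate": fit.beta_hat, "se": se}
    )
    df["ci_low"] = df["estimate"] - _Z * df["se"]
    df["ci_high"] = df["estimate"] + _Z * df["se"]
    if exp_scale:
        for col in ("estimate", "ci_low", "ci_high"):
            df[f"exp_{col}"] = np.exp(df[col])
    return df


def comparison_table(comparisons: Sequence[ModelComparison]) -> pd.DataFrame:
    """Q-difference tests as a table (richer model first)."""
    return pd.DataFrame(
        {
            "richer": [c.models[0] for c in comparisons],
            "sparser": [c.models[1] for c in comparisons],
            "Q_diff": [c.Q_diff for c in comparisons],
            "df": [c.df_diff for c in comparisons],
            "p": [c.p for c in comparisons],
            "weights": [c.weights for c in comparisons],
        }
    )


def forest_text(
    fit: NmaFit | CnmaFit,
    reference: str | None = None,
    sm: str = "OR",
    digits: int = 2,
) -> str:
    """Plain-text forest table vs the reference: one line per treatment,
    exponentiated effect with 95% CI at the requested precision."""
    reference = reference or _default_reference(fit)
    df = treatment_table(fit, reference=reference)
    name_w = max(len(t) for t in df["treatment"]) + 2
    lines = [
        f"{'Treatment':<{name_w}}{sm} [95% CI]   (vs {reference})",
        "-" * (name_w + 25),
    ]
    for row in df.itertuples(index=False):
        if row.treatment == reference:
            lines.append(f"{row.treatment:<{name_w}}1 (reference)")
            continue
        lines.append(
            f"{row.treatment:<{name_w}}"
            f"{row.exp_estimate:.{digits}f} "
            f"[{row.exp_ci_low:.{digits}f}-{row.exp_ci_high:.{digits}f}]"
        )
    tag = getattr(fit, "model_tag", "standard")
    lines.append("")
    lines.append(
        f"model: {tag} ({fit.effects_model} effects), "
        f"Q = {fit.Q:.2f}, df = {fit.df_Q if isinstance(fit, NmaFit) else fit.df}, "
        f"tau2 = {fit.tau2:.4f}"
    )
    return "\n".join(lines)
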