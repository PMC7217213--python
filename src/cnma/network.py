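"""Contrast-level evidence networks.

A network holds one row per pairwise treatment comparison: an effect
estimate on an additive scale (log odds ratio, mean difference, ...) with
its standard error, following the convention ``effect = treat1 - treat2``.
A study with p arms contributes all p(p-1)/2 pairwise contrasts; their
standard errors are re-weighted (:func:`adjust_multiarm`) so that the
study enters the network with the information matrix of the joint
arm-level weighted model rather than with p(p-1)/2 spuriously independent
rows.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputFormatError, ValidationError

__all__ = [
    "Contrast",
    "Network",
    "read_contrasts",
    "contrasts_from_arms",
    "build_incidence",
    "adjust_multiarm",
    "build_weights",
]

#: accepted column aliases for contrast-level tables (netmeta-style names
#: ``TE``/``seTE`` are common in exported data sets)
_CONTRAST_ALIASES = {
    "study": ("study", "studlab", "study_id"),
    "treat1": ("treat1", "treatment1", "t1"),
    "treat2": ("treat2", "treatment2", "t2"),
    "effect": ("effect", "te", "d", "logor", "yi"),
    "se": ("se", "sete", "stderr", "sei"),
}

_ARM_ALIASES = {
    "study": ("study", "studlab", "study_id"),
    "treatment": ("treatment", "treat", "trt"),
    "events": ("events", "event", "responders", "r"),
    "n": ("n", "total", "sampsize"),
}


@dataclass(frozen=True)
class Contrast:
    """A single pairwise comparison, ``effect = treat1 - treat2``."""

    study: str
    treat1: str
    treat2: str
    effect: float
    se: float
    se_adjusted: float | None = None

    def __post_init__(self):
        if self.treat1 == self.treat2:
            raise ValidationError(
                f"study {self.study!r}: treat1 and treat2 are both {self.treat1!r}"
            )
        if not np.isfinite(self.effect):
            raise ValidationError(f"study {self.study!r}: non-finite effect")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValidationError(
                f"study {self.study!r} ({self.treat1} vs {self.treat2}): "
                f"standard error must be positive, got {self.se!r}"
            )


class Network:
    """An ordered, validated collection of pairwise contrasts.

    Parameters
    ----------
    contrasts
        The pairwise comparisons, one per within-study treatment pair.
    treatment_order, study_order
        Optional explicit orderings. By default treatments and studies are
        sorted lexicographically so that every derived matrix is
        reproducible from the data alone.

    Attributes
    ----------
    m : number of pairwise comparisons (rows of the incidence matrix)
    n : number of treatments
    k : number of studies
    n_arms_total : total number of treatment arms, sum of p over studies
    """

    def __init__(
        self,
        contrasts: Iterable[Contrast],
        treatment_order: Sequence[str] | None = None,
        study_order: Sequence[str] | None = None,
    ):
        contrasts = list(contrasts)
        if not contrasts:
            raise ValidationError("network has no contrasts")

        seen_treats = {t for c in contrasts for t in (c.treat1, c.treat2)}
        seen_studies = {c.study for c in contrasts}

        if treatment_order is None:
            self.treatments = sorted(seen_treats)
        else:
            treatment_order = list(treatment_order)
            missing = seen_treats - set(treatment_order)
            if missing:
                raise ValidationError(
                    f"treatment_order is missing treatments: {sorted(missing)}"
                )
            self.treatments = treatment_order
        if study_order is None:
            self.studies = sorted(seen_studies, key=str)
        else:
            study_order = list(study_order)
            missing = seen_studies - set(study_order)
            if missing:
                raise ValidationError(f"study_order is missing studies: {sorted(missing)}")
            self.studies = study_order

        s_pos = {s: i for i, s in enumerate(self.studies)}
        t_pos = {t: i for i, t in enumerate(self.treatments)}
        self.contrasts = sorted(
            contrasts,
            key=lambda c: (s_pos[c.study], t_pos[c.treat1], t_pos[c.treat2]),
        )

        self._validate_multiarm_expansion()

    def _validate_multiarm_expansion(self) -> None:
        pairs_by_study: dict[str, set[frozenset]] = {}
        arms_by_study: dict[str, set[str]] = {}
        for c in self.contrasts:
            pair = frozenset((c.treat1, c.treat2))
            pairs = pairs_by_study.setdefault(c.study, set())
            if pair in pairs:
                raise ValidationError(
                    f"study {c.study!r}: duplicate comparison {set(pair)}"
                )
            pairs.add(pair)
            arms_by_study.setdefault(c.study, set()).update(pair)

        self.arms_per_study: dict[str, int] = {}
        for study, arms in arms_by_study.items():
            p = len(arms)
            expected = p * (p - 1) // 2
            got = len(pairs_by_study[study])
            if got != expected:
                raise ValidationError(
                    f"study {study!r} involves {p} treatments but has {got} "
                    f"contrasts; a {p}-arm study must contribute exactly "
                    f"{expected} pairwise contrasts"
                )
            self.arms_per_study[study] = p

    # -- sizes ---------------------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.contrasts)

    @property
    def n(self) -> int:
        return len(self.treatments)

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def n_arms_total(self) -> int:
        return sum(self.arms_per_study.values())

    # -- vector views --------------------------------------------------------
    @property
    def effects(self) -> np.ndarray:
        return np.array([c.effect for c in self.contrasts], dtype=float)

    @property
    def se(self) -> np.ndarray:
        return np.array([c.se for c in self.contrasts], dtype=float)

    @property
    def se_adjusted(self) -> np.ndarray:
        if any(c.se_adjusted is None for c in self.contrasts):
            raise ValidationError(
                "se_adjusted not set; run adjust_multiarm() first"
            )
        return np.array([c.se_adjusted for c in self.contrasts], dtype=float)

    @property
    def is_adjusted(self) -> bool:
        return all(c.se_adjusted is not None for c in self.contrasts)

    def study_index(self) -> np.ndarray:
        """Integer study id per contrast row (position in ``studies``)."""
        pos = {s: i for i, s in enumerate(self.studies)}
        return np.array([pos[c.study] for c in self.contrasts], dtype=int)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        g.add_edges_from((c.treat1, c.treat2) for c in self.contrasts)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph())

    def with_contrasts(self, contrasts: Iterable[Contrast]) -> "Network":
        return Network(contrasts, treatment_order=self.treatments, study_order=self.studies)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study": [c.study for c in self.contrasts],
                "treat1": [c.treat1 for c in self.contrasts],
                "treat2": [c.treat2 for c in self.contrasts],
                "effect": self.effects,
                "se": self.se,
                "se_adjusted": [c.se_adjusted for c in self.contrasts],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Network(m={self.m} comparisons, n={self.n} treatments, "
            f"k={self.k} studies, n_arms={self.n_arms_total})"
        )


def _resolve_columns(df: pd.DataFrame, aliases: Mapping[str, tuple]) -> pd.DataFrame:
    lower = {str(c).strip().lower(): c for c in df.columns}
    mapping = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lower:
                mapping[canonical] = lower[name]
                break
        else:
            raise InputFormatError(
                f"required column {canonical!r} not found "
                f"(accepted names: {', '.join(names)}; got {list(df.columns)})"
            )
    return df.rename(columns={v: k for k, v in mapping.items()})[list(aliases)]


def _read_table(source) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting comma/tab/semicolon."""
    if isinstance(source, pd.DataFrame):
        return source
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    header = text.splitlines()[0] if text else ""
    counts = {sep: header.count(sep) for sep in (",", "\t", ";")}
    sep = max(counts, key=counts.get)
    if counts[sep] == 0:
        raise InputFormatError("could not detect a delimiter (comma/tab/semicolon)")
    return pd.read_csv(io.StringIO(text), sep=sep)


def read_contrasts(
    source,
    treatment_order: Sequence[str] | None = None,
    study_order: Sequence[str] | None = None,
) -> Network:
    """Build a :class:`Network` from a contrast-level table.

    ``source`` may be a path to a CSV/TSV/semicolon-delimited file, an open
    text handle, or a DataFrame with columns study, treat1, treat2,
    effect (``TE``) and se (``seTE``).
    """
    df = _resolve_columns(_read_table(source), _CONTRAST_ALIASES)
    contrasts = []
    for row in df.itertuples(index=False):
        try:
            effect = float(row.effect)
            se = float(row.se)
        except (TypeError, ValueError) as exc:
            raise InputFormatError(
                f"study {row.study!r}: effect/se not parseable ({row.effect!r}, {row.se!r})"
            ) from exc
        contrasts.append(
            Contrast(str(row.study), str(row.treat1).strip(), str(row.treat2).strip(), effect, se)
        )
    return Network(contrasts, treatment_order=treatment_order, study_order=study_order)


def contrasts_from_arms(
    source,
    treatment_order: Sequence[str] | None = None,
    study_order: Sequence[str] | None = None,
) -> Network:
    """Convert arm-level binary outcome data to a log odds ratio network.

    Expects columns study, treatment, events, n. Every within-study
    treatment pair contributes one contrast with

        effect = log[(a/(n1-a)) / (b/(n2-b))],
        se     = sqrt(1/a + 1/(n1-a) + 1/b + 1/(n2-b)).

    If any of the four cells of a 2x2 table is zero, 0.5 is added to all
    four cells of that comparison (per-comparison continuity correction).
    """
    df = _resolve_columns(_read_table(source), _ARM_ALIASES)
    contrasts = []
    for study, grp in df.groupby("study", sort=False):
        if len(grp) < 2:
            raise ValidationError(f"study {study!r} has a single arm")
        if grp["treatment"].duplicated().any():
            raise ValidationError(f"study {study!r}: duplicate treatment arm")
        arms = []
        for row in grp.itertuples(index=False):
            events, n = float(row.events), float(row.n)
            if events < 0 or n <= events:
                raise ValidationError(
                    f"study {study!r} arm {row.treatment!r}: need 0 <= events < n, "
                    f"got events={row.events}, n={row.n}"
                )
            arms.append((str(row.treatment).strip(), events, n))
        arms.sort(key=lambda a: a[0])
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                (t1, a, n1), (t2, b, n2) = arms[i], arms[j]
                cells = np.array([a, n1 - a, b, n2 - b], dtype=float)
                if np.any(cells == 0):
                    cells = cells + 0.5
                a_, c_, b_, d_ = cells
                effect = float(np.log((a_ / c_) / (b_ / d_)))
                se = float(np.sqrt(np.sum(1.0 / cells)))
                contrasts.append(Contrast(str(study), t1, t2, effect, se))
    return Network(contrasts, treatment_order=treatment_order, study_order=study_order)


def build_incidence(network: Network) -> np.ndarray:
    """The m x n edge-vertex incidence matrix B.

    Row j has +1 in the column of ``treat1`` and -1 in the column of
    ``treat2`` of comparison j; the product B @ theta maps treatment-level
    effects onto contrasts.
    """
    t_pos = {t: i for i, t in enumerate(network.treatments)}
    B = np.zeros((network.m, network.n))
    for j, c in enumerate(network.contrasts):
        B[j, t_pos[c.treat1]] = 1.0
        B[j, t_pos[c.treat2]] = -1.0
    return B


def _adjust_study(
    pairs: list[tuple[int, int]], variances: np.ndarray, p: int, label: str, tol: float
) -> np.ndarray:
    """Adjusted contrast variances for one p-arm study.

    Recovers arm-level variances s_i^2 from the p(p-1)/2 observed contrast
    variances via least squares on v_jk = s_j^2 + s_k^2, then rebuilds
    contrast weights from the arm-level GLS information matrix:
    w_jk = (1/s_j^2)(1/s_k^2) / sum_i 1/s_i^2.
    """
    M = np.zeros((len(pairs), p))
    for row, (i, j) in enumerate(pairs):
        M[row, i] = 1.0
        M[row, j] = 1.0
    s2, *_ = np.linalg.lstsq(M, variances, rcond=None)
    resid = M @ s2 - variances
    if np.max(np.abs(resid)) > tol * max(np.max(variances), 1.0):
        warnings.warn(
            f"study {label!r}: contrast variances are not consistent with an "
            f"arm-based decomposition (max residual {np.max(np.abs(resid)):.3g}); "
            "using the least-squares reconciliation",
            stacklevel=3,
        )
    if np.any(s2 <= 0):
        raise ValidationError(
            f"study {label!r}: implied arm variance is not positive "
            f"({np.round(s2, 6).tolist()}); contrast variances are incompatible"
        )
    w_arm = 1.0 / s2
    total = w_arm.sum()
    adjusted = np.empty(len(pairs))
    for row, (i, j) in enumerate(pairs):
        adjusted[row] = total / (w_arm[i] * w_arm[j])
    return adjusted


def adjust_multiarm(network: Network, tau2: float = 0.0, tol: float = 1e-8) -> Network:
    """Set ``se_adjusted`` on every contrast.

    Two-arm studies are unchanged (up to the ``tau2`` inflation). For a
    p-arm study (p >= 3) the p(p-1)/2 correlated contrasts are re-weighted
    so that the study's contribution to the network information matrix
    equals that of a generalized least squares fit on its arms. With
    ``tau2 > 0`` the heterogeneity variance is added to each raw sampling
    variance before the adjustment, as required for random-effects weights.
    """
    if tau2 < 0:
        raise ValidationError(f"tau2 must be nonnegative, got {tau2}")
    by_study: dict[str, list[Contrast]] = {}
    for c in network.contrasts:
        by_study.setdefault(c.study, []).append(c)

    new = []
    for study, rows in by_study.items():
        if len(rows) == 1:
            (c,) = rows
            se_adj = c.se if tau2 == 0 else float(np.sqrt(c.se**2 + tau2))
            new.append(replace(c, se_adjusted=se_adj))
            continue
        arms = sorted({t for c in rows for t in (c.treat1, c.treat2)})
        pos = {t: i for i, t in enumerate(arms)}
        pairs = [(pos[c.treat1], pos[c.treat2]) for c in rows]
        variances = np.array([c.se**2 + tau2 for c in rows])
        adjusted = _adjust_study(pairs, variances, len(arms), study, tol)
        new.extend(
            replace(c, se_adjusted=float(np.sqrt(v))) for c, v in zip(rows, adjusted)
        )
    return network.with_contrasts(new)


def build_weights(network: Network, tau2: float = 0.0) -> np.ndarray:
    """The m x m diagonal weight matrix W.

    For ``tau2 = 0`` the weights are the inverse squared multi-arm-adjusted
    standard errors. For ``tau2 > 0`` the heterogeneity variance is added
    to each raw sampling variance and the multi-arm adjustment re-run
    before inverting.
    """
    adjusted = adjust_multiarm(network, tau2=tau2)
    return np.diag(1.0 / adjusted.se_adjusted**2)
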