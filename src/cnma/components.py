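"""Treatment -> component combination structure (matrix C).

Treatments are parsed into components by splitting their labels on a
separator, e.g. ``"Face-to-face CBT + SSRI"`` with separator ``"+"`` has
components ``Face-to-face CBT`` and ``SSRI``. The combination matrix C is
n x c with C[i, j] > 0 when component j contributes to treatment i
(entries above 1 encode dose multiples). An inactive treatment (placebo,
usual care) is modelled as an all-zero row: it contributes no component,
which is a modelling assumption, stronger than merely choosing it as the
reference of the parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["ComponentStructure", "build_combination", "add_interactions"]


@dataclass(frozen=True)
class ComponentStructure:
    """Component labels and the n x c combination matrix C.

    Rows follow ``treatments``, columns follow ``components``. Interaction
    columns (labelled ``"A*B"``) may be appended by
    :func:`add_interactions`.
    """

    treatments: tuple[str, ...]
    components: tuple[str, ...]
    C: np.ndarray
    inactive: str | None = None
    separator: str = "+"

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", C)
        if C.shape != (len(self.treatments), len(self.components)):
            raise ValidationError(
                f"C has shape {C.shape}, expected "
                f"({len(self.treatments)}, {len(self.components)})"
            )
        if np.any(C < 0):
            raise ValidationError("combination matrix entries must be nonnegative")
        zero_cols = [
            comp for j, comp in enumerate(self.components) if not C[:, j].any()
        ]
        if zero_cols:
            raise ValidationError(
                f"component column(s) {zero_cols} are all zero: the component "
                "occurs in no treatment and cannot be estimated"
            )
        if self.inactive is not None:
            if self.inactive not in self.treatments:
                raise ValidationError(f"inactive treatment {self.inactive!r} unknown")
            row = C[self.treatments.index(self.inactive)]
            if row.any():
                raise ValidationError(
                    f"inactive treatment {self.inactive!r} must have an all-zero row"
                )

    @property
    def c(self) -> int:
        return len(self.components)

    def row(self, treatment: str) -> np.ndarray:
        return self.C[self.treatments.index(treatment)]

    def subset(self, treatments: Sequence[str]) -> "ComponentStructure":
        """Restrict to a subset of treatments, dropping components that no
        longer occur (used when fitting a subnetwork)."""
        rows = [self.treatments.index(t) for t in treatments]
        C = self.C[rows]
        keep = [j for j in range(self.c) if C[:, j].any()]
        return ComponentStructure(
            treatments=tuple(treatments),
            components=tuple(self.components[j] for j in keep),
            C=C[:, keep],
            inactive=self.inactive if self.inactive in treatments else None,
            separator=self.separator,
        )

    def drop_component(self, component: str) -> "ComponentStructure":
        """Remove one component column (reference-component parameterization
        for disconnected fits)."""
        if component not in self.components:
            raise ValidationError(f"component {component!r} unknown")
        keep = [j for j, comp in enumerate(self.components) if comp != component]
        return ComponentStructure(
            treatments=self.treatments,
            components=tuple(self.components[j] for j in keep),
            C=self.C[:, keep],
            inactive=self.inactive,
            separator=self.separator,
        )


def _parse(label: str, separator: str) -> list[str]:
    tokens = [tok.strip() for tok in label.split(separator)]
    if any(not tok for tok in tokens):
        raise ValidationError(
            f"treatment label {label!r} parses to an empty component token"
        )
    return tokens


def build_combination(
    treatments: Sequence[str],
    separator: str = "+",
    inactive: str | None = None,
    doses: Mapping[str, Mapping[str, float]] | None = None,
) -> ComponentStructure:
    """Parse treatment labels into a :class:`ComponentStructure`.

    Components are the distinct label tokens, sorted, minus the inactive
    treatment's label. ``doses`` maps a treatment label to an explicit
    ``{component: multiplier}`` composition, overriding token parsing —
    e.g. ``{"A double": {"A": 2}}`` codes a doubled dose as twice the
    component effect.
    """
    if not separator:
        raise ValidationError("separator must be a nonempty string")
    if inactive is not None:
        if inactive not in treatments:
            raise ValidationError(f"inactive treatment {inactive!r} is not a treatment")
        if separator in inactive and len(_parse(inactive, separator)) > 1:
            raise ValidationError(
                f"inactive label {inactive!r} contains the separator {separator!r}"
            )
    doses = dict(doses or {})
    unknown = set(doses) - set(treatments)
    if unknown:
        raise ValidationError(f"dose spec names unknown treatments: {sorted(unknown)}")

    composition: dict[str, dict[str, float]] = {}
    for t in treatments:
        if t == inactive:
            composition[t] = {}
        elif t in doses:
            composition[t] = {comp: float(mult) for comp, mult in doses[t].items()}
        else:
            composition[t] = {}
            for tok in _parse(t, separator):
                composition[t][tok] = composition[t].get(tok, 0.0) + 1.0

    components = sorted({comp for comp_map in composition.values() for comp in comp_map})
    C = np.zeros((len(treatments), len(components)))
    pos = {comp: j for j, comp in enumerate(components)}
    for i, t in enumerate(treatments):
        for comp, mult in composition[t].items():
            C[i, pos[comp]] = mult
    return ComponentStructure(
        treatments=tuple(treatments),
        components=tuple(components),
        C=C,
        inactive=inactive,
        separator=separator,
    )


def add_interactions(
    comps: ComponentStructure, pairs: Sequence[Sequence[str]]
) -> ComponentStructure:
    """Append one interaction column per requested component set.

    The column for ``(A, B)`` is labelled ``"A*B"`` (components sorted) and
    has entry 1 for every treatment containing all components of the set;
    three-way and higher sets work the same way. A set that co-occurs in
    no treatment would give an all-zero, inestimable column and is
    rejected.
    """
    C = comps.C
    new_cols = []
    new_labels = []
    for pair in pairs:
        members = sorted(set(pair))
        if len(members) < 2:
            raise ValidationError(f"interaction {pair!r} needs at least two components")
        idx = []
        for comp in members:
            if comp not in comps.components:
                raise ValidationError(f"interaction names unknown component {comp!r}")
            idx.append(comps.components.index(comp))
        col = np.all(C[:, idx] > 0, axis=1).astype(float)
        label = "*".join(members)
        if not col.any():
            raise ValidationError(
                f"interaction {label!r} occurs in no treatment; the column would "
                "be all zero"
            )
        if label in comps.components or label in new_labels:
            raise ValidationError(f"interaction {label!r} already present")
        new_cols.append(col)
        new_labels.append(label)
    return ComponentStructure(
        treatments=comps.treatments,
        components=comps.components + tuple(new_labels),
        C=np.column_stack([C] + new_cols) if new_cols else C,
        inactive=comps.inactive,
        separator=comps.separator,
    )
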