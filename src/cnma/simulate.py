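"""Synthetic evidence networks with known component truth.

The generator emulates the structure of combination-treatment data sets
such as the depression network: an inactive reference (placebo), single-
and multi-component treatments, a majority of two-arm studies with some
three-arm studies, and log-odds-ratio-sized effects and standard errors.

Randomness enters at the arm level, which keeps the draws compatible
with the model being fitted:

* a per-arm random effect u_i ~ N(0, tau2/2), so every contrast carries
  marginal heterogeneity variance tau2, contrasts sharing an arm have
  heterogeneity covariance tau2/2 (the 0.5*BB' block structure the
  moment estimator assumes), and within-study consistency of the
  contrast means holds exactly;
* a per-arm sampling error e_i ~ N(0, sigma_i^2), so multi-arm contrasts
  are correlated exactly as the multi-arm weight adjustment assumes,
  with recorded contrast standard error sqrt(sigma_i^2 + sigma_j^2).
"""

from __future__ import annotations

import itertools

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .components import ComponentStructure, add_interactions, build_combination
from .errors import ValidationError
from .network import Contrast, Network

__all__ = [
    "SimSpec",
    "SimResult",
    "simulate",
    "depression_like_spec",
    "random_connected_network",
]

#: default component truth, log odds ratio scale (ORs ~ 1.2 to 1.8)
_DEFAULT_COMPONENTS = {"A": 0.55, "B": 0.35, "C": 0.15}
_DEFAULT_TREATMENTS = ("placebo", "A", "B", "C", "A+B", "A+C", "B+C")


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated network.

    ``components`` maps component labels to their true additive effects
    beta* (vs the inactive reference); ``interactions`` maps interaction
    labels ("A*B") to true synergy terms gamma (zero means the truth is
    additive). Studies are either given explicitly as tuples of treatment
    labels or drawn: ``k_studies`` studies whose arm counts are sampled
    from ``arms`` (with replacement) and whose treatments are sampled
    uniformly without replacement.
    """

    components: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMPONENTS)
    )
    treatments: Sequence[str] = _DEFAULT_TREATMENTS
    interactions: Mapping[str, float] = field(default_factory=dict)
    studies: Sequence[Sequence[str]] | None = None
    k_studies: int = 30
    arms: Sequence[int] = (2, 2, 2, 2, 3)
    se_range: tuple[float, float] = (0.2, 0.5)
    tau2_true: float = 0.0
    separator: str = "+"
    inactive: str | None = "placebo"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ValidationError(f"se_range lower bound must be positive, got {self.se_range}")
        if self.tau2_true < 0:
            raise ValidationError("tau2_true must be nonnegative")
        comp_structure = self.component_structure()
        for comp in self.components:
            if comp not in comp_structure.components:
                raise ValidationError(
                    f"component {comp!r} appears in no treatment"
                )

    def component_structure(self) -> ComponentStructure:
        """The additive structure (no interaction columns) of the
        simulated treatments, in sorted treatment order."""
        return build_combination(
            sorted(self.treatments), separator=self.separator, inactive=self.inactive
        )

    def true_theta(self) -> dict[str, float]:
        """True treatment effects vs the inactive reference, additive plus
        any interaction truth."""
        comps = self.component_structure()
        if self.interactions:
            pairs = [lab.split("*") for lab in self.interactions]
            comps = add_interactions(comps, pairs)
        beta = np.array(
            [
                self.components.get(c, self.interactions.get(c, 0.0))
                for c in comps.components
            ]
        )
        theta = comps.C @ beta
        return dict(zip(comps.treatments, theta))


@dataclass(frozen=True)
class SimResult:
    network: Network
    comps: ComponentStructure
    beta_true: np.ndarray        # over comps.components
    theta_true: dict[str, float]
    seed: int


def _draw_designs(spec: SimSpec, rng: np.random.Generator) -> list[tuple[str, ...]]:
    treatments = list(spec.treatments)
    for attempt in range(200):
        designs = []
        for _ in range(spec.k_studies):
            p = int(rng.choice(spec.arms))
            if p > len(treatments):
                raise ValidationError(
                    f"cannot draw a {p}-arm study from {len(treatments)} treatments"
                )
            picked = rng.choice(len(treatments), size=p, replace=False)
            designs.append(tuple(treatments[i] for i in sorted(picked)))
        edges = {frozenset(pair) for des in designs for pair in zip(des, des[1:])}
        import networkx as nx

        g = nx.Graph(tuple(e) for e in edges)
        g.add_nodes_from(treatments)
        if nx.is_connected(g):
            return designs
    raise ValidationError(
        "could not draw a connected design in 200 attempts; increase k_studies"
    )


def simulate(spec: SimSpec, seed: int | None = None) -> SimResult:
    """Draw one network under the spec's study conditions.

    Fully reproducible: the same (spec, seed) pair yields a byte-identical
    network. ``seed`` overrides ``spec.seed`` when given.
    """
    used_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    theta = spec.true_theta()

    designs = (
        [tuple(s) for s in spec.studies]
        if spec.studies is not None
        else _draw_designs(spec, rng)
    )
    for des in designs:
        if len(des) < 2 or len(set(des)) != len(des):
            raise ValidationError(f"invalid study design {des!r}")

    lo, hi = spec.se_range
    width = len(str(len(designs)))
    contrasts = []
    for s_idx, des in enumerate(designs):
        label = f"s{s_idx + 1:0{width}d}"
        arms = sorted(des)
        # per-arm sd scaled so the contrast se is the RMS of two draws
        sigma = rng.uniform(lo, hi, size=len(arms)) / np.sqrt(2.0)
        u = rng.normal(0.0, np.sqrt(spec.tau2_true / 2.0), size=len(arms))
        e = rng.normal(0.0, 1.0, size=len(arms)) * sigma
        y = np.array([theta[t] for t in arms]) + u + e
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                contrasts.append(
                    Contrast(
                        study=label,
                        treat1=arms[i],
                        treat2=arms[j],
                        effect=float(y[i] - y[j]),
                        se=float(np.sqrt(sigma[i] ** 2 + sigma[j] ** 2)),
                    )
                )

    network = Network(contrasts)
    comps = spec.component_structure()
    beta_true = np.array([spec.components.get(c, 0.0) for c in comps.components])
    return SimResult(
        network=network,
        comps=comps,
        beta_true=beta_true,
        theta_true=theta,
        seed=used_seed,
    )


def depression_like_spec(tau2_true: float = 0.02, effects_seed: int = 77) -> SimSpec:
    """Study conditions shaped like a large antidepressant network:
    placebo (inactive) plus 18 single-component treatments (drug classes
    and psychotherapies) plus three two-component combinations sharing
    the SSRI component.

    Each treatment is compared to placebo in two studies; the
    combinations are additionally compared to their components, including
    two three-arm studies. Component truths are drawn once (from
    ``effects_seed``) on the log odds ratio scale in [0, 0.7], i.e. ORs
    up to about 2. The standard-vs-additive model comparison on this
    structure has n - 1 - c = 21 - 18 = 3 degrees of freedom.
    """
    singles = [
        "TCA", "SSRI", "SNRI", "NRI", "SARI", "NaSSa", "rMAO-A", "Hypericum",
        "Ind drug", "CBT", "PST", "Interpsy", "Psychodyn", "Other f2f",
        "Remote CBT", "Self-help CBT", "No-contact CBT", "UC",
    ]
    combos = ["CBT + SSRI", "PST + SSRI", "Interpsy + SSRI"]
    rng = np.random.default_rng(effects_seed)
    beta = dict(zip(singles, np.round(rng.uniform(0.0, 0.7, len(singles)), 3)))
    studies: list[tuple[str, ...]] = []
    for t in singles + combos:
        studies.append(("placebo", t))
        studies.append(("placebo", t))
    studies += [
        ("CBT + SSRI", "SSRI"),
        ("PST", "PST + SSRI", "SSRI"),
        ("Interpsy + SSRI", "Interpsy"),
        ("TCA", "SSRI"),
        ("Hypericum", "SSRI", "placebo"),
    ]
    return SimSpec(
        components=beta,
        treatments=["placebo"] + singles + combos,
        studies=studies,
        se_range=(0.2, 0.5),
        tau2_true=tau2_true,
        inactive="placebo",
    )


def random_connected_network(
    rng: np.random.Generator,
    max_components: int = 3,
    max_treatments: int = 8,
    max_studies: int = 20,
):
    """Draw a random connected network over combination treatments.

    Treatments are non-empty subsets of up to ``max_components``
    components plus an inactive placebo; studies mix two- and three-arm
    designs. Returns (network, comps). Redraws until connected.
    """
    alphabet = ["A", "B", "C", "D"][: rng.integers(2, max_components + 1)]
    subsets = [
        "+".join(sub)
        for size in range(1, len(alphabet) + 1)
        for sub in itertools.combinations(alphabet, size)
    ]
    for _ in range(100):
        n_treat = int(rng.integers(3, min(max_treatments, len(subsets) + 1) + 1))
        picked = list(rng.choice(len(subsets), size=min(n_treat - 1, len(subsets)), replace=False))
        treatments = sorted(subsets[i] for i in picked) + ["Placebo"]
        k = int(rng.integers(max(3, len(treatments) - 1), max_studies + 1))
        contrasts = []
        for s in range(k):
            p = int(rng.choice([2, 2, 2, 3]))
            p = min(p, len(treatments))
            arms = sorted(
                treatments[i]
                for i in rng.choice(len(treatments), size=p, replace=False)
            )
            # arm-level variances keep multi-arm contrast variances
            # compatible with the arm-based decomposition
            arm_var = {a: float(rng.uniform(0.05, 1.0)) for a in arms}
            for t1, t2 in itertools.combinations(arms, 2):
                contrasts.append(
                    Contrast(
                        f"s{s:02d}",
                        t1,
                        t2,
                        float(rng.normal(0.0, 1.0)),
                        float(np.sqrt(arm_var[t1] + arm_var[t2])),
                    )
                )
        net = Network(contrasts)
        if not net.is_connected():
            continue
        inactive = "Placebo" if "Placebo" in net.treatments else None
        comps = build_combination(net.treatments, separator="+", inactive=inactive)
        return net, comps
    raise RuntimeError("failed to draw a connected network")
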