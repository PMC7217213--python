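"""Shared fixtures: the worked hypothetical networks and a random
connected-network generator used by the oracle-equivalence tests."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cnma import Contrast, Network, build_combination
from cnma.simulate import random_connected_network  # noqa: F401  (re-exported for tests)

HYPOTHETICAL_ORDER = ["A", "A+B", "A+B+C", "B+C", "Placebo"]
HYPOTHETICAL_STUDIES = [
    ("s1", "A", "A+B"),
    ("s2", "A", "A+B+C"),
    ("s3", "A+B", "B+C"),
    ("s4", "A+B", "A+B+C"),
    ("s5", "B+C", "A+B+C"),
    ("s6", "A", "Placebo"),
]


def hypothetical_network(effects=None, se=None) -> Network:
    """The six-study, five-treatment hypothetical combination network."""
    effects = effects if effects is not None else [0.5] * 6
    se = se if se is not None else [1.0] * 6
    contrasts = [
        Contrast(s, t1, t2, float(d), float(e))
        for (s, t1, t2), d, e in zip(HYPOTHETICAL_STUDIES, effects, se)
    ]
    return Network(
        contrasts,
        treatment_order=HYPOTHETICAL_ORDER,
        study_order=[s for s, _, _ in HYPOTHETICAL_STUDIES],
    )


@pytest.fixture
def hypothetical():
    return hypothetical_network()


@pytest.fixture
def hypothetical_comps():
    return build_combination(HYPOTHETICAL_ORDER, separator="+", inactive="Placebo")


DISCONNECTED_ORDER = ["A", "B", "C", "B+C", "A+C", "A+B"]


@pytest.fixture
def disconnected_three():
    """Three two-arm studies, each its own subnet: A vs B+C; B vs A+C;
    A+B vs C."""
    contrasts = [
        Contrast("s1", "A", "B+C", 1.0, 1.0),
        Contrast("s2", "B", "A+C", 0.5, 1.0),
        Contrast("s3", "A+B", "C", 0.8, 1.0),
    ]
    return Network(contrasts, treatment_order=DISCONNECTED_ORDER)


@pytest.fixture
def disconnected_reduced():
    """Studies 1 and 3 only: treatments A, C, B+C, A+B; X_a has rank 2."""
    contrasts = [
        Contrast("s1", "A", "B+C", 1.0, 1.0),
        Contrast("s3", "A+B", "C", 0.8, 1.0),
    ]
    return Network(contrasts, treatment_order=["A", "C", "B+C", "A+B"])
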