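"""Network construction: IO, incidence, multi-arm adjustment, weights."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest

from cnma import (
    Contrast,
    InputFormatError,
    Network,
    ValidationError,
    adjust_multiarm,
    build_incidence,
    build_weights,
    contrasts_from_arms,
    read_contrasts,
)
from conftest import HYPOTHETICAL_ORDER, hypothetical_network


class TestReadContrasts:
    def test_hypothetical_csv_sizes(self):
        rows = ["study,treat1,treat2,TE,seTE"]
        for s, t1, t2 in [
            ("1", "A", "A+B"), ("2", "A", "A+B+C"), ("3", "A+B", "B+C"),
            ("4", "A+B", "A+B+C"), ("5", "B+C", "A+B+C"), ("6", "A", "Placebo"),
        ]:
            rows.append(f"{s},{t1},{t2},0.5,1.0")
        net = read_contrasts(io.StringIO("\n".join(rows)))
        assert (net.n, net.m, net.k) == (5, 6, 6)
        assert all(p == 2 for p in net.arms_per_study.values())

    def test_minimal_and_three_arm(self):
        net = read_contrasts(io.StringIO("study\ttreat1\ttreat2\teffect\tse\ns1\tA\tP\t0.5\t1.0"))
        assert (net.n, net.m) == (2, 1)
        rows = "study;treat1;treat2;TE;seTE\ns;A;B;1;1\ns;A;C;1;1\ns;B;C;0;1"
        net3 = read_contrasts(io.StringIO(rows))
        assert net3.m == 3 and net3.arms_per_study["s"] == 3

    def test_missing_column_rejected(self):
        with pytest.raises(InputFormatError, match="se"):
            read_contrasts(io.StringIO("study,treat1,treat2,TE\ns,A,B,1"))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            read_contrasts(io.StringIO("study,treat1,treat2,TE,seTE\ns,A,B,1,0"))

    def test_duplicate_comparison_rejected(self):
        text = "study,treat1,treat2,TE,seTE\ns,A,B,1,1\ns,B,A,2,1"
        with pytest.raises(ValidationError, match="duplicate"):
            read_contrasts(io.StringIO(text))

    def test_incomplete_multiarm_expansion_rejected(self):
        text = "study,treat1,treat2,TE,seTE\ns,A,B,1,1\ns,B,C,1,1"
        with pytest.raises(ValidationError, match="3-arm"):
            read_contrasts(io.StringIO(text))

    def test_default_ordering_is_lexicographic(self):
        text = "study,treat1,treat2,TE,seTE\ns2,Z,M,1,1\ns1,B,Z,1,1\ns1,A,B,0,1\ns1,A,Z,1,1"
        net = read_contrasts(io.StringIO(text))
        assert net.treatments == ["A", "B", "M", "Z"]
        assert net.studies == ["s1", "s2"]


class TestContrastsFromArms:
    def test_symmetric_table_gives_zero_logor(self):
        df = pd.DataFrame(
            {"study": ["s", "s"], "treatment": ["A", "B"], "events": [10, 10], "n": [20, 20]}
        )
        net = contrasts_from_arms(df)
        assert net.contrasts[0].effect == pytest.approx(0.0)
        assert net.contrasts[0].se == pytest.approx(np.sqrt(0.4))

    def test_hand_computed_two_by_two(self):
        df = pd.DataFrame(
            {"study": ["s", "s"], "treatment": ["A", "B"], "events": [15, 5], "n": [20, 20]}
        )
        net = contrasts_from_arms(df)
        assert net.contrasts[0].effect == pytest.approx(np.log(9.0), abs=1e-12)
        assert net.contrasts[0].se == pytest.approx(
            np.sqrt(1 / 15 + 1 / 5 + 1 / 5 + 1 / 15), abs=1e-12
        )

    def test_three_arm_within_study_consistency(self):
        df = pd.DataFrame(
            {
                "study": ["s"] * 3,
                "treatment": ["x", "y", "z"],
                "events": [12, 8, 15],
                "n": [30, 25, 40],
            }
        )
        net = contrasts_from_arms(df)
        assert net.m == 3
        d = {(c.treat1, c.treat2): c.effect for c in net.contrasts}
        assert d[("x", "y")] + d[("y", "z")] == pytest.approx(d[("x", "z")], abs=1e-12)

    def test_zero_cell_continuity_correction(self):
        df = pd.DataFrame(
            {"study": ["s", "s"], "treatment": ["A", "B"], "events": [0, 5], "n": [10, 10]}
        )
        net = contrasts_from_arms(df)
        expected = np.log((0.5 / 10.5) / (5.5 / 5.5))
        assert net.contrasts[0].effect == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "events,n,match",
        [([5], [10], "single arm"), ([5, 12], [10, 12], "events < n")],
    )
    def test_invalid_arm_tables_rejected(self, events, n, match):
        df = pd.DataFrame(
            {
                "study": ["s"] * len(events),
                "treatment": list("AB")[: len(events)],
                "events": events,
                "n": n,
            }
        )
        with pytest.raises(ValidationError):
            contrasts_from_arms(df)


class TestIncidence:
    def test_hypothetical_matrix_matches_print(self):
        B = build_incidence(hypothetical_network())
        expected = np.array(
            [
                [1, -1, 0, 0, 0],
                [1, 0, -1, 0, 0],
                [0, 1, 0, -1, 0],
                [0, 1, -1, 0, 0],
                [0, 0, -1, 1, 0],
                [1, 0, 0, 0, -1],
            ],
            dtype=float,
        )
        np.testing.assert_array_equal(B, expected)

    def test_single_study(self):
        net = Network([Contrast("s", "A", "P", 0.5, 1.0)], treatment_order=["A", "P"])
        np.testing.assert_array_equal(build_incidence(net), [[1.0, -1.0]])

    def test_row_sums_vanish(self):
        B = build_incidence(hypothetical_network())
        np.testing.assert_array_equal(B.sum(axis=1), np.zeros(6))


def _equal_variance_study(p: int, v: float = 1.0) -> Network:
    arms = [f"T{i}" for i in range(p)]
    contrasts = [
        Contrast("s", a, b, 0.1, np.sqrt(v)) for a, b in itertools.combinations(arms, 2)
    ]
    return Network(contrasts)


class TestAdjustMultiarm:
    def test_two_arm_bit_identical(self):
        net = Network([Contrast("s", "A", "P", 0.5, 0.731)])
        adj = adjust_multiarm(net)
        assert adj.contrasts[0].se_adjusted == 0.731

    @pytest.mark.parametrize("p,factor", [(3, 1.5), (4, 2.0)])
    def test_equal_variance_factor(self, p, factor):
        v = 0.49
        adj = adjust_multiarm(_equal_variance_study(p, v))
        for c in adj.contrasts:
            assert c.se_adjusted**2 == pytest.approx(factor * v, rel=1e-12)

    @pytest.mark.parametrize("p", [2, 3, 4, 5])
    def test_information_matrix_matches_arm_level_gls(self, p):
        """Adjusted edge weights reproduce the arm-level GLS information
        matrix L = diag(w) - w w' / sum(w) exactly."""
        rng = np.random.default_rng(p)
        arms = [f"T{i}" for i in range(p)]
        s2 = rng.uniform(0.2, 1.0, size=p)  # arm variances
        contrasts = [
            Contrast("s", arms[i], arms[j], 0.0, float(np.sqrt(s2[i] + s2[j])))
            for i, j in itertools.combinations(range(p), 2)
        ]
        net = Network(contrasts)
        adj = adjust_multiarm(net)
        # graph Laplacian from the adjusted weights
        L = np.zeros((p, p))
        pos = {a: i for i, a in enumerate(net.treatments)}
        for c in adj.contrasts:
            w = 1.0 / c.se_adjusted**2
            i, j = pos[c.treat1], pos[c.treat2]
            L[i, i] += w
            L[j, j] += w
            L[i, j] -= w
            L[j, i] -= w
        w_arm = 1.0 / s2[[net.treatments.index(a) for a in arms]]
        # oracle: GLS information of p independent arms vs their mean
        order = [arms.index(t) for t in net.treatments]
        w_arm = (1.0 / s2)[order]
        L_gls = np.diag(w_arm) - np.outer(w_arm, w_arm) / w_arm.sum()
        np.testing.assert_allclose(L, L_gls, atol=1e-12)

    def test_idempotent(self):
        net = adjust_multiarm(_equal_variance_study(3))
        again = adjust_multiarm(net)
        assert [c.se_adjusted for c in net.contrasts] == [
            c.se_adjusted for c in again.contrasts
        ]

    def test_inconsistent_variances_warn(self):
        contrasts = [
            Contrast("s", "A", "B", 0.0, 1.0),
            Contrast("s", "A", "C", 0.0, 1.0),
            Contrast("s", "B", "C", 0.0, 1.3),
        ]
        # consistent decomposition exists (arm variances 0.345/0.655/...)
        adjust_multiarm(Network(contrasts))  # no warning expected
        bad = [
            Contrast("s", "A", "B", 0.0, 1.0),
            Contrast("s", "A", "C", 0.0, 1.0),
            Contrast("s", "A", "D", 0.0, 1.0),
            Contrast("s", "B", "C", 0.0, 1.0),
            Contrast("s", "B", "D", 0.0, 1.0),
            Contrast("s", "C", "D", 0.0, 1.2),
        ]
        with pytest.warns(UserWarning, match="reconciliation"):
            adjust_multiarm(Network(bad))

    def test_negative_implied_arm_variance_rejected(self):
        contrasts = [
            Contrast("s", "A", "B", 0.0, 0.1),
            Contrast("s", "A", "C", 0.0, 1.0),
            Contrast("s", "B", "C", 0.0, 1.0),
        ]
        # v_AB tiny but v_AC, v_BC large -> s_C^2 ~ 1, s_A^2+s_B^2 = 0.01
        # still solvable; make it infeasible instead:
        contrasts = [
            Contrast("s", "A", "B", 0.0, 1.0),
            Contrast("s", "A", "C", 0.0, 0.1),
            Contrast("s", "B", "C", 0.0, 0.1),
        ]
        with pytest.raises(ValidationError, match="arm variance"):
            adjust_multiarm(Network(contrasts))


class TestBuildWeights:
    def test_common_effect_weights(self):
        net = Network([Contrast("s", "A", "P", 0.5, 2.0)])
        np.testing.assert_allclose(build_weights(net, 0.0), [[0.25]])

    def test_tau2_added_to_raw_variance(self):
        net = Network([Contrast("s", "A", "P", 0.5, 1.0)])
        np.testing.assert_allclose(build_weights(net, 1.0), [[0.5]])

    def test_tau2_added_before_multiarm_adjustment(self):
        tau2 = 0.3
        v = 1.0
        W = build_weights(_equal_variance_study(3, v), tau2)
        # equal-variance 3-arm: adjusted variance 1.5 * (v + tau2)
        np.testing.assert_allclose(np.diag(W), 1.0 / (1.5 * (v + tau2)))
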