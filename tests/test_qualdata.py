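"""Statement grammar, ordering semantics, and the logistic/hinge scores."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from mekfit.qualdata import (
    Condition,
    QualStatement,
    TrajectoryBank,
    delta,
    heaviside_prediction,
    parse_statements,
    qual_neg_loglik,
    qual_penalty,
    sigmoid_prob,
    write_statements,
)
from conftest import make_trajectory


def bank_with(values: dict[str, dict[str, list[float]]], times=(0.0, 300.0, 1800.0)):
    """TrajectoryBank from per-variant species series."""
    return TrajectoryBank({
        v: make_trajectory(times, series) for v, series in values.items()
    })


def stmt(va, ta, vb, tb, z, obs="ERK_pp", scale=1.0):
    return QualStatement(side_a=Condition(va, obs, ta),
                         side_b=Condition(vb, obs, tb), z=z, scale=scale)


class TestParsing:
    def test_cross_variant_statement(self):
        out = parse_statements(
            "WT.MEK_pRDS at time = 300 < N78G.MEK_pRDS at time = 300")
        (s,) = out
        assert s.side_a == Condition("WT", "MEK_pRDS", 300.0)
        assert s.side_b == Condition("N78G", "MEK_pRDS", 300.0)
        assert s.z == 0

    def test_cross_time_statement_and_space_after_dot(self):
        text = ("KO.MEK_pRDS at time = 300 > KO.MEK_pRDS at time = 1800\n"
                "N78G. MEK_pRDS at time = 300 > T292D.MEK_pRDS at time = 300\n")
        a, b = parse_statements(text)
        assert a.z == 1 and a.side_a.variant == a.side_b.variant == "KO"
        assert b.side_a == Condition("N78G", "MEK_pRDS", 300.0)

    def test_comments_and_blank_lines_skipped(self):
        text = "# header\n\nWT.ERK_pp at time = 300 > KO.ERK_pp at time = 300\n"
        out = parse_statements(text)
        assert len(out) == 1 and out[0].line == 3

    @pytest.mark.parametrize("bad", [
        "WT.MEK_pRDS at 300 < N78G.MEK_pRDS at time = 300",  # missing "time ="
        "WT.MEK_pRDS at time = 300 <= N78G.MEK_pRDS at time = 300",  # bad relation
        "WT.MEK_pRDS at time = 300",  # one-sided
    ])
    def test_malformed_lines_report_line_number(self, bad):
        with pytest.raises(ValueError, match="line 1"):
            parse_statements(bad)

    def test_unknown_variant_or_observable(self):
        with pytest.raises(ValueError, match="unknown variant"):
            parse_statements("XX.ERK_pp at time = 1 > WT.ERK_pp at time = 2")
        with pytest.raises(ValueError, match="unknown observable"):
            parse_statements("WT.pAKT at time = 1 > WT.pAKT at time = 2")

    def test_round_trip_is_stable(self):
        text = ("WT.MEK_pRDS at time = 300 < N78G.MEK_pRDS at time = 300\n"
                "KO.MEK_pRDS at time = 300 > KO.MEK_pRDS at time = 1800\n")
        once = write_statements(parse_statements(text))
        twice = write_statements(parse_statements(once))
        assert once == twice == text

    def test_identical_sides_rejected(self):
        with pytest.raises(ValueError, match="must differ"):
            stmt("WT", 300.0, "WT", 300.0, z=1)


class TestDelta:
    def test_difference_and_antisymmetry(self):
        bank = bank_with({"WT": {"ERK_pp": [0, 10, 0]},
                          "KO": {"ERK_pp": [0, 4, 0]}})
        s = stmt("WT", 300.0, "KO", 300.0, z=1)
        assert delta(s, bank) == pytest.approx(6.0)
        s_swapped = stmt("KO", 300.0, "WT", 300.0, z=0)
        assert delta(s_swapped, bank) == pytest.approx(-6.0)

    def test_identical_conditions_give_zero(self):
        bank = bank_with({"WT": {"ERK_pp": [0, 7, 7]}})
        assert delta(stmt("WT", 300.0, "WT", 1800.0, z=1), bank) == pytest.approx(0.0)

    def test_missing_variant_or_time(self):
        bank = bank_with({"WT": {"ERK_pp": [0, 1, 2]}})
        with pytest.raises(KeyError, match="KO"):
            delta(stmt("KO", 300.0, "WT", 300.0, z=1), bank)
        with pytest.raises(KeyError, match="not on the simulated grid"):
            delta(stmt("WT", 42.0, "WT", 300.0, z=1), bank)


def test_heaviside_boundary_convention():
    assert heaviside_prediction(0.0) == 1
    assert heaviside_prediction(-0.1) == 0
    assert heaviside_prediction(2.0) == 1


def test_sigmoid_prob_values_and_stability():
    assert sigmoid_prob(0.0, 1.0) == pytest.approx(0.5)
    assert sigmoid_prob(1.0, 1.0) == pytest.approx(0.7310585786300049, abs=1e-12)
    tiny = sigmoid_prob(-1e4, 1.0)
    assert 0.0 <= tiny <= 1e-300
    assert sigmoid_prob(1e4, 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="positive"):
        sigmoid_prob(1.0, 0.0)


@given(st.floats(-30, 30), st.floats(0.05, 100))
@settings(deadline=None, max_examples=50)
def test_sigmoid_outcome_probabilities_sum_to_one(d, s):
    p1 = sigmoid_prob(d, s)
    p0 = math.exp(-d / s) / (1.0 + math.exp(-d / s))
    assert p0 + p1 == pytest.approx(1.0, abs=1e-12)


@given(st.floats(-30, 30), st.floats(-30, 30))
@settings(deadline=None, max_examples=50)
def test_sigmoid_strictly_increasing(a, b):
    assume(abs(a - b) > 1e-6)
    lo, hi = sorted((a, b))
    assert sigmoid_prob(lo, 2.0) < sigmoid_prob(hi, 2.0)


class TestScores:
    def scored(self, dlt, z, scale=1.0):
        # negative observables are clamped, so encode the sign via B > A
        a, b = (dlt, 0.0) if dlt >= 0 else (0.0, -dlt)
        bank = bank_with({"WT": {"ERK_pp": [0, a, b]}})
        s = stmt("WT", 300.0, "WT", 1800.0, z=z, scale=scale)
        return s, bank

    def test_neg_loglik_boundary_is_ln2(self):
        for z in (0, 1):
            s, bank = self.scored(0.0, z)
            assert qual_neg_loglik([s], bank) == pytest.approx(math.log(2), abs=1e-12)

    def test_neg_loglik_consistent_statement(self):
        s, bank = self.scored(1.0, z=1)
        assert qual_neg_loglik([s], bank) == pytest.approx(
            math.log(1 + math.exp(-1)), abs=1e-12)  # 0.313261687...

    def test_penalty_hinge_examples(self):
        s, bank = self.scored(-2.0, z=1)
        assert qual_penalty([s], bank) == pytest.approx(2.0)
        s, bank = self.scored(3.0, z=0, scale=2.0)  # w = 0.5
        assert qual_penalty([s], bank) == pytest.approx(1.5)
        s, bank = self.scored(5.0, z=1)
        assert qual_penalty([s], bank) == 0.0

    def test_penalty_zero_iff_predictions_match(self):
        rng = np.random.default_rng(0)
        for dlt in rng.normal(size=20) * 3:
            for z in (0, 1):
                s, bank = self.scored(float(dlt), z)
                pen = qual_penalty([s], bank)
                assert pen >= 0.0
                if heaviside_prediction(delta(s, bank)) == z or dlt == 0:
                    assert pen == 0.0
                else:
                    assert pen == pytest.approx(abs(dlt))

    def test_satisfaction_is_scale_free(self):
        for c in (0.5, 3.0, 1e4):
            bank = bank_with({"WT": {"ERK_pp": [0, 10 * c, 4 * c]}})
            s = stmt("WT", 300.0, "WT", 1800.0, z=1)
            assert heaviside_prediction(delta(s, bank)) == 1


def test_limit_equivalence_of_likelihood_and_penalty():
    """s * neg_loglik -> penalty as the logistic scale s -> 0 (w = 1)."""
    rng = np.random.default_rng(7)
    deltas = rng.uniform(-5, 5, size=64)
    s_small = 1e-3
    for dlt in deltas:
        a, b = (float(dlt), 0.0) if dlt >= 0 else (0.0, -float(dlt))
        for z in (0, 1):
            bank = bank_with({"WT": {"ERK_pp": [0, a, b]}})
            st_like = stmt("WT", 300.0, "WT", 1800.0, z=z, scale=s_small)
            st_pen = stmt("WT", 300.0, "WT", 1800.0, z=z, scale=1.0)
            gap = abs(s_small * qual_neg_loglik([st_like], bank)
                      - qual_penalty([st_pen], bank))
            assert gap < 1e-2
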