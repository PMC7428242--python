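"""Harvest relation, monopoly effort and unpenalized encounter payoffs."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from fisherygame import (
    BasePayoffs,
    BioeconomicParams,
    DegenerateEncounterWarning,
    NotViableError,
    ParameterError,
    StockState,
    base_payoffs,
    harvest,
    is_viable,
    monopoly_effort,
    normalize,
)


class TestHarvest:
    @pytest.mark.parametrize(
        ("B_prime", "q", "f", "expected"),
        [
            (1.0, 0.023, 0.0, 0.0),  # zero effort catches nothing
            (0.3, 0.023, 18.0, 0.10169971462022627),  # hand evaluation
            (0.0, 0.023, 5.0, 0.0),  # empty stock
        ],
    )
    def test_examples(self, B_prime, q, f, expected):
        assert harvest(B_prime, q, f) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"B_prime": -0.1, "q": 0.023, "f": 1.0},
        {"B_prime": 0.3, "q": 0.023, "f": -1.0},
        {"B_prime": 0.3, "q": 0.0, "f": 1.0},
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ParameterError):
            harvest(**kwargs)

    @given(
        B=st.floats(0.01, 1.0),
        q=st.floats(0.001, 0.5),
        f=st.floats(0.1, 500.0),
        df=st.floats(0.1, 100.0),
    )
    @settings(derandomize=True)
    def test_increasing_concave_and_bounded(self, B, q, f, df):
        assume(q * (f + 2 * df) < 20)  # beyond this the exponential saturates in floats
        h0, h1, h2 = harvest(B, q, f), harvest(B, q, f + df), harvest(B, q, f + 2 * df)
        assert h0 < h1 < B  # increasing, never exhausts the stock
        assert h1 - h0 > h2 - h1  # concave: diminishing returns to effort


class TestMonopolyEffort:
    def test_case_study_value(self, econ):
        # rho = c'/(B' P q) ~ 1.2602e-4 at B'=0.3
        f_T = monopoly_effort(econ, StockState(B_prime=0.3))
        assert f_T == pytest.approx(390.3929840417613, rel=1e-12)

    def test_maximizes_profit(self, econ):
        """Independent oracle: numeric maximization of season profit."""
        state = StockState(B_prime=0.3)
        f_T = monopoly_effort(econ, state)
        profit = lambda f: state.B_prime * (1 - np.exp(-econ.q * f)) * econ.P - econ.c_prime * f
        res = minimize_scalar(lambda f: -profit(f), bounds=(0.0, 5 * f_T), method="bounded",
                              options={"xatol": 1e-8})
        assert f_T == pytest.approx(res.x, abs=1e-4)
        grid = np.linspace(0.0, 3 * f_T, 4001)
        assert profit(f_T) >= profit(grid).max()

    @given(
        B=st.floats(0.05, 1.0),
        f0=st.floats(1.0, 800.0),
    )
    @settings(derandomize=True)
    def test_first_order_condition_inversion(self, B, f0):
        # choosing c' on the FOC surface must return exactly f0
        P, q = 23.0, 0.023
        c_prime = B * P * q * math.exp(-q * f0)
        econ = BioeconomicParams(P=P, q=q, c_prime=c_prime)
        assert monopoly_effort(econ, StockState(B_prime=B)) == pytest.approx(f0, rel=1e-10)

    def test_not_viable(self, econ):
        threshold = econ.c_prime / (econ.P * econ.q)  # ~3.78e-5
        with pytest.raises(NotViableError):
            monopoly_effort(econ, StockState(B_prime=threshold / 2))
        assert not is_viable(econ, StockState(B_prime=threshold / 2))


class TestBasePayoffs:
    def test_case_study_values(self, econ):
        bp = base_payoffs(econ, StockState(B_prime=0.3))
        assert bp.Pi_CC == pytest.approx(2.33873, abs=1e-5)
        assert bp.Pi_CN == pytest.approx(0.31774, abs=1e-5)
        assert bp.Pi_NC == pytest.approx(6.573582, abs=1e-5)
        assert bp.Pi_NN == 0.0

    @given(B=st.floats(0.001, 1.0))
    @settings(derandomize=True)
    def test_revenue_conservation(self, econ, B):
        """Cooperator + cheater revenue in a mixed encounter equals the
        total-harvest revenue at the monopoly effort, exactly."""
        state = StockState(B_prime=B)
        if not is_viable(econ, state):
            return
        bp = base_payoffs(econ, state)
        if bp.degenerate:
            return
        f_T = monopoly_effort(econ, state)
        rho = econ.c_prime / (B * econ.P * econ.q)
        total_revenue = B * (1 - rho) * econ.P
        total_cost = econ.c_prime * f_T
        assert bp.Pi_CN + bp.Pi_NC == pytest.approx(total_revenue - total_cost, abs=1e-12)

    def test_degenerate_encounter_clipped(self):
        # pick c' so that f_T = f*/2 < f*: the cheater would fish negative effort
        P, q, fs = 23.0, 0.023, 18.0
        B = 0.5
        econ = BioeconomicParams(P=P, q=q, c_prime=B * P * q * math.exp(-q * fs / 2))
        with pytest.warns(DegenerateEncounterWarning):
            bp = base_payoffs(econ, StockState(B_prime=B))
        assert bp.degenerate
        assert bp.Pi_NC == 0.0  # cheater contributes no effort, earns nothing
        assert bp.Pi_CN == bp.Pi_CC  # cooperator fishes f* alone

    def test_formulas_continuous_at_f_star_equals_f_T(self):
        # exactly at f_T = f* the analytic mixed payoffs coincide with the
        # clipped ones: cheater share (L + q f*)/L = 0, cooperator share 1
        P, q, fs = 23.0, 0.023, 18.0
        B = 0.5
        cp = B * P * q * math.exp(-q * fs) * (1 + 1e-9)  # f_T barely below f*
        with pytest.warns(DegenerateEncounterWarning):
            bp = base_payoffs(BioeconomicParams(P=P, q=q, c_prime=cp), StockState(B_prime=B))
        assert bp.Pi_NC == 0.0
        assert bp.Pi_CN == pytest.approx(bp.Pi_CC, rel=1e-6)

    def test_not_viable_raises(self, econ):
        with pytest.raises(NotViableError):
            base_payoffs(econ, StockState(B_prime=1e-6))


class TestNormalize:
    @pytest.mark.parametrize(
        ("c", "B", "K", "expected"),
        [
            (20.0, 300.0, 1000.0, (0.02, 0.3)),
            (0.0, 1000.0, 1000.0, (0.0, 1.0)),
        ],
    )
    def test_examples(self, c, B, K, expected):
        assert normalize(c, B, K) == expected

    def test_invariant_violation(self):
        with pytest.raises(ParameterError):
            normalize(1.0, 2000.0, 1000.0)
        with pytest.raises(ParameterError):
            normalize(1.0, 1.0, 0.0)

    @staticmethod
    def _raw_payoffs(P, q, c, B, fs):
        """Independent oracle: payoff algebra on raw (un-normalized) units."""
        rho = c / (B * P * q)
        L = math.log(rho)
        f_T = -L / q
        Pi_CC = B * (1 - math.exp(-q * fs)) * P - c * fs
        Pi_CN = (c - B * P * q) * fs / L - c * fs
        Pi_NC = ((L + q * fs) / L) * B * (1 - rho) * P - c * (f_T - fs)
        return Pi_CC, Pi_CN, Pi_NC

    @given(
        K=st.floats(10.0, 1e6),
        B_frac=st.floats(0.05, 1.0),
        c_scale=st.floats(0.1, 10.0),
    )
    @settings(derandomize=True)
    def test_payoff_homogeneity(self, K, B_frac, c_scale):
        """Normalizing (c, B) by K then computing payoffs equals computing on
        raw units and dividing by K: the model is scale-free."""
        P, q, fs = 23.0, 0.023, 18.0
        B = B_frac * K
        c = 2e-5 * K * c_scale  # keep the fishery viable
        c_prime, B_prime = normalize(c, B, K)
        econ = BioeconomicParams(P=P, q=q, c_prime=c_prime, f_star=fs, K=K)
        state = StockState(B_prime=B_prime)
        if not is_viable(econ, state):
            return
        bp = base_payoffs(econ, state)
        raw = self._raw_payoffs(P, q, c, B, fs)
        assert bp.Pi_CC == pytest.approx(raw[0] / K, rel=1e-9, abs=1e-12)
        assert bp.Pi_CN == pytest.approx(raw[1] / K, rel=1e-9, abs=1e-12)
        assert bp.Pi_NC == pytest.approx(raw[2] / K, rel=1e-9, abs=1e-12)


def test_parameter_validation():
    with pytest.raises(ParameterError):
        BioeconomicParams(P=-1)
    with pytest.raises(ParameterError):
        BioeconomicParams(q=1.5)
    with pytest.raises(ParameterError):
        StockState(B_prime=0.0)
    with pytest.raises(ParameterError):
        StockState(B_prime=1.2)
    with pytest.raises(ParameterError):
        StockState(B_prime=0.5, r=-0.1)
    assert BasePayoffs(1.0, 0.5, 2.0).Pi_NN == 0.0
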