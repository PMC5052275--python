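"""Closed-form race model: worked values, domain errors, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuedtoj.config import ModelConfig
from cuedtoj.model import (
    RateSet,
    TrialCondition,
    cue_capture_probability,
    decompose_contributions,
    overall_rate,
    probe_first_probability,
    probe_first_probability_arrays,
)

rates_st = st.floats(min_value=1.0, max_value=150.0)
small_rates_st = st.floats(min_value=0.0, max_value=25.0)
soa_st = st.floats(min_value=-200.0, max_value=250.0)
coa_st = st.sampled_from([0.0, 40.0, 80.0, 140.0, 200.0])


class TestProbeFirstProbability:
    def test_symmetric_racers_give_half(self):
        rates = RateSet(v_p=50, v_r=50, v_cp=0)
        assert probe_first_probability(rates, TrialCondition(0.0, 100.0)) == pytest.approx(0.5)

    def test_cue_race_adds_capture_mass_at_soa_zero(self):
        # Cue completes its 140 ms window with prob 1 - e^-1.4; otherwise the
        # symmetric target race decides: 0.7534 + 0.2466/2 = 0.8767.
        rates = RateSet(v_p=50, v_r=50, v_cp=10)
        p = probe_first_probability(rates, TrialCondition(0.0, 140.0))
        assert p == pytest.approx(0.8767, abs=1e-3)

    def test_extreme_soa_limits(self):
        rates = RateSet(v_p=40, v_r=60, v_cp=0, v_neutral=30)
        assert probe_first_probability(rates, TrialCondition(-5000.0, 80.0)) == pytest.approx(1.0, abs=1e-6)
        assert probe_first_probability(rates, TrialCondition(5000.0, 80.0)) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(v_p=-1.0, v_r=50.0),
            dict(v_p=50.0, v_r=math.nan),
            dict(v_p=50.0, v_r=50.0, v_cp=math.inf),
            dict(v_p=50.0, v_r=50.0, t0=-5.0),
        ],
    )
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(ValueError):
            RateSet(**bad)

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValueError):
            TrialCondition(soa=0.0, coa=-10.0)
        with pytest.raises(ValueError):
            TrialCondition(soa=math.inf)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(v_p=rates_st, v_r=rates_st, v_cp=small_rates_st, v_n=rates_st, coa=coa_st)
    def test_bounded_and_monotone_in_soa(self, v_p, v_r, v_cp, v_n, coa):
        rates = RateSet(v_p, v_r, v_cp, v_n)
        grid = np.linspace(-250, 300, 56)
        probs = [probe_first_probability(rates, TrialCondition(s, coa)) for s in grid]
        probs = np.asarray(probs)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.all(np.diff(probs) <= 1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(v_p=rates_st, v_r=rates_st, v_cp=small_rates_st, v_n=rates_st,
           coa=st.sampled_from([40.0, 80.0, 140.0]),
           t0=st.sampled_from([0.0, 15.0]))
    def test_continuous_at_regime_boundaries(self, v_p, v_r, v_cp, v_n, coa, t0):
        rates = RateSet(v_p, v_r, v_cp, v_n, t0=t0)
        for s0 in (0.0, coa):
            left = probe_first_probability(rates, TrialCondition(s0 - 1e-7, coa))
            right = probe_first_probability(rates, TrialCondition(s0 + 1e-7, coa))
            assert left == pytest.approx(right, abs=1e-5)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(v=rates_st, soa=soa_st, coa=coa_st)
    def test_reduces_to_neutral_curve_without_cue_mechanisms(self, v, soa, coa):
        # v_cp = 0 and v_p = v_r = v_neutral must reproduce the no-cue curve.
        rates = RateSet(v_p=v, v_r=v, v_cp=0.0, v_neutral=v)
        cued = probe_first_probability(rates, TrialCondition(soa, coa))
        neutral = probe_first_probability(rates, TrialCondition(soa, None))
        assert cued == pytest.approx(neutral, abs=1e-12)


class TestCueCapture:
    def test_worked_percentages(self):
        # 10 Hz over a 140 ms window -> 75%; 20 Hz -> 94%.
        assert round(100 * cue_capture_probability(10.0, 140.0)) == 75
        assert round(100 * cue_capture_probability(20.0, 140.0)) == 94

    def test_zero_window(self):
        assert cue_capture_probability(35.0, 0.0) == 0.0

    def test_threshold_shortens_window(self):
        full = cue_capture_probability(10.0, 140.0, t0=0.0)
        shortened = cue_capture_probability(10.0, 140.0, t0=15.0)
        assert shortened == pytest.approx(-math.expm1(-0.01 * 125.0))
        assert shortened < full

    def test_monotone_in_rate_and_window(self):
        assert cue_capture_probability(20, 80) > cue_capture_probability(10, 80)
        assert cue_capture_probability(10, 140) > cue_capture_probability(10, 80)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            cue_capture_probability(-1.0, 100.0)
        with pytest.raises(ValueError):
            cue_capture_probability(10.0, -1.0)


class TestDecomposition:
    def test_event_split_at_soa_zero(self):
        rates = RateSet(v_p=50, v_r=50, v_cp=10)
        via_cue, via_probe = decompose_contributions(rates, TrialCondition(0.0, 140.0))
        assert via_cue == pytest.approx(0.7534, abs=1e-3)
        assert via_probe == pytest.approx(0.1233, abs=1e-3)

    def test_no_cue_race_means_no_cue_contribution(self):
        rates = RateSet(v_p=40, v_r=70, v_cp=0, v_neutral=30)
        cond = TrialCondition(30.0, 80.0)
        via_cue, via_probe = decompose_contributions(rates, cond)
        assert via_cue == 0.0
        assert via_probe == pytest.approx(probe_first_probability(rates, cond))

    def test_sum_matches_total_probability(self, rng):
        for _ in range(20):
            rates = RateSet(
                v_p=rng.uniform(5, 120), v_r=rng.uniform(5, 120),
                v_cp=rng.uniform(0, 25), v_neutral=rng.uniform(10, 60),
                t0=float(rng.choice([0.0, 15.0])),
            )
            cond = TrialCondition(rng.uniform(-150, 220), float(rng.choice([40, 80, 140])))
            via_cue, via_probe = decompose_contributions(rates, cond)
            total = probe_first_probability(rates, cond)
            assert abs(via_cue + via_probe - total) < 1e-10


class TestOverallRate:
    def test_matches_narrative_values(self):
        assert overall_rate(RateSet(29, 29, 0, 29), cued=False) == 58
        assert overall_rate(RateSet(58, 113, 10)) == 181

    def test_zero_rates(self):
        assert overall_rate(RateSet(0, 0, 0)) == 0.0

    def test_additive_in_components(self, rng):
        for _ in range(10):
            a, b, c = rng.uniform(0, 100, 3)
            assert overall_rate(RateSet(a, b, c)) == pytest.approx(a + b + c)


class TestRegimeVariants:
    def test_fixed_regime_uses_neutral_rate_when_reference_leads(self):
        # With the reference shown before the cue, the 'fixed' rule races it
        # at v_neutral throughout; v_r must then be irrelevant.
        cfg = ModelConfig(regime_rule="fixed")
        cond = TrialCondition(150.0, 40.0)
        p1 = probe_first_probability(RateSet(50, 90, 5, 30), cond, cfg)
        p2 = probe_first_probability(RateSet(50, 10, 5, 30), cond, cfg)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_piecewise_regime_blends_both_rates(self):
        cond = TrialCondition(150.0, 40.0)
        p1 = probe_first_probability(RateSet(50, 90, 5, 30), cond)
        p2 = probe_first_probability(RateSet(50, 10, 5, 30), cond)
        assert p1 != pytest.approx(p2, abs=1e-6)


class TestKernelEquivalence:
    def test_numba_kernel_matches_reference_implementation(self, rng):
        """The compiled scalar kernel must agree with the vectorized closed
        form to near machine precision (dual implementations of one model)."""
        from cuedtoj._kernels import neutral_scalar, p1st_scalar

        for _ in range(200):
            v_p, v_r = rng.uniform(1, 150, 2)
            v_cp = rng.uniform(0, 30)
            v_n = rng.uniform(5, 80)
            soa = rng.uniform(-200, 250)
            coa = float(rng.choice([0.0, 40.0, 80.0, 140.0]))
            t0 = float(rng.choice([0.0, 15.0]))
            for rule, flag in (("piecewise", True), ("fixed", False)):
                ref = probe_first_probability_arrays(
                    v_p, v_r, v_cp, v_n, soa, coa, t0=t0, regime_rule=rule
                )
                got = p1st_scalar(v_p, v_r, v_cp, v_n, soa, coa, t0, flag)
                assert got == pytest.approx(float(ref), abs=1e-12)
            ref_n = probe_first_probability_arrays(
                0.0, 0.0, 0.0, v_n, soa, np.nan
            )
            assert neutral_scalar(v_n, soa) == pytest.approx(float(ref_n), abs=1e-12)
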