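"""Fuzzy controller: membership shapes, defuzzification, and update law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vagusloop.controller import (
    DEFAULT_RULES,
    ConfigurationError,
    ControllerState,
    ErrorMembershipSet,
    FuzzyControllerConfig,
    FuzzyRule,
    SlopeMembershipSet,
    compute_error,
    compute_slope,
    controller_step,
    defuzzify,
    fuzzify,
)


def brute_force_defuzzify(memberships, rules):
    """Independent oracle: plain 5-term weighted sum of singleton outputs."""
    total = 0.0
    for r in rules:
        act = memberships[r.error_zone]
        if r.slope_zone != "Any":
            act = act * memberships[r.slope_zone]
        total += act * r.output_singleton
    return max(-1.0, min(1.0, total))


@pytest.mark.parametrize(
    "hr,sp,expected", [(400, 350, 50), (350, 350, 0), (300, 350, -50)]
)
def test_error_is_signed_difference(hr, sp, expected):
    assert compute_error(hr, sp) == expected


def test_error_rejects_nonfinite():
    with pytest.raises(ValueError):
        compute_error(float("nan"), 350)
    with pytest.raises(ValueError):
        compute_error(math.inf, 350)


@pytest.mark.parametrize(
    "now,prev,expected", [(12, 10, 4.0), (10, 10, 0.0), (-3, 2, -10.0)]
)
def test_slope_divides_by_half_second(now, prev, expected):
    assert compute_slope(now, prev) == pytest.approx(expected)


class TestMembership:
    def test_symmetric_center(self, default_cfg):
        m = fuzzify(0.0, 0.0, default_cfg)
        assert m["Near"] > 0.9
        assert m["Below"] < 0.05 and m["Above"] < 0.05
        assert m["Below"] == pytest.approx(m["Above"])
        assert m["Increasing"] == pytest.approx(0.5)
        assert m["Decreasing"] == pytest.approx(0.5)

    def test_deep_saturation(self, default_cfg):
        m = fuzzify(100.0, 10.0, default_cfg)
        assert m["Above"] == pytest.approx(1.0)
        assert m["Increasing"] == 1.0

    def test_sigmoid_half_at_midpoint(self, default_cfg):
        mp = default_cfg.error_mfs.below_midpoint
        assert fuzzify(mp, 0.0, default_cfg)["Below"] == pytest.approx(0.5)
        mp = default_cfg.error_mfs.above_midpoint
        assert fuzzify(mp, 0.0, default_cfg)["Above"] == pytest.approx(0.5)

    @given(err=st.floats(-500, 500), slope=st.floats(-50, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_memberships_are_a_partition(self, err, slope):
        cfg = FuzzyControllerConfig(setpoint=300.0)
        m = fuzzify(err, slope, cfg)
        for v in m.values():
            assert 0.0 <= v <= 1.0
        total = m["Below"] + m["Near"] + m["Above"]
        assert total <= 1.0 + 1e-12
        if m["Near"] > 0:
            assert total == pytest.approx(1.0)
        assert m["Increasing"] + m["Decreasing"] == pytest.approx(1.0)

    def test_misconfigured_midpoints_rejected(self):
        with pytest.raises(ConfigurationError):
            ErrorMembershipSet(below_midpoint=5.0, above_midpoint=-5.0)
        with pytest.raises(ConfigurationError):
            SlopeMembershipSet(decreasing_full=1.0, increasing_full=-1.0)


class TestDefuzzify:
    def test_near_rule_is_zero(self):
        m = {"Below": 0.0, "Near": 1.0, "Above": 0.0, "Increasing": 0.5, "Decreasing": 0.5}
        assert defuzzify(m, DEFAULT_RULES) == 0.0

    def test_single_saturated_rule(self):
        m = {"Below": 0.0, "Near": 0.0, "Above": 1.0, "Increasing": 1.0, "Decreasing": 0.0}
        assert defuzzify(m, DEFAULT_RULES) == 1.0

    def test_mixed_activation_hand_computed(self):
        # 0.6*0.5*1 + 0.6*0.5*0.4 + 0.4*0 = 0.42
        m = {"Below": 0.0, "Near": 0.4, "Above": 0.6, "Increasing": 0.5, "Decreasing": 0.5}
        assert defuzzify(m, DEFAULT_RULES) == pytest.approx(0.42)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            b, a = rng.uniform(0, 1, 2)
            near = max(0.0, 1.0 - a - b)
            inc = rng.uniform(0, 1)
            m = {
                "Below": b,
                "Near": near,
                "Above": a,
                "Increasing": inc,
                "Decreasing": 1.0 - inc,
            }
            assert defuzzify(m, DEFAULT_RULES) == pytest.approx(
                brute_force_defuzzify(m, DEFAULT_RULES), abs=1e-12
            )

    def test_unknown_zone_in_rule_rejected(self):
        with pytest.raises(ConfigurationError):
            FuzzyRule("Sideways", "Any", 0.0)
        bad = DEFAULT_RULES[:4] + (FuzzyRule("Above", "Any", 0.5),)
        m = {"Below": 0.0, "Near": 1.0}
        with pytest.raises(ConfigurationError):
            defuzzify(m, bad)

    def test_five_rules_required(self):
        with pytest.raises(ConfigurationError):
            defuzzify({}, DEFAULT_RULES[:4])


class TestSignAndShape:
    def test_sign_correct_beyond_dead_zone(self, default_cfg):
        for err in (1.0, 3.0, 10.0, 50.0):
            for slope in (-20.0, -1.0, 0.0, 1.0, 20.0):
                d = defuzzify(fuzzify(err, slope, default_cfg), default_cfg.rules)
                assert d >= 0.0, (err, slope)
                dn = defuzzify(fuzzify(-err, -slope, default_cfg), default_cfg.rules)
                assert dn <= 0.0

    def test_near_zero_error_gives_near_zero_output(self, default_cfg):
        # inside the dead zone the output magnitude stays small (< 0.05)
        for err in np.linspace(-1, 1, 21):
            for slope in (-20.0, 0.0, 20.0):
                d = defuzzify(fuzzify(err, slope, default_cfg), default_cfg.rules)
                assert abs(d) < 0.05
        assert defuzzify(fuzzify(0.0, 0.0, default_cfg), default_cfg.rules) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_output_continuous_in_error(self, default_cfg):
        k = default_cfg.error_mfs.steepness
        step = 0.01
        grid = np.arange(-30, 30, step)
        for slope in (-2.0, 0.0, 2.0):
            vals = [
                defuzzify(fuzzify(e, slope, default_cfg), default_cfg.rules)
                for e in grid
            ]
            max_jump = np.max(np.abs(np.diff(vals)))
            assert max_jump <= k * step  # Lipschitz bound from sigmoid slopes

    def test_surface_has_four_plateaus_and_zero_region(self, default_cfg):
        surf = lambda e, s: defuzzify(fuzzify(e, s, default_cfg), default_cfg.rules)
        assert surf(50, 5) == pytest.approx(1.0, abs=0.02)
        assert surf(50, -5) == pytest.approx(0.4, abs=0.02)
        assert surf(-50, -5) == pytest.approx(-1.0, abs=0.02)
        assert surf(-50, 5) == pytest.approx(-0.4, abs=0.02)
        assert surf(0, 0) == pytest.approx(0.0, abs=0.05)


class TestControllerStep:
    def test_gain_sets_per_update_increment(self):
        # G = 10 at 2 Hz: a fully saturated rule moves cout by 5 per update
        cfg = FuzzyControllerConfig(gain=10.0, setpoint=300.0)
        state = ControllerState(cout=0.0, prev_error=99.0)
        cout, state = controller_step(401.0, state, cfg)  # err=101, slope=+4
        assert cout == pytest.approx(5.0)

    def test_steady_at_setpoint(self, default_cfg):
        state = ControllerState()
        for _ in range(20):
            cout, state = controller_step(default_cfg.setpoint, state, default_cfg)
        assert cout == pytest.approx(0.0, abs=1e-9)
        assert state.n_updates == 20

    def test_constant_full_rate_accumulation(self):
        # G = 2 with a saturated positive rule: cout reaches 10 after 10 updates
        cfg = FuzzyControllerConfig(gain=2.0, setpoint=300.0)
        state = ControllerState(cout=0.0, prev_error=99.0)
        hr = 400.0
        for k in range(10):
            cout, state = controller_step(hr + k, state, cfg)  # slope +2 throughout
        assert cout == pytest.approx(10.0)

    @given(st.lists(st.floats(0, 800), min_size=3, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rate_bound_per_second(self, hrs):
        cfg = FuzzyControllerConfig(gain=5.0, setpoint=300.0)
        state = ControllerState()
        couts = [0.0]
        for hr in hrs:
            cout, state = controller_step(hr, state, cfg)
            couts.append(cout)
        # any 1 s window = 2 consecutive updates at 2 Hz
        for i in range(len(couts) - 2):
            assert abs(couts[i + 2] - couts[i]) <= cfg.gain + 1e-9

    def test_cout_clamped_to_limits(self):
        cfg = FuzzyControllerConfig(
            gain=100.0, setpoint=300.0, cout_limits=(-20.0, 20.0)
        )
        state = ControllerState(prev_error=99.0)
        for _ in range(10):
            cout, state = controller_step(700.0, state, cfg)
        assert cout == 20.0

    def test_config_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            FuzzyControllerConfig(gain=-1.0, setpoint=300.0)
        with pytest.raises(ConfigurationError):
            FuzzyControllerConfig(update_rate=0.0, setpoint=300.0)
        with pytest.raises(ConfigurationError):
            FuzzyControllerConfig(setpoint=300.0, cout_limits=(10.0, 20.0))
        with pytest.raises(ConfigurationError):
            FuzzyControllerConfig(setpoint=300.0, rules=DEFAULT_RULES[:3])
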