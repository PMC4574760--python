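"""Unit and property tests for the core kinetic operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myokinetics.kinetics import (
    FeedbackConfig,
    RateSet,
    StageState,
    SwitchConfig,
    apply_stage1_suppression,
    feedback_factor,
    l3_composite,
    l_composite,
    rhs,
    smooth_D,
    smooth_l1,
)

FB = FeedbackConfig(n_dagger=3.25e5, s=3.5e-5)


class TestFeedbackFactor:
    def test_half_at_threshold(self):
        # the density ceiling is defined as a 50% cut of every flux
        assert feedback_factor(FB.n_dagger, FB) == pytest.approx(0.5, abs=1e-15)
        assert feedback_factor(3.0e5, FeedbackConfig(3.0e5, 4e-5)) == 0.5

    def test_empty_culture_value(self):
        # direct evaluation of the logistic at n_tot = 0
        expected = 1.0 / (1.0 + math.exp(-3.5e-5 * 3.25e5))
        assert feedback_factor(0.0, FB) == pytest.approx(expected, rel=1e-12)
        assert feedback_factor(0.0, FB) == pytest.approx(0.9999885, abs=1e-7)

    def test_crowded_limit_and_overflow(self):
        # clamped exponent: saturates without overflow
        assert feedback_factor(1e12, FB) < 1e-300
        assert feedback_factor(0.0, FeedbackConfig(1e12, 1.0)) == 1.0

    @given(st.floats(min_value=0.0, max_value=1e7),
           st.floats(min_value=1e-6, max_value=1e-3))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_and_decreasing(self, n, s):
        fb = FeedbackConfig(n_dagger=3.25e5, s=s)
        f = feedback_factor(n, fb)
        assert 0.0 < f <= 1.0
        assert feedback_factor(n + 1e4, fb) <= f
        # strict bounds and monotonicity away from float saturation
        if abs(s * (n - fb.n_dagger)) < 30:
            assert f < 1.0
            assert feedback_factor(n + 1e4, fb) < f

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            feedback_factor(float("nan"), FB)
        with pytest.raises(ValueError):
            feedback_factor(-1.0, FB)


class TestCompositeRates:
    @pytest.mark.parametrize("r,p,d,expected", [
        (0.5, 0.7, 0.3, -0.3),      # symmetric division contributes nothing
        (1.0, 0.7, 0.3, 0.4),       # full self-renewal: p - d
        (0.8, 0.4, 0.2, 0.04),      # stage-0 static rates
        (0.0, 0.1, 0.6, -0.7),      # stage-1 static post-peak rates
    ])
    def test_l_composite(self, r, p, d, expected):
        assert l_composite(r, p, d) == pytest.approx(expected)

    @pytest.mark.parametrize("p3,d3,D,expected", [
        (0.3, 0.20, 0.0, 0.10),     # dynamic stage-3 before MHC release
        (0.25, 0.25, 0.0, 0.0),
        (0.1, 0.25, 0.05, -0.20),   # static final-epoch stage-3 rates
    ])
    def test_l3_composite(self, p3, d3, D, expected):
        assert l3_composite(p3, d3, D) == pytest.approx(expected)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            l_composite(1.3, 0.1, 0.1)
        with pytest.raises(ValueError):
            l3_composite(-0.1, 0.1, 0.0)


def _switch_cfg(**kw):
    defaults = dict(n1_star=2e4, n3_star=4e4, n1_dstar=2.15e4, n3_dstar=4.4e4,
                    l_plus=0.24, l_minus=-0.55, slope_up_l1=3.0e-4,
                    k=1.25e-4, D_plus=0.55)
    defaults.update(kw)
    return SwitchConfig(**defaults)


class TestSmoothSwitches:
    def test_l1_branch_values(self):
        cfg = _switch_cfg()
        # below/at the lower knot
        assert smooth_l1(1e4, "ascending", cfg) == cfg.l_plus
        assert smooth_l1(cfg.n1_star, "ascending", cfg) == cfg.l_plus
        assert smooth_l1(1e4, "descending", cfg) == cfg.l_minus
        # linear decline on the band
        mid = 0.5 * (cfg.n1_star + cfg.n1_dstar)
        assert smooth_l1(mid, "ascending", cfg) == pytest.approx(
            cfg.l_plus - cfg.slope_up_l1 * (mid - cfg.n1_star))

    def test_l1_continuity_at_knots(self):
        cfg = _switch_cfg()
        eps = 1e-6
        for direction in ("ascending", "descending"):
            lo = smooth_l1(cfg.n1_star - eps, direction, cfg)
            hi = smooth_l1(cfg.n1_star + eps, direction, cfg)
            assert lo == pytest.approx(hi, abs=1e-6)

    def test_l1_descending_joins_ascending_at_upper_knot(self):
        cfg = _switch_cfg()
        up = smooth_l1(cfg.n1_dstar, "ascending", cfg)
        down = smooth_l1(cfg.n1_dstar, "descending", cfg)
        assert up == pytest.approx(down, rel=1e-12)

    def test_D_branch_values(self):
        cfg = _switch_cfg()
        assert smooth_D(cfg.n3_star, "ascending", cfg) == 0.0
        assert smooth_D(1e4, "ascending", cfg) == 0.0
        assert smooth_D(1e4, "descending", cfg) == cfg.D_plus
        # ascending value at the upper knot equals the descending branch there
        top = cfg.k * (cfg.n3_dstar - cfg.n3_star)
        assert smooth_D(cfg.n3_dstar, "ascending", cfg) == pytest.approx(top)
        assert smooth_D(cfg.n3_dstar, "descending", cfg) == pytest.approx(top)

    @given(st.floats(min_value=0.0, max_value=1e5))
    @settings(derandomize=True, max_examples=50)
    def test_D_never_negative(self, n3):
        cfg = _switch_cfg()
        assert smooth_D(n3, "ascending", cfg) >= 0.0
        assert smooth_D(n3, "descending", cfg) >= 0.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SwitchConfig(n1_star=2e4, n3_star=4e4, n1_dstar=3e4)  # > 1.1x
        with pytest.raises(ValueError):
            SwitchConfig(n1_star=2e4, n3_star=4e4, n3_dstar=3e4)  # below n3*
        with pytest.raises(ValueError):
            smooth_D(1e4, "ascending", _switch_cfg(k=None))


RATES = RateSet(r=(0.8, 0.9, 1.0, 1.0, 0.0),
                p=(0.4, 0.6, 0.2, 0.3, 0.0),
                d=(0.2, 0.2, 0.2, 0.2, 0.1),
                D=0.55)

stage_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1e6), min_size=5, max_size=5
).map(np.array)


class TestRHS:
    def test_zero_state_gives_zero_flux(self):
        dy = rhs(np.zeros(5), RATES, FB)
        assert np.all(dy == 0.0)

    def test_single_stage_growth_and_influx(self):
        fb = FeedbackConfig(n_dagger=1e9, s=1e-3)  # f == 1 numerically
        y = np.array([1000.0, 0, 0, 0, 0])
        dy = rhs(y, RATES, fb)
        assert dy[0] == pytest.approx(RATES.l(0) * 1000.0)
        assert dy[1] == pytest.approx(2 * (1 - 0.8) * 0.4 * 1000.0)
        assert np.all(dy[2:] == 0.0)

    @given(stage_vectors)
    @settings(derandomize=True, max_examples=100)
    def test_flux_conservation(self, y):
        """Asymmetric-division and direct-differentiation terms cancel:
        the total flux is f * (sum p_i n_i - sum d_i n_i)."""
        dy = rhs(y, RATES, FB)
        f = feedback_factor(float(y.sum()), FB)
        r, p, d, _ = RATES.as_arrays()
        expected = f * (p @ y - d @ y)
        assert dy.sum() == pytest.approx(expected, rel=1e-9, abs=1e-6)

    @given(stage_vectors, st.integers(min_value=0, max_value=4))
    @settings(derandomize=True, max_examples=100)
    def test_nonnegativity_forward_invariant(self, y, i):
        """An empty stage only receives influx: dn_i/dt >= 0 at n_i = 0."""
        y[i] = 0.0
        dy = rhs(y, RATES, FB)
        assert dy[i] >= 0.0

    def test_inactive_stages_held_at_zero(self):
        y = np.array([1e3, 1e3, 1e3, 1e3, 1e3])
        dy = rhs(y, RATES, FB, active_stages=(False, False))
        assert dy[3] == 0.0 and dy[4] == 0.0
        dy = rhs(y, RATES, FB, active_stages=(True, False))
        # stage 3 integrates, but without direct differentiation
        f = feedback_factor(float(y.sum()), FB)
        assert dy[3] == pytest.approx(
            f * ((0.3 - 0.2) * 1e3 + 2 * (1 - 1.0) * 0.2 * 1e3))
        assert dy[4] == 0.0

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            rhs(np.array([-10.0, 0, 0, 0, 0]), RATES, FB)


class TestSuppression:
    CFG = _switch_cfg(n1_sup=8e3)

    @pytest.mark.parametrize("deriv,n1,active,expected", [
        (50.0, 9e3, True, 0.0),     # growth above the threshold is blocked
        (-20.0, 9e3, True, -20.0),  # decline passes through
        (50.0, 9e3, False, 50.0),   # rule not armed before MyoD release
        (50.0, 7e3, True, 50.0),    # below the threshold
    ])
    def test_clamp(self, deriv, n1, active, expected):
        assert apply_stage1_suppression(deriv, n1, active, self.CFG) == expected

    def test_disabled_passes_through(self):
        cfg = _switch_cfg(n1_sup=8e3, suppression_enabled=False)
        assert apply_stage1_suppression(50.0, 9e3, True, cfg) == 50.0


class TestStageState:
    def test_total_is_stage_sum(self):
        s = StageState(n0=1, n1=2, n2=3, n3=4, n4=5)
        assert s.n_tot == 15
        assert np.array_equal(s.as_array(), [1, 2, 3, 4, 5])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            StageState(n0=-1.0)
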