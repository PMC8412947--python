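"""Stance detection, length reconstruction, differentiation, normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtulab import (
    EventDetectionError,
    LeverArm,
    TimeSeriesTrace,
    ValidationError,
    belly_length,
    detect_stance,
    differentiate,
    mtu_length,
    time_normalize,
)
from mtulab.kinematics import STANCE_GRID, StanceWindow, stance_average


def trace(values, rate=100.0):
    return TimeSeriesTrace(np.asarray(values, dtype=float), rate)


class TestDetectStance:
    def test_single_flexion_hump_between_two_minima(self):
        # knee flexes and re-extends between minima at samples 10 and 80
        n = 101
        x = np.zeros(n)
        x[:11] = np.linspace(5, 0, 11)
        x[10:81] = 20 * np.sin(np.pi * np.linspace(0, 1, 71)) ** 2
        x[80:] = np.linspace(0, 5, 21)
        w = detect_stance(trace(x))
        # brute-force oracle: scan all local minima, all consecutive pairs
        mins = [i for i in range(1, n - 1) if x[i] < x[i - 1] and x[i] <= x[i + 1]]
        pairs = list(zip(mins[:-1], mins[1:]))
        exc = [np.max(x[i:j + 1]) - max(x[i], x[j]) for i, j in pairs]
        assert (w.touchdown_index, w.toeoff_index) == pairs[int(np.argmax(exc))] == (10, 80)

    def test_monotone_trace_fails(self):
        with pytest.raises(EventDetectionError):
            detect_stance(trace(np.arange(50.0)))

    def test_picks_largest_excursion_among_multiple_humps(self):
        u = np.linspace(0, 1, 51)
        hump = lambda a: a * np.sin(np.pi * u) ** 2
        x = np.concatenate([[1.0], hump(5), hump(30), hump(5), [1.0]])
        w = detect_stance(trace(x))
        seg = x[w.touchdown_index : w.toeoff_index + 1]
        assert np.max(seg) == pytest.approx(30.0)

    def test_synthetic_trial_window_is_sample_exact(self, soleus_trial):
        w = detect_stance(soleus_trial.traces["knee_deg"])
        assert w.touchdown_index == soleus_trial.ground_truth["touchdown_index"]
        assert w.toeoff_index == soleus_trial.ground_truth["toeoff_index"]


class TestMtuLength:
    def test_constant_angle_gives_initial_length(self):
        out = mtu_length(trace(np.full(50, 12.0)), LeverArm.constant(50.0), 400.0)
        assert np.allclose(out.values, 400.0)

    def test_single_step_closed_form(self):
        # 0.1 rad step at 50 mm lever -> +5 mm
        ang = trace([0.0, np.rad2deg(0.1)])
        out = mtu_length(ang, LeverArm.constant(50.0), 400.0)
        assert out.values[-1] == pytest.approx(405.0, abs=1e-12)

    def test_angle_dependent_lever_grid_refinement(self):
        # quadrature oracle: a 10x finer angle path changes total dL < 1e-3 mm
        lever = LeverArm.from_table([0, 10, 20, 30], [40, 45, 52, 61])
        t1 = np.linspace(0, 1, 201)
        t2 = np.linspace(0, 1, 2001)
        phi = lambda t: 25.0 * np.sin(np.pi * t / 2)
        c1 = mtu_length(trace(phi(t1), 200), lever, 400.0).values[-1]
        c2 = mtu_length(trace(phi(t2), 2000), lever, 400.0).values[-1]
        assert abs(c1 - c2) < 1e-3

    def test_out_of_table_angle_raises(self):
        lever = LeverArm.from_table([0, 30], [40, 50])
        with pytest.raises(ValidationError):
            mtu_length(trace([0.0, 40.0]), lever, 400.0)


class TestBellyLength:
    def test_zero_pennation_tracks_fascicle(self):
        f = trace(np.linspace(50, 45, 20))
        b = belly_length(f, f.with_values(np.zeros(20)), 300.0)
        assert np.allclose(np.diff(b.values), np.diff(f.values))

    def test_constant_pennation_closed_form(self):
        f = trace([50.0, 48.0])
        p = f.with_values([30.0, 30.0])
        b = belly_length(f, p, 300.0)
        assert b.values[-1] - b.values[0] == pytest.approx(-2 * np.cos(np.deg2rad(30)), abs=1e-12)

    def test_matches_direct_projection_trace(self):
        rng = np.random.default_rng(0)
        f = trace(50 - np.cumsum(rng.uniform(0, 0.2, 40)))
        p = f.with_values(np.linspace(15, 25, 40))
        b = belly_length(f, p, 100.0)
        proj = f.values * np.cos(np.deg2rad(p.values))
        assert np.allclose(np.diff(b.values), np.diff(proj))

    def test_mismatched_time_bases_rejected(self):
        with pytest.raises(ValidationError):
            belly_length(trace(np.ones(10)), trace(np.ones(11)), 100.0)


class TestDifferentiate:
    def test_linear_ramp_exact(self):
        v = differentiate(trace(10.0 * np.arange(50) / 100.0, 100.0))
        assert np.allclose(v.values, 10.0)

    def test_constant_gives_zero(self):
        assert np.allclose(differentiate(trace(np.full(30, 7.0))).values, 0.0)

    def test_sine_interior_taylor_bound(self):
        f, rate = 2.0, 200.0
        t = np.arange(400) / rate
        v = differentiate(trace(np.sin(2 * np.pi * f * t), rate)).values
        truth = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        bound = (2 * np.pi * f) ** 3 * (1 / rate) ** 2 / 6
        assert np.max(np.abs(v[1:-1] - truth[1:-1])) < bound

    def test_recovers_quadratic_velocity_to_second_order(self):
        rate = 100.0
        t = np.arange(200) / rate
        v_true = 3.0 + 2.0 * t  # integral: 3t + t^2
        x = 3.0 * t + t**2
        v = differentiate(trace(x, rate)).values
        assert np.allclose(v[1:-1], v_true[1:-1], atol=1e-10)

    def test_too_short(self):
        with pytest.raises(ValidationError):
            differentiate(trace([1.0, 2.0]))


class TestTimeNormalize:
    def test_identity_when_window_has_101_samples(self):
        x = np.random.default_rng(1).normal(size=120)
        w = StanceWindow(5, 105)
        assert np.allclose(time_normalize(trace(x), w), x[5:106])

    def test_linear_trace_exact(self):
        x = np.linspace(0, 10, 77)
        g = time_normalize(trace(x), StanceWindow(0, 76))
        assert np.allclose(g, np.linspace(0, 10, 101))
        assert g[0] == x[0] and g[-1] == x[-1]

    def test_window_outside_trace(self):
        with pytest.raises(ValidationError):
            time_normalize(trace(np.ones(50)), StanceWindow(10, 60))


class TestStanceAverage:
    def test_linearity_mean_of_averages_equals_average_of_mean_curve(self):
        rng = np.random.default_rng(2)
        curves = rng.normal(size=(7, 101))
        a = np.mean([stance_average(c) for c in curves])
        b = stance_average(curves.mean(axis=0))
        assert abs(a - b) < 1e-12

    def test_constant_curve(self):
        assert stance_average(np.full(101, 3.3)) == pytest.approx(3.3, abs=1e-14)

    def test_grid_average_matches_analytic_time_average(self, soleus_trial):
        # stance average of normalized fascicle velocity vs closed form
        from mtulab import AnalysisConfig, analyze_trial, generate_mvc_dataset

        cfg = soleus_trial.config
        mvc = generate_mvc_dataset(cfg.L0_mm, cfg.Fmax_N, curvature=cfg.fl_curvature)
        rep = analyze_trial(soleus_trial, mvc, AnalysisConfig.for_synthetic(soleus_trial))
        gt = soleus_trial.ground_truth["mean_fascicle_velocity_norm"]
        assert rep.scalars["mean_fascicle_velocity_norm"] == pytest.approx(gt, rel=1e-3)


@given(st.floats(-50, 50), st.integers(5, 60))
def test_mtu_length_exact_for_constant_angle(angle, n):
    out = mtu_length(trace(np.full(n, angle)), LeverArm.constant(42.0), 350.0)
    assert np.allclose(out.values, 350.0)


@given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
def test_normalize_preserves_endpoints(vals):
    tr = trace(vals)
    w = StanceWindow(0, len(vals) - 1)
    g = time_normalize(tr, w)
    assert g[0] == tr.values[0] and g[-1] == tr.values[-1]
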