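"""Speed, bursts, segmentation, trajectory geometry, chaos and power laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metastate import (PoissonNullParams, burst_gap_test, chaos01, compute_speed,
                       divergence_profile, fit_powerlaw, segment_states,
                       trajectory_metrics)
from metastate.components import ActivationSeries
from metastate.dynamics import SpeedSeries, duration_matched_state_ratios

from conftest import boundary_f1


def series(X):
    return ActivationSeries(np.asarray(X, float), None)


class TestSpeed:
    def test_constant_trajectory_zero_speed(self):
        s = compute_speed(series(np.ones((50, 3))))
        assert np.allclose(s.values, 0.0)

    def test_unit_steps(self):
        X = np.zeros((30, 2))
        X[:, 0] = np.arange(30)
        s = compute_speed(series(X))
        assert np.allclose(s.values, 1.0)

    def test_matches_bruteforce_norms(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 4))
        s = compute_speed(series(X))
        brute = [np.linalg.norm(X[t + 1] - X[t]) for t in range(99)]
        assert np.allclose(s.values, brute)

    def test_mask_gaps_produce_no_step(self, feature_rec):
        from metastate.bands import WindowGrid
        X = np.random.default_rng(1).standard_normal((20, 2))
        grid = WindowGrid.regular(100.0, 5.0)
        mask = np.ones(20, bool)
        mask[7] = False
        a = ActivationSeries(X, grid.replace_mask(mask))
        s = compute_speed(a)
        assert np.isnan(s.values[6]) and np.isnan(s.values[7])
        assert np.isfinite(s.values[5])


class TestBurstGap:
    def test_analytic_expectation_for_regular_events(self):
        # speeds spike exactly every 10 windows -> observed mean gap 10
        v = np.zeros(5000)
        v[::10] = 1.0
        v += np.linspace(0, 0.1, 5000)  # break ties below the spikes
        obs, exp, p = burst_gap_test(SpeedSeries(v, np.ones(5000, bool)), seed=0)
        assert exp == 10.0
        assert obs == pytest.approx(10.0, abs=0.2)
        assert p > 0.05  # perfectly regular events are the opposite of bursty

    def test_iid_speeds_match_poisson_expectation(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(20_000) ** 2
        obs, exp, p = burst_gap_test(SpeedSeries(v, np.ones_like(v, bool)), seed=0)
        assert obs == pytest.approx(10.0, abs=1.0)
        assert p > 0.01

    def test_planted_bursts_cluster(self, feature_acts):
        s = compute_speed(feature_acts)
        obs, exp, p = burst_gap_test(s, seed=0)
        assert obs < exp + 0.1
        assert p < 0.01

    def test_constant_speeds_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            burst_gap_test(SpeedSeries(np.ones(2000), np.ones(2000, bool)))

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            PoissonNullParams(rate=1.5)


class TestSegmentation:
    def test_planted_boundaries_recovered(self, feature_rec, feature_acts):
        seg = segment_states(compute_speed(feature_acts), feature_acts, seed=0)
        f1 = boundary_f1(seg.transitions(), feature_rec.truth.transition_intervals)
        assert f1 > 0.9

    def test_segments_tile_grid_without_overlap(self, feature_acts):
        seg = segment_states(compute_speed(feature_acts), feature_acts, seed=0)
        covered = 0
        prev_end = 0
        for kind, s, e in seg.segments:
            assert s == prev_end
            prev_end = e
            covered += e - s
        assert covered == len(feature_acts.values)

    def test_constant_series_single_state(self):
        X = np.ones((600, 2)) + 1e-6 * np.random.default_rng(0).standard_normal((600, 2))
        seg = segment_states(compute_speed(series(X)), series(X), seed=0)
        assert len(seg.transitions()) == 0

    def test_three_planted_states_found(self):
        # drives off isolates the state-count selection
        from metastate import SynthConfig, generate_feature_stream
        cfg = SynthConfig(duration=86400.0, n_states=3, circadian_amplitude=0.0,
                          slow_axis_amplitude=0.0, state_osc_amplitude=0.0, seed=3)
        rec = generate_feature_stream(cfg)
        a = ActivationSeries(rec.truth.activations, rec.grid)
        seg = segment_states(compute_speed(a), a, seed=0)
        assert seg.n_state_clusters == 3

    def test_degenerate_min_dwell(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        seg = segment_states(compute_speed(series(X)), series(X), min_dwell=50, seed=0)
        assert seg.segments == [("state", 0, 10)]


class TestTrajectoryMetrics:
    def test_straight_line_ratio_exactly_one(self):
        X = np.outer(np.arange(20), [1.0, 2.0])
        tm = trajectory_metrics([(0, 20)], series(X))
        assert tm.ratios[0] == pytest.approx(1.0, abs=1e-12)

    def test_out_and_back_arithmetic(self):
        # 5 steps out, 4 back: length 9, displacement 1
        x = np.concatenate([np.arange(6.0), np.arange(5.0)[::-1][1:] + 1])
        X = np.column_stack([x, np.zeros_like(x)])
        tm = trajectory_metrics([(0, len(x))], series(X))
        assert tm.lengths[0] == pytest.approx(9.0)
        assert tm.displacements[0] == pytest.approx(1.0)
        assert tm.ratios[0] == pytest.approx(9.0)

    def test_zero_displacement_excluded(self):
        x = np.array([0.0, 1.0, 0.0])
        X = np.column_stack([x, np.zeros_like(x)])
        tm = trajectory_metrics([(0, 3)], series(X))
        assert np.isnan(tm.ratios[0])

    def test_transitions_more_circuitous_than_matched_states(self, feature_rec, feature_acts):
        truth = feature_rec.truth.transition_intervals
        states, prev = [], 0
        for s, e in truth:
            if s - prev >= 2:
                states.append((prev, s))
            prev = e
        tm = trajectory_metrics(truth, feature_acts)
        matched = duration_matched_state_ratios(truth, states, feature_acts, seed=0)
        assert np.nanmean(tm.ratios) > np.nanmean(matched)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ratio_at_least_one(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((rng.integers(3, 40), 3))
        tm = trajectory_metrics([(0, len(X))], series(X))
        if np.isfinite(tm.ratios[0]):
            assert tm.ratios[0] >= 1.0 - 1e-12


class TestDivergenceProfile:
    def _planted(self, feature_rec):
        vn = feature_rec.truth.slow_axis_value / feature_rec.config.slow_axis_amplitude
        n = feature_rec.grid.n_windows
        return [((o, nw), (s, e)) for (s, e, o, nw) in feature_rec.truth.transitions
                if vn[s] > 0.35 and vn[min(e, n - 1)] > 0.35]

    def test_identical_paths_zero_same_distance(self):
        path = np.cumsum(np.random.default_rng(0).standard_normal((10, 2)), axis=0)
        X = np.vstack([path, path, path + 5, path + 5])
        trans = [((0, 1), (0, 10)), ((0, 1), (10, 20)),
                 ((0, 2), (20, 30)), ((0, 2), (30, 40))]
        dp = divergence_profile(trans, series(X))
        assert np.allclose(dp.d_same, 0.0)

    def test_shared_start_zero_effect_at_origin(self, feature_rec, feature_acts):
        dp = divergence_profile(self._planted(feature_rec), feature_acts)
        assert abs(dp.cohens_d[0]) < 0.25

    def test_late_convergence_crosses_one_after_half(self, feature_rec, feature_acts):
        dp = divergence_profile(self._planted(feature_rec), feature_acts)
        crossing = np.flatnonzero(dp.cohens_d >= 1.0)
        assert len(crossing) > 0
        assert dp.progress[crossing[0]] > 0.5

    def test_insufficient_groups_named(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        with pytest.raises(ValueError, match="same-"):
            divergence_profile([((0, 1), (0, 10)), ((2, 3), (10, 20))], series(X))


class TestChaos01:
    @staticmethod
    def logistic(n, r=3.99, x0=0.3):
        x = np.empty(n)
        x[0] = x0
        for t in range(1, n):
            x[t] = r * x[t - 1] * (1 - x[t - 1])
        return x

    @staticmethod
    def reference_K(x, c_values):
        """Independent straight-line reference implementation (per c)."""
        x = np.asarray(x, float)
        N = len(x)
        ncut = N // 10
        Ks = []
        for c in c_values:
            p = np.zeros(N)
            q = np.zeros(N)
            acc_p = acc_q = 0.0
            for j in range(N):
                acc_p += x[j] * np.cos((j + 1) * c)
                acc_q += x[j] * np.sin((j + 1) * c)
                p[j], q[j] = acc_p, acc_q
            D = []
            for n in range(1, ncut + 1):
                M = np.mean((p[n:] - p[:-n]) ** 2 + (q[n:] - q[:-n]) ** 2)
                D.append(M - x.mean() ** 2 * (1 - np.cos(n * c)) / (1 - np.cos(c)))
            ns = np.arange(1, ncut + 1)
            D = np.array(D)
            Ks.append(np.corrcoef(ns, D)[0, 1] if D.std() > 0 else 0.0)
        return float(np.median(Ks))

    def test_logistic_map_chaotic(self):
        r = chaos01(self.logistic(5000), seed=0)
        assert r.K > 0.9

    def test_sinusoid_regular(self):
        t = np.arange(5000)
        r = chaos01(np.sin(2 * np.pi * t / 40), seed=0)
        assert abs(r.K) < 0.1

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        cs = rng.uniform(np.pi / 5, 4 * np.pi / 5, 20)
        x = self.logistic(2000)
        ours = chaos01(x, n_c=20, seed=0)
        assert ours.K == pytest.approx(self.reference_K(x, cs), abs=0.05)
        t = np.arange(2000)
        s = np.sin(2 * np.pi * t / 40)
        ours_s = chaos01(s, n_c=20, seed=0)
        assert ours_s.K == pytest.approx(self.reference_K(s, cs), abs=0.05)

    def test_constant_series_flagged_zero(self):
        r = chaos01(np.ones(1000), seed=0)
        assert r.K == 0.0 and r.degenerate

    def test_linear_rescaling_invariance(self):
        x = self.logistic(3000)
        a = chaos01(x, seed=0).K
        b = chaos01(7.3 * x - 2.1, seed=0).K
        assert a == pytest.approx(b, abs=0.02)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            chaos01(np.random.default_rng(0).standard_normal(100))

    def test_transition_windows_more_chaotic_than_states(self, feature_rec):
        from metastate._utils import contiguous_runs
        truth = feature_rec.truth
        n = feature_rec.grid.n_windows
        trans_w = np.zeros(n, bool)
        for s, e in truth.transition_intervals:
            trans_w[s:e] = True
        comps = [c for c in range(truth.activations.shape[1])
                 if c not in (truth.slow_axis_component, truth.v_pair[1])]
        Kt = chaos01(truth.activations[trans_w][:5000][:, comps], seed=0).K
        s0, e0 = max(contiguous_runs(~trans_w), key=lambda r: r[1] - r[0])
        Ks = chaos01(truth.activations[s0:e0][:, comps], seed=0).K
        assert Kt > Ks


class TestPowerLaw:
    def test_pareto_exponent_recovered_and_preferred(self):
        rng = np.random.default_rng(0)
        x = (1 - rng.random(10_000)) ** (-1 / 1.5)  # alpha = 2.5, xmin = 1
        fit = fit_powerlaw(x, discrete=False, xmin=1.0, n_bootstrap=50, seed=0)
        assert 2.4 <= fit.alpha <= 2.6
        stat, p = fit.lr_vs_exponential
        assert stat > 0 and p < 0.05
        assert fit.bootstrap_p > 0.1  # power law not rejected

    def test_exponential_data_rejected_or_dispreferred(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(3.0, 10_000) + 1
        fit = fit_powerlaw(x, discrete=False, n_bootstrap=50, seed=0)
        stat, p = fit.lr_vs_exponential
        assert fit.bootstrap_p < 0.1 or (stat < 0 and p < 0.05)

    def test_planted_discrete_dwell_exponent(self):
        from metastate import SynthConfig, generate_state_sequence
        cfg = SynthConfig(duration=1e5 * 5.0, n_states=2, dwell_exponent=2.5,
                          dwell_xmin=1, transition_len_range=(1, 1), seed=0)
        truth = generate_state_sequence(cfg)
        d, prev = [], 0
        for s, e in truth.transition_intervals:
            if s - prev > 0:
                d.append(s - prev)
            prev = e
        fit = fit_powerlaw(np.array(d), discrete=True, xmin=1, n_bootstrap=5, seed=0)
        assert fit.alpha == pytest.approx(2.5, abs=0.15)

    def test_short_tail_rejected(self):
        with pytest.raises(ValueError, match="tail too short"):
            fit_powerlaw(np.arange(1, 50, dtype=float), xmin=1.0)

    def test_alpha_above_one_invariant(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(1.0, 1.0, 5000)
        fit = fit_powerlaw(x, discrete=False, n_bootstrap=5, seed=0)
        assert fit.alpha > 1.0
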