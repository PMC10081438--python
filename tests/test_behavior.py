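"""Behavior decoding, transition coincidence, axis ordering, network map."""

import numpy as np
import pytest

from metastate.behavior import (attractor_distance_by_state, axis_ordering,
                                decode_behavior, manifold_network_map,
                                transition_coincidence)


class TestDecode:
    def _toy(self, nonlinear=False, seed=0):
        rng = np.random.default_rng(seed)
        n = 4000
        X = rng.standard_normal((n, 4))
        day = np.repeat([0, 1], n // 2)
        if nonlinear:
            score = X[:, 0] ** 2 + X[:, 1] ** 2
        else:
            score = X[:, 0] + 0.5 * X[:, 1]
        labels = np.where(score > np.median(score), "a", "b")
        lifted = np.column_stack([X, X ** 2])
        return X, lifted, labels, day

    def test_shuffled_labels_at_chance(self):
        X, lifted, labels, day = self._toy()
        rng = np.random.default_rng(1)
        res = decode_behavior(lifted, X, rng.permutation(labels), day, (0, 1),
                              smooth_windows=1)
        for cat in res.auc:
            assert 0.45 <= res.auc[cat]["koopman"] <= 0.55
            assert 0.45 <= res.auc[cat]["raw"] <= 0.55

    def test_linear_labels_decoded_by_both(self):
        X, lifted, labels, day = self._toy(nonlinear=False)
        res = decode_behavior(lifted, X, labels, day, (0, 1), smooth_windows=1)
        assert res.mean_auc["raw"] > 0.9
        assert res.mean_auc["koopman"] >= res.mean_auc["raw"] - 0.05

    def test_quadratic_labels_favor_lifted_features(self):
        X, lifted, labels, day = self._toy(nonlinear=True)
        res = decode_behavior(lifted, X, labels, day, (0, 1), smooth_windows=1)
        assert res.mean_auc["koopman"] > res.mean_auc["raw"]
        assert res.mean_auc["koopman"] > 0.9

    def test_underrepresented_category_skipped(self, caplog):
        X, lifted, labels, day = self._toy()
        labels = labels.copy()
        labels[:10] = "rare"
        res = decode_behavior(lifted, X, labels, day, (0, 1), smooth_windows=1)
        assert "rare" not in res.auc


class TestCoincidence:
    def test_perfect_coincidence(self):
        bursts = np.arange(100.0, 5000.0, 250.0)
        res = transition_coincidence(bursts, bursts[:20], span=5000.0,
                                     n_surrogates=199, min_shift=100.0, seed=0)
        assert res.statistic == 0.0
        assert res.p <= 1 / 200 + 1e-12

    def test_planted_state_coupling(self, feature_rec):
        rec = feature_rec
        bursts = np.array([rec.grid.start_times[s] for s, _ in rec.truth.transition_intervals])
        lab = rec.truth.behavior_labels
        changes = rec.grid.start_times[np.flatnonzero(lab[1:] != lab[:-1]) + 1]
        res = transition_coincidence(bursts, changes, span=rec.config.duration,
                                     n_surrogates=500, seed=0)
        assert res.p < 0.01
        assert res.statistic < res.null_mean

    def test_null_calibrated(self):
        rng = np.random.default_rng(0)
        ps = []
        for k in range(30):
            bursts = np.sort(rng.uniform(0, 4e5, 100))
            changes = np.sort(rng.uniform(0, 4e5, 50))
            ps.append(transition_coincidence(bursts, changes, 4e5,
                                             n_surrogates=99, seed=k).p)
        ps = np.array(ps)
        assert (ps < 0.05).mean() < 0.2
        assert 0.2 < np.median(ps)

    def test_requires_bursts_and_changes(self):
        with pytest.raises(ValueError, match="burst"):
            transition_coincidence([], np.arange(20.0), 100.0)
        with pytest.raises(ValueError, match="10"):
            transition_coincidence(np.arange(5.0), np.arange(5.0), 100.0)


class TestAttractorDistance:
    def test_all_windows_at_attractor(self):
        z = np.tile([1.0, 2.0], (100, 1))
        labels = np.array(["digital"] * 50 + ["wakeful_rest"] * 50)
        res = attractor_distance_by_state(z, labels, np.array([1.0, 2.0]))
        assert res["active_mean"] == 0.0 and res["rest_mean"] == 0.0

    def test_planted_departure_direction(self, feature_rec, feature_acts, day_index):
        from metastate.koopman import KoopmanEmbedding, find_attractor
        m = KoopmanEmbedding(heldout_days=(2, 3))
        m.fit(feature_acts, day_index=day_index)
        t, Z = m.encode(feature_acts)
        att = find_attractor(m, Z=Z)
        res = attractor_distance_by_state(Z, feature_rec.truth.behavior_labels[t], att.z_star)
        assert res["active_mean"] > res["rest_mean"]

    def test_invariant_under_orthogonal_rotation(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((200, 3))
        labels = np.array(["social", "wakeful_rest"] * 100)
        z_star = rng.standard_normal(3)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        a = attractor_distance_by_state(z, labels, z_star)
        b = attractor_distance_by_state(z @ Q.T, labels, Q @ z_star)
        assert a["active_mean"] == pytest.approx(b["active_mean"])

    def test_missing_rest_rejected(self):
        z = np.zeros((10, 2))
        with pytest.raises(ValueError, match="wakeful_rest"):
            attractor_distance_by_state(z, np.array(["digital"] * 10), np.zeros(2))


class TestAxisOrdering:
    NEIGHBORS = [("active", "wakeful_rest"), ("wakeful_rest", "N1"),
                 ("N1", "REM"), ("REM", "N2/N3")]

    def _cohort(self, n_rec=4, seed=0):
        rng = np.random.default_rng(seed)
        means = {"active": 2.0, "wakeful_rest": 1.0, "N1": 0.0, "REM": -1.0, "N2/N3": -2.0}
        alongs, labels = [], []
        for r in range(n_rec):
            lab = rng.choice(list(means), size=2000)
            along = np.array([means[c] for c in lab]) + 0.3 * rng.standard_normal(2000) \
                + 0.1 * rng.standard_normal()
            alongs.append(along)
            labels.append(lab)
        return alongs, labels

    def test_planted_ordering_recovered(self):
        alongs, labels = self._cohort()
        res = axis_ordering(alongs, labels, self.NEIGHBORS)
        order = ["active", "wakeful_rest", "N1", "REM", "N2/N3"]
        cents = [np.mean(res.centroids[c]) for c in order]
        assert all(a > b for a, b in zip(cents, cents[1:]))
        for pair in self.NEIGHBORS:
            assert res.neighbor_tests[pair][2]  # significant

    def test_duplicated_category_not_significant(self):
        rng = np.random.default_rng(1)
        alongs, labels = [], []
        for r in range(4):
            lab = rng.choice(["a", "b"], size=1000)
            along = rng.standard_normal(1000)
            alongs.append(along)
            labels.append(lab)
        res = axis_ordering(alongs, labels, [("a", "b")])
        assert not res.neighbor_tests[("a", "b")][2]

    def test_requires_multiple_recordings(self):
        with pytest.raises(ValueError, match="recordings"):
            axis_ordering([np.zeros(100)], [np.array(["a"] * 100)], [])


class TestNetworkMap:
    def test_identity_series_spearman_one(self):
        rng = np.random.default_rng(0)
        alongs, groups = [], []
        for r in range(3):
            x = rng.standard_normal(500)
            alongs.append(x)
            groups.append({("default", "theta"): x.copy(),
                           ("visual", "gamma"): rng.standard_normal(500)})
        res = manifold_network_map(alongs, groups)
        assert res[("default", "theta")]["mean_r"] == pytest.approx(1.0)
        assert res[("default", "theta")]["significant"]

    def test_independent_noise_centered_at_zero(self):
        rng = np.random.default_rng(1)
        alongs, groups = [], []
        for r in range(8):
            alongs.append(rng.standard_normal(400))
            groups.append({(n, b): rng.standard_normal(400)
                           for n in ("default", "visual") for b in ("theta", "alpha")})
        res = manifold_network_map(alongs, groups)
        rs = [v["mean_r"] for v in res.values()]
        assert abs(np.mean(rs)) < 0.15
        assert sum(v["significant"] for v in res.values()) <= 1
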