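"""Koopman operator learning, spectrum, attractor, manifold and flow field."""

import numpy as np
import pytest

from metastate.koopman import (KoopmanEmbedding, center_manifold, find_attractor,
                               flow_field, solve_fixed_point, spectrum,
                               along_coordinate)


def constant_segments_data(n_segments=8, seg_len=400, dim=3, seed=0):
    """Identity dynamics: several constant trajectories, one per 'day'."""
    rng = np.random.default_rng(seed)
    segs, days = [], []
    for d in range(n_segments):
        segs.append(np.tile(rng.standard_normal(dim), (seg_len, 1)))
        days.append(np.full(seg_len, d))
    return np.vstack(segs), np.concatenate(days)


class TestOperatorLearning:
    def test_identity_dynamics_unit_eigenvalue(self):
        X, day = constant_segments_data()
        m = KoopmanEmbedding(context_len=4, n_lags=2, poly_degree=1,
                             heldout_days=(6, 7))
        m.fit(X, day_index=day)
        assert abs(abs(m.eigenvalues_[0]) - 1.0) < 0.02
        # multi-step prediction error stays near the reconstruction level
        # (ridge shrinkage contributes ~(1 - |lambda|) * H per step)
        assert m.training_log_["multi_step"] < m.training_log_["reconstruction"] + 0.05

    def test_linear_system_spectrum_recovered(self):
        th = 0.3
        A = 0.95 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rng = np.random.default_rng(0)
        n = 20_000
        X = np.zeros((n, 2))
        X[0] = [1, 0]
        for t in range(1, n):
            X[t] = A @ X[t - 1] + 0.05 * rng.standard_normal(2)
        m = KoopmanEmbedding(context_len=4, n_lags=2, poly_degree=2)
        m.fit(X)
        assert abs(np.abs(m.eigenvalues_[0]) - 0.95) < 0.02
        assert abs(np.abs(m.eigenvalues_[1]) - 0.95) < 0.02

    def test_polynomial_embedding_spectrum(self):
        # x1 <- 0.9 x1; x2 <- 0.5 x2 + (0.81 - 0.5) x1^2 has the exact
        # 3-observable linear lift {x1, x2, x1^2} with spectrum {0.9, 0.5, 0.81}
        rng = np.random.default_rng(1)
        n = 8000
        X = np.zeros((n, 2))
        X[0] = [1.0, 0.3]
        for t in range(1, n):
            if t % 400 == 0:
                X[t] = rng.uniform(-1, 1, 2)
                continue
            x1, x2 = X[t - 1]
            X[t] = [0.9 * x1, 0.5 * x2 + (0.81 - 0.5) * x1 ** 2]
        m = KoopmanEmbedding(context_len=1, n_lags=0, poly_degree=2, ridge_alpha=1e-10)
        m.fit(X)
        for target in (0.9, 0.5, 0.81):
            assert np.min(np.abs(m.eigenvalues_ - target)) < 0.05

    def test_latent_multistep_is_repeated_affine_map(self):
        X, day = constant_segments_data(seed=3)
        m = KoopmanEmbedding(context_len=3, n_lags=1, poly_degree=1)
        m.fit(X)
        t, Z = m.encode(X)
        z = Z[:5]
        for _ in range(4):
            z = z @ m.operator_.T + m.bias_
        _, pred = m.predict(X, steps=4)
        assert np.allclose(pred[:5], m.decode(z), atol=1e-10)

    def test_heldout_days_require_day_index(self):
        X, _ = constant_segments_data()
        with pytest.raises(ValueError, match="day_index"):
            KoopmanEmbedding(heldout_days=(0, 1)).fit(X)

    def test_exactly_two_heldout_days(self):
        X, day = constant_segments_data()
        with pytest.raises(ValueError, match="two"):
            KoopmanEmbedding(heldout_days=(0, 1, 2)).fit(X, day_index=day)

    def test_training_pairs_avoid_heldout_windows(self, feature_acts, day_index):
        # index audit is built in: a successful fit implies no leakage
        m = KoopmanEmbedding(heldout_days=(2, 3))
        m.fit(feature_acts, day_index=day_index)
        assert m.training_log_["n_pairs"] > 0


class TestSpectrum:
    def test_scaled_identity(self):
        m = KoopmanEmbedding()
        m.operator_ = 0.5 * np.eye(4)
        m.eigenvalues_, m.modes_ = np.linalg.eig(m.operator_)
        spec = spectrum(m)
        assert np.allclose(spec.eigenvalues, 0.5)
        assert spec.max_modulus == pytest.approx(0.5)

    def test_scaled_rotation_complex_pair(self):
        th = 0.7
        m = KoopmanEmbedding()
        m.operator_ = 0.9 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lam, modes = np.linalg.eig(m.operator_)
        m.eigenvalues_, m.modes_ = lam, modes
        spec = spectrum(m)
        assert np.allclose(np.abs(spec.eigenvalues), 0.9)
        assert np.allclose(np.sort(np.angle(spec.eigenvalues)), [-th, th])

    def test_matches_characteristic_roots(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 5)) * 0.3
        m = KoopmanEmbedding()
        m.operator_ = A
        lam, modes = np.linalg.eig(A)
        m.eigenvalues_, m.modes_ = lam, modes
        spec = spectrum(m)
        roots = np.roots(np.poly(A))
        assert np.allclose(np.sort_complex(spec.eigenvalues), np.sort_complex(roots),
                           atol=1e-8)


class TestFixedPoint:
    def test_homogeneous_case(self):
        z, deflated = solve_fixed_point(0.5 * np.eye(3), np.zeros(3))
        assert np.allclose(z, 0.0) and not deflated

    def test_scalar_geometric_series(self):
        z, _ = solve_fixed_point(np.array([[0.5]]), np.array([1.0]))
        assert z[0] == pytest.approx(2.0)

    def test_unit_eigenvalue_deflated_and_flagged(self):
        K = np.diag([1.0, 0.5])
        z, deflated = solve_fixed_point(K, np.array([0.3, 1.0]))
        assert deflated
        assert z[1] == pytest.approx(2.0)

    def test_residual_invariant_on_contractive_model(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5000, 3)) * 0.5
        # strongly mean-reverting synthetic dynamics
        for t in range(1, len(X)):
            X[t] = 0.5 * X[t - 1] + np.array([1.0, -0.5, 0.2]) + 0.1 * X[t]
        m = KoopmanEmbedding(context_len=2, n_lags=1, poly_degree=1)
        m.fit(X)
        att = find_attractor(m)
        if not att.deflated:
            assert att.residual < 1e-6 * max(np.linalg.norm(att.z_star), 1.0)


class TestCenterManifold:
    def _diag_model(self, entries):
        m = KoopmanEmbedding()
        m.operator_ = np.diag(entries)
        m.bias_ = np.zeros(len(entries))
        lam, modes = np.linalg.eig(m.operator_)
        order = np.argsort(-np.abs(lam))
        m.eigenvalues_, m.modes_ = lam[order], modes[:, order]
        return m

    def test_diagonal_operator_selects_slowest_axis(self):
        m = self._diag_model([0.99, 0.5, 0.1])
        man = center_manifold(m, n_axes=1)
        axis = np.abs(man.axis[0])
        assert axis[0] == pytest.approx(1.0)
        assert np.allclose(axis[1:], 0.0, atol=1e-10)
        assert man.eigenvalues[0] == pytest.approx(0.99)

    def test_projectors_sum_to_identity(self):
        rng = np.random.default_rng(0)
        A = 0.5 * rng.standard_normal((6, 6))
        m = KoopmanEmbedding()
        m.operator_ = A
        lam, modes = np.linalg.eig(A)
        m.eigenvalues_, m.modes_ = lam, modes
        man = center_manifold(m, n_axes=2)
        assert np.allclose(man.projector_along + man.projector_off, np.eye(6), atol=1e-8)
        v = rng.standard_normal(6)
        assert np.allclose(man.projector_along @ v + man.projector_off @ v, v)

    def test_n_axes_bounded(self):
        m = self._diag_model([0.9, 0.5])
        with pytest.raises(ValueError, match="n_axes"):
            center_manifold(m, n_axes=5)

    def test_along_coordinate_tracks_planted_slow_axis(self, feature_rec, feature_acts, day_index):
        m = KoopmanEmbedding(heldout_days=(2, 3))
        m.fit(feature_acts, day_index=day_index)
        man = center_manifold(m, spectrum(m))
        t, Z = m.encode(feature_acts)
        along = along_coordinate(man, Z)
        r = np.corrcoef(along, feature_rec.truth.slow_axis_value[t])[0, 1]
        assert abs(r) > 0.8


class TestAttractorAndFlow:
    def test_planted_attractor_recovered(self, feature_rec, feature_acts, day_index):
        m = KoopmanEmbedding(heldout_days=(2, 3))
        m.fit(feature_acts, day_index=day_index)
        t, Z = m.encode(feature_acts)
        att = find_attractor(m, Z=Z,
                             feature_groups=feature_rec.truth.feature_index,
                             component_loadings=feature_rec.truth.component_loadings)
        tr = feature_rec.truth.attractor_point
        d = np.linalg.norm(att.decoded_pattern - tr) / np.linalg.norm(tr)
        assert d < 0.1
        # the planted default-mode/theta features carry the largest signature
        top = max(att.network_signature, key=lambda k: abs(att.network_signature[k]))
        assert top == ("default", "theta")

    def test_flow_points_toward_attractor_for_contraction(self):
        m = KoopmanEmbedding()
        m.operator_ = 0.7 * np.eye(2)
        m.bias_ = np.array([0.3, 0.0])  # fixed point at (1, 0)
        m.decoder_ = np.eye(2)
        m.decoder_bias_ = np.zeros(2)
        m.mean_ = np.zeros(2)
        m.scale_ = np.ones(2)
        lam, modes = np.linalg.eig(m.operator_)
        m.eigenvalues_, m.modes_ = lam, modes
        rng = np.random.default_rng(0)
        Z = rng.uniform(-3, 3, (500, 2))
        ff = flow_field(m, Z, projection=np.eye(2), n_cells=6)
        z_star = np.array([1.0, 0.0])
        cos = []
        for i in range(6):
            for j in range(6):
                if not ff.supported[i, j]:
                    continue
                cx = 0.5 * (ff.grid_x[i] + ff.grid_x[i + 1])
                cy = 0.5 * (ff.grid_y[j] + ff.grid_y[j + 1])
                to_att = z_star - np.array([cx, cy])
                d = ff.displacement[i, j]
                if np.linalg.norm(to_att) > 0.3 and np.linalg.norm(d) > 0:
                    cos.append(np.dot(d, to_att) / np.linalg.norm(d) / np.linalg.norm(to_att))
        assert np.mean(cos) > 0.7

    def test_flow_vanishes_at_fixed_point(self):
        m = KoopmanEmbedding()
        m.operator_ = 0.7 * np.eye(2)
        m.bias_ = np.zeros(2)
        lam, modes = np.linalg.eig(m.operator_)
        m.eigenvalues_, m.modes_ = lam, modes
        Z = np.vstack([np.zeros(2), np.ones(2) * 1e-9])
        ff = flow_field(m, Z, projection=np.eye(2), n_cells=2)
        mags = np.linalg.norm(ff.displacement[ff.supported], axis=-1)
        assert np.nanmin(mags) < 1e-6
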