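"""Koopman embedding of activation dynamics with attractor and center manifold.

The activation series is lifted into a higher-dimensional observable space
in which one-step evolution is (affine) linear: ``z[t+1] ~ K z[t] + b``.
The lifting is a fixed nonlinear dictionary built from a delay context
(lagged copies of the activations over ``context_len`` windows) and
polynomial observables (squares and pairwise products), so the operator,
decoder and spectrum all have closed-form ridge estimates; the encoder is
deterministic and self-supervised in the sense that the training signal is
the series' own future. The three training losses (reconstruction, one-step
latent prediction, multi-step rollout) are computed and logged.

Downstream analyses are linear-algebraic: the spectrum of ``K``; the central
attractor ``z* = (I - K)^(-1) b`` decoded back to activation space; the
center manifold spanned by the modes with eigenvalue modulus closest to 1,
with complementary along/off projectors; and a flow field of expected
one-step displacements over a 2-D projection.

Two whole days are held out of operator fitting ("held-out days") so that
behavior decoding in the latent space can be evaluated across disjoint days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .chaos import chaos01
from .components import ActivationSeries

__all__ = [
    "KoopmanEmbedding", "KoopmanSpectrum", "spectrum", "AttractorState",
    "find_attractor", "solve_fixed_point", "CenterManifold", "center_manifold",
    "FlowField", "flow_field", "compare_along_off",
]

logger = logging.getLogger(__name__)


class KoopmanEmbedding(BaseEstimator):
    """Affine Koopman operator on a delay + polynomial observable dictionary.

    Parameters
    ----------
    context_len : int
        Delay context in windows (default 24 = 2 minutes of 5-s windows).
    n_lags : int
        Number of lagged copies of the activations included in the
        dictionary, spread evenly over the context.
    poly_degree : int
        1 disables polynomial observables; 2 adds squares and pairwise
        products of the current activations.
    ridge_alpha : float
        Ridge penalty (relative to the mean squared observable scale) for
        the operator and decoder fits.
    horizon : int
        Rollout length H for the logged multi-step loss.
    loss_weights : (w_recon, w_onestep, w_multistep)
        Weights used for the logged total loss.
    heldout_days : tuple of int or None
        Exactly two day indices excluded from operator fitting when a
        ``day_index`` is passed to :meth:`fit`.

    Attributes
    ----------
    operator_ : (D, D) Koopman matrix
    bias_ : (D,) affine term
    eigenvalues_, modes_ : spectrum of ``operator_``, modulus-sorted
    training_log_ : dict of logged losses
    """

    def __init__(self, context_len: int = 24, n_lags: int = 4, poly_degree: int = 2,
                 ridge_alpha: float = 1e-6, horizon: int = 8,
                 loss_weights=(1.0, 1.0, 0.5), heldout_days=None, seed: int = 0):
        self.context_len = context_len
        self.n_lags = n_lags
        self.poly_degree = poly_degree
        self.ridge_alpha = ridge_alpha
        self.horizon = horizon
        self.loss_weights = loss_weights
        self.heldout_days = heldout_days
        self.seed = seed

    # ---------------------------------------------------------------- lifting
    def _lag_offsets(self):
        if self.n_lags == 0 or self.context_len <= 1:
            return []
        return sorted({int(round(l)) for l in
                       np.linspace(1, self.context_len - 1, self.n_lags)} - {0})

    def _lift_names(self, d):
        names = [f"x{i}" for i in range(d)]
        for lag in self._lag_offsets():
            names += [f"x{i}[t-{lag}]" for i in range(d)]
        if self.poly_degree >= 2:
            names += [f"x{i}*x{j}" for i in range(d) for j in range(i, d)]
        return names

    def _lift(self, X, t_idx):
        """Observable vectors at the given time indices (context must fit)."""
        d = X.shape[1]
        cols = [X[t_idx]]
        for lag in self._lag_offsets():
            cols.append(X[t_idx - lag])
        if self.poly_degree >= 2:
            cur = X[t_idx]
            iu = np.triu_indices(d)
            cols.append(cur[:, iu[0]] * cur[:, iu[1]])
        return np.concatenate(cols, axis=1)

    def _valid_times(self, n, keep, day=None, days=None):
        """Times whose full context is retained (and inside allowed days)."""
        ok = keep.copy()
        if days is not None:
            ok &= np.isin(day, days)
        C = max(self.context_len, max(self._lag_offsets(), default=0) + 1)
        valid = np.zeros(n, dtype=bool)
        run = 0
        for t in range(n):
            run = run + 1 if ok[t] else 0
            if run >= C:
                valid[t] = True
        return valid

    # ---------------------------------------------------------------- fitting
    def fit(self, X, y=None, day_index=None, keep_mask=None):
        """Fit operator, bias and decoder on all non-held-out windows.

        Parameters
        ----------
        X : (n, d) activation matrix or :class:`ActivationSeries`
        day_index : (n,) int day label per window; required when
            ``heldout_days`` is set.
        """
        if isinstance(X, ActivationSeries):
            if keep_mask is None and X.grid is not None:
                keep_mask = X.grid.keep_mask
            X = X.values
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        keep = np.ones(n, bool) if keep_mask is None else np.asarray(keep_mask, bool)
        if self.heldout_days is not None:
            if day_index is None:
                raise ValueError("heldout_days set but no day_index given")
            if len(set(self.heldout_days)) != 2:
                raise ValueError("exactly two held-out day indices are required")
        day_index = None if day_index is None else np.asarray(day_index)
        train_days = None
        if self.heldout_days is not None:
            train_days = np.setdiff1d(np.unique(day_index), list(self.heldout_days))
        C = max(self.context_len, max(self._lag_offsets(), default=0) + 1)
        if keep.sum() < 10 * C:
            raise ValueError("training span must cover at least 10x the context length")

        self.mean_ = X[keep].mean(axis=0)
        self.scale_ = X[keep].std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_

        valid = self._valid_times(n, keep, day_index, train_days)
        pair = valid[:-1] & valid[1:]
        t0 = np.flatnonzero(pair)
        if self.heldout_days is not None:
            # audit: no training pair touches a held-out window
            held = np.isin(day_index, list(self.heldout_days))
            if held[t0].any() or held[t0 + 1].any():
                raise AssertionError("held-out windows leaked into training pairs")
        if len(t0) < 10:
            raise ValueError("too few contiguous training pairs")
        Z0 = self._lift(Xs, t0)
        Z1 = self._lift(Xs, t0 + 1)
        D = Z0.shape[1]
        self.n_features_in_ = d
        self.latent_dim_ = D

        self.latent_mean_ = Z0.mean(axis=0)
        A = np.column_stack([Z0, np.ones(len(Z0))])
        scale2 = np.mean(A * A)
        G = A.T @ A + self.ridge_alpha * scale2 * len(A) * np.eye(D + 1)
        W = np.linalg.solve(G, A.T @ Z1)
        self.operator_ = W[:D].T
        self.bias_ = W[D].copy()

        # decoder: lifted state -> current (standardized) activations
        Wd = np.linalg.solve(G, A.T @ Xs[t0])
        self.decoder_ = Wd[:D].T
        self.decoder_bias_ = Wd[D].copy()

        lam, modes = np.linalg.eig(self.operator_)
        order = np.argsort(-np.abs(lam))
        self.eigenvalues_ = lam[order]
        self.modes_ = modes[:, order]

        # training losses (logged)
        recon = float(np.mean((self._decode(Z0) - Xs[t0]) ** 2))
        one_step = float(np.mean((self._advance(Z0) - Z1) ** 2))
        multi = self._rollout_loss(Xs, t0, valid)
        w = self.loss_weights
        self.training_log_ = {
            "reconstruction": recon,
            "one_step": one_step,
            "multi_step": multi,
            "total": w[0] * recon + w[1] * one_step + w[2] * multi,
            "n_pairs": int(len(t0)),
        }
        logger.info("koopman fit: %s", self.training_log_)
        return self

    def _rollout_loss(self, Xs, t0, valid):
        H = self.horizon
        ok = t0[(t0 + H < len(Xs))]
        if len(ok) == 0:
            return np.nan
        # only starts whose whole rollout stays valid
        good = np.array([valid[t:t + H + 1].all() for t in ok])
        ok = ok[good]
        if len(ok) == 0:
            return np.nan
        if len(ok) > 2000:
            ok = ok[np.linspace(0, len(ok) - 1, 2000).astype(int)]
        Z = self._lift(Xs, ok)
        err = 0.0
        for h in range(1, H + 1):
            Z = self._advance(Z)
            err += np.mean((self._decode(Z) - Xs[ok + h]) ** 2)
        return float(err / H)

    # ------------------------------------------------------------- inference
    def _advance(self, Z):
        return Z @ self.operator_.T + self.bias_

    def _decode(self, Z):
        return Z @ self.decoder_.T + self.decoder_bias_

    def encode(self, X, keep_mask=None):
        """Lifted trajectory; returns (time indices, lifted states)."""
        check_is_fitted(self, "operator_")
        if isinstance(X, ActivationSeries):
            if keep_mask is None and X.grid is not None:
                keep_mask = X.grid.keep_mask
            X = X.values
        X = np.asarray(X, dtype=float)
        keep = np.ones(len(X), bool) if keep_mask is None else np.asarray(keep_mask, bool)
        Xs = (X - self.mean_) / self.scale_
        valid = self._valid_times(len(X), keep)
        t = np.flatnonzero(valid)
        return t, self._lift(Xs, t)

    def decode(self, Z):
        """Map lifted states back to activation space (un-standardized)."""
        check_is_fitted(self, "operator_")
        return self._decode(np.atleast_2d(Z)) * self.scale_ + self.mean_

    def predict(self, X, steps: int = 1, keep_mask=None):
        """Roll the affine operator forward; returns decoded activations.

        The latent multi-step prediction is exactly repeated application of
        ``(K, b)`` (linearity contract).
        """
        t, Z = self.encode(X, keep_mask)
        for _ in range(steps):
            Z = self._advance(Z)
        return t + steps, self.decode(Z)


@dataclass
class KoopmanSpectrum:
    eigenvalues: np.ndarray
    modes: np.ndarray
    max_modulus: float
    defective: bool = False


def spectrum(model: KoopmanEmbedding) -> KoopmanSpectrum:
    """Modulus-sorted eigendecomposition of the fitted operator."""
    check_is_fitted(model, "operator_")
    lam, modes = model.eigenvalues_, model.modes_
    resid = np.linalg.norm(model.operator_ @ modes - modes * lam[None, :], axis=0)
    defective = bool(np.any(resid > 1e-6 * max(np.abs(lam).max(), 1.0)))
    if defective:  # fall back to Schur invariant subspaces
        from scipy.linalg import schur
        T, Q = schur(model.operator_, output="complex")
        lam = np.diag(T)
        order = np.argsort(-np.abs(lam))
        lam, modes = lam[order], Q[:, order]
        logger.warning("defective operator: using Schur vectors")
    return KoopmanSpectrum(lam, modes, float(np.abs(lam).max()), defective)


@dataclass
class AttractorState:
    z_star: np.ndarray
    decoded_pattern: np.ndarray
    residual: float
    deflated: bool = False
    network_signature: dict = None


def solve_fixed_point(K, b, unit_tol: float = 1e-6, anchor=None):
    """Solve ``(I - K) z = b``; modes with eigenvalue ~ 1 are deflated.

    Returns (z_star, deflated flag). When ``|1 - lambda| < unit_tol`` the
    mode barely decays, so ``b/(1 - lambda)`` amplifies estimation noise
    arbitrarily and the fixed point is effectively non-unique along it; the
    solve proceeds in the complement and those mode coordinates are anchored
    at ``anchor`` (a representative latent state, e.g. the training mean; 0
    when not given), with the result flagged.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    lam, V = np.linalg.eig(K)
    near_one = np.abs(lam - 1.0) < max(unit_tol, 1e-12)
    if near_one.any():
        keep = ~near_one
        Vi = np.linalg.inv(V)
        beta = Vi @ b.astype(complex)
        alpha = np.zeros_like(beta) if anchor is None else Vi @ np.asarray(anchor, complex)
        alpha[keep] = beta[keep] / (1.0 - lam[keep])
        return np.real(V @ alpha), True
    return np.linalg.solve(np.eye(len(b)) - K, b), False


def find_attractor(model: KoopmanEmbedding, feature_groups=None,
                   component_loadings=None, unit_tol: float = 0.05,
                   Z=None) -> AttractorState:
    """Central attractor: the fixed point of the affine latent update.

    Center-like modes (``|1 - lambda| < unit_tol``, i.e. decay times beyond
    ~1/unit_tol steps or very slow oscillations) carry persistent structure
    rather than attraction and amplify estimation noise in the fixed-point
    solve; they are excluded first, anchored at the mean of the analyzed
    lifted trajectory ``Z`` (the training-mean latent state when ``Z`` is
    not given), and the result is flagged as deflated. ``decoded_pattern`` is the
    attractor decoded to activation space. When ``component_loadings``
    (components x features) and ``feature_groups`` (feature -> group key,
    e.g. (network, band)) are given, the signature aggregates the
    attractor's feature-space pattern per group; otherwise the signature is
    per activation component.
    """
    check_is_fitted(model, "operator_")
    anchor = np.asarray(Z).mean(axis=0) if Z is not None else getattr(model, "latent_mean_", None)
    z_star, deflated = solve_fixed_point(model.operator_, model.bias_, unit_tol,
                                         anchor=anchor)
    resid = float(np.linalg.norm(model.operator_ @ z_star + model.bias_ - z_star))
    decoded = model.decode(z_star)[0]
    signature = {}
    if component_loadings is not None and feature_groups is not None:
        pattern = decoded @ np.asarray(component_loadings)
        groups = {}
        for f, key in enumerate(feature_groups):
            groups.setdefault(key, []).append(pattern[f])
        signature = {k: float(np.mean(v)) for k, v in groups.items()}
    else:
        signature = {f"component_{i}": float(v) for i, v in enumerate(decoded)}
    return AttractorState(z_star, decoded, resid, deflated, signature)


@dataclass
class CenterManifold:
    axis: np.ndarray             # (n_real_dims, D) real basis of the slow modes
    left_axis: np.ndarray        # matching rows of the left eigenbasis
    projector_along: np.ndarray  # (D, D)
    projector_off: np.ndarray
    eigenvalues: np.ndarray      # the selected (slowest-decaying) eigenvalues
    orientation: float = 1.0


def center_manifold(model: KoopmanEmbedding, spec: KoopmanSpectrum = None,
                    n_axes: int = 1) -> CenterManifold:
    """Span of the modes whose eigenvalue modulus is closest to 1.

    A complex conjugate pair contributes two real dimensions. The along/off
    projectors are the spectral (oblique) projectors onto the selected modes
    and their complement; they sum to the identity exactly.
    """
    check_is_fitted(model, "operator_")
    if spec is None:
        spec = spectrum(model)
    D = model.operator_.shape[0]
    if n_axes > D:
        raise ValueError("n_axes exceeds the latent dimension")
    lam = spec.eigenvalues
    order = np.argsort(np.abs(np.abs(lam) - 1.0))
    used = set()
    for idx in order:
        idx = int(idx)
        if idx in used:
            continue
        used.add(idx)
        if abs(lam[idx].imag) > 1e-12:
            # include the conjugate partner of a complex mode
            others = [k for k in range(len(lam)) if k not in used]
            if others:
                conj = min(others, key=lambda k: abs(lam[k] - np.conj(lam[idx])))
                used.add(conj)
        if len(used) >= n_axes:
            break
    sel = np.zeros(len(lam), dtype=bool)
    sel[list(used)] = True
    V = spec.modes
    Vi = np.linalg.inv(V) if not spec.defective else np.linalg.pinv(V)
    P_along = np.real(V[:, sel] @ Vi[sel, :])
    P_off = np.eye(D) - P_along
    # real orthonormal basis of the selected mode span
    raw = np.column_stack([f(V[:, sel]) for f in (np.real, np.imag)])
    q, r = np.linalg.qr(raw)
    rank = (np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1e-30)).sum()
    axis = q[:, :rank].T
    left = np.real(Vi[sel, :])
    left = left / np.linalg.norm(left, axis=1, keepdims=True)
    return CenterManifold(axis, left, P_along, P_off, lam[sel])


def along_coordinate(manifold: CenterManifold, Z):
    """Scalar (or low-D) coordinate of lifted states along the center manifold."""
    coord = np.atleast_2d(Z) @ manifold.left_axis.T * manifold.orientation
    return coord[:, 0] if coord.shape[1] == 1 else coord


def orient_axis(manifold: CenterManifold, along_values, wake_mask, sleep_mask):
    """Fix the axis sign so the wake centroid exceeds the sleep centroid."""
    if wake_mask.any() and sleep_mask.any():
        if np.mean(along_values[wake_mask]) < np.mean(along_values[sleep_mask]):
            manifold.orientation = -manifold.orientation
    return manifold


@dataclass
class FlowField:
    grid_x: np.ndarray
    grid_y: np.ndarray
    displacement: np.ndarray  # (nx, ny, 2); NaN where unsupported
    supported: np.ndarray     # (nx, ny) bool


def flow_field(model: KoopmanEmbedding, Z, projection=None, n_cells: int = 12) -> FlowField:
    """Expected one-step displacement over a 2-D projection of the latent space.

    ``projection`` is a (2, D) matrix; default is the top-2 PCA of ``Z``.
    Each data-supported cell uses the mean lifted state of its members as
    representative; the displacement at the projected attractor vanishes.
    """
    check_is_fitted(model, "operator_")
    Z = np.asarray(Z)
    if projection is None:
        Zc = Z - Z.mean(axis=0)
        _, _, Vt = np.linalg.svd(Zc, full_matrices=False)
        projection = Vt[:2]
    P = np.asarray(projection)
    xy = Z @ P.T
    gx = np.linspace(xy[:, 0].min(), xy[:, 0].max(), n_cells + 1)
    gy = np.linspace(xy[:, 1].min(), xy[:, 1].max(), n_cells + 1)
    disp = np.full((n_cells, n_cells, 2), np.nan)
    sup = np.zeros((n_cells, n_cells), dtype=bool)
    ix = np.clip(np.searchsorted(gx, xy[:, 0], side="right") - 1, 0, n_cells - 1)
    iy = np.clip(np.searchsorted(gy, xy[:, 1], side="right") - 1, 0, n_cells - 1)
    for i in range(n_cells):
        for j in range(n_cells):
            m = (ix == i) & (iy == j)
            if not m.any():
                continue
            z = Z[m].mean(axis=0)
            disp[i, j] = P @ (model.operator_ @ z + model.bias_) - P @ z
            sup[i, j] = True
    return FlowField(gx, gy, disp, sup)


def compare_along_off(model: KoopmanEmbedding, manifold: CenterManifold, X,
                      keep_mask=None, max_lag: int = 200, n_off_pcs: int = 3,
                      chaos_kwargs=None):
    """Autocorrelation and 0-1 chaos of along- vs off-manifold dynamics.

    The lifted trajectory is split by the manifold projectors; the along
    part is its (low-D) eigencoordinate, the off part is summarized by its
    top principal components. Returns a dict with both autocorrelation
    curves and both chaos statistics.
    """
    t, Z = model.encode(X, keep_mask)
    along = np.atleast_2d(Z @ manifold.left_axis.T * manifold.orientation)
    off = Z @ manifold.projector_off.T
    offc = off - off.mean(axis=0)
    _, _, Vt = np.linalg.svd(offc, full_matrices=False)
    off_pcs = offc @ Vt[:n_off_pcs].T
    if along.std() == 0 or off_pcs.std() == 0:
        logger.warning("degenerate along/off split (zero variance)")

    def acf(x, L):
        x = x - x.mean()
        denom = np.sum(x * x)
        return np.array([np.sum(x[:-k] * x[k:]) / denom if k else 1.0 for k in range(L)])

    kw = chaos_kwargs or {}
    return {
        "times": t,
        "along": along[:, 0] if along.shape[1] == 1 else along,
        "off": off_pcs,
        "acf_along": acf(along[:, 0], max_lag),
        "acf_off": acf(off_pcs[:, 0], max_lag),
        "chaos_along": chaos01(along, **kw),
        "chaos_off": chaos01(off_pcs, **kw),
    }
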