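"""Linking network activations to circadian time-of-day and heart rate.

Both links follow a strict split-half protocol: models are fit on the first
temporal half of retained windows and evaluated with frozen weights on the
second half. Time of day is encoded circularly as (sin, cos) of the 24-h
phase and linked by canonical correlation analysis; heart rate is linked by
L1-regularized regression with the penalty chosen by blocked (contiguous)
cross-validation inside the training half. Because both the activations and
the targets are strongly autocorrelated, significance comes from circular
time-shift surrogates of the held-out target (minimum shift two hours), not
i.i.d. shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import CCA
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .components import ActivationSeries

__all__ = ["CircadianTarget", "LinkResult", "link_circadian", "link_heart_rate"]

SECONDS_PER_DAY = 86400.0


@dataclass
class CircadianTarget:
    phase: np.ndarray      # radians in [0, 2pi)
    encoding: np.ndarray   # (n, 2) = (sin, cos), unit norm per row

    @classmethod
    def from_times(cls, t_seconds, t0: float = 0.0):
        phase = 2 * np.pi * (((np.asarray(t_seconds, float) + t0) % SECONDS_PER_DAY) / SECONDS_PER_DAY)
        return cls(phase, np.column_stack([np.sin(phase), np.cos(phase)]))


@dataclass
class LinkResult:
    kind: str
    weights: np.ndarray
    train_r: float
    test_r: float
    perm_p: float
    n_perm: int
    support: np.ndarray = None   # nonzero-coefficient mask (heart rate)


def _halves(n):
    h = n // 2
    return np.arange(h), np.arange(h, n)


def _shift_offsets(rng, n, n_perm, min_shift):
    if n - min_shift <= min_shift:
        return rng.integers(1, n, size=n_perm)
    return rng.integers(min_shift, n - min_shift, size=n_perm)


def _safe_corr(a, b):
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def link_circadian(a: ActivationSeries, target: CircadianTarget, n_perm: int = 200,
                   min_shift_windows: int = 1440, min_span_windows: int = 17280,
                   seed=0) -> LinkResult:
    """CCA between activations and the circular time-of-day encoding.

    Fit on the first half of retained windows; ``test_r`` is the correlation
    of the frozen canonical variates on the second half; ``perm_p`` compares
    the signed correlation against circular shifts of the test-half target
    (minimum shift ``min_shift_windows``, default 2 h). The comparison is
    one-sided: the canonical correlation is positive on the training half by
    construction, so a genuine link stays positive on the held-out half,
    while a two-sided test would tie with anti-phase shifts of the periodic
    target and an exclusion of those shifts would break exchangeability.
    Each half must span at least one circadian period (default 17280 windows
    = 24 h at 5-s windows).
    """
    keep = a.grid.keep_mask if a.grid is not None else np.ones(len(a.values), bool)
    X = a.values[keep]
    Y = target.encoding[keep]
    n = len(X)
    tr, te = _halves(n)
    if len(tr) < min_span_windows or len(te) < min_span_windows:
        raise ValueError("insufficient span: each half must cover a full circadian period")
    cca = CCA(n_components=1, max_iter=1000)
    cca.fit(X[tr], Y[tr])
    u_tr, v_tr = (z.ravel() for z in cca.transform(X[tr], Y[tr]))
    train_r = _safe_corr(u_tr, v_tr)
    u_te, v_te = (z.ravel() for z in cca.transform(X[te], Y[te]))
    test_r = _safe_corr(u_te, v_te)

    rng = np.random.default_rng(seed)
    offs = _shift_offsets(rng, len(te), n_perm, min_shift_windows)
    null = np.empty(n_perm)
    for k, off in enumerate(offs):
        null[k] = _safe_corr(u_te, np.roll(v_te, int(off)))
    perm_p = float((1 + np.sum(null >= test_r)) / (n_perm + 1))
    return LinkResult("circadian", cca.x_weights_.ravel().copy(), train_r, test_r, perm_p, n_perm)


def link_heart_rate(a: ActivationSeries, hr, n_perm: int = 200, n_folds: int = 5,
                    min_shift_windows: int = 1440, min_span_windows: int = 8640,
                    max_missing_frac: float = 0.20, seed=0) -> LinkResult:
    """L1-regularized prediction of heart rate from activations, split-half.

    The penalty path is selected by blocked cross-validation (contiguous
    folds, no shuffling) within the training half; frozen coefficients are
    evaluated on the held-out half, with circular-shift surrogates of the
    held-out heart-rate series providing ``perm_p``.
    """
    hr = np.asarray(hr, dtype=float)
    keep = a.grid.keep_mask if a.grid is not None else np.ones(len(a.values), bool)
    if hr.shape[0] != a.values.shape[0]:
        raise ValueError("heart rate must be aligned to the window grid")
    missing = ~np.isfinite(hr) & keep
    if keep.sum() and missing.sum() / keep.sum() > max_missing_frac:
        from ._utils import contiguous_runs
        spans = contiguous_runs(missing)
        raise ValueError(f"heart rate missing in more than 20% of windows; gaps at {spans[:10]}")
    use = keep & np.isfinite(hr)
    X = a.values[use]
    y = hr[use]
    n = len(X)
    tr, te = _halves(n)
    if len(tr) < min_span_windows or len(te) < min_span_windows:
        raise ValueError("insufficient span: each half must cover >= 12 h")
    model = LassoCV(cv=KFold(n_splits=n_folds, shuffle=False), random_state=0)
    model.fit(X[tr], y[tr])
    pred_tr = model.predict(X[tr])
    pred_te = model.predict(X[te])
    train_r = _safe_corr(pred_tr, y[tr])
    test_r = _safe_corr(pred_te, y[te])

    rng = np.random.default_rng(seed)
    offs = _shift_offsets(rng, len(te), n_perm, min_shift_windows)
    null = np.array([_safe_corr(pred_te, np.roll(y[te], int(off))) for off in offs])
    perm_p = float((1 + np.sum(null >= test_r)) / (n_perm + 1))
    return LinkResult("heart_rate", model.coef_.copy(), train_r, test_r, perm_p, n_perm,
                      support=model.coef_ != 0)


def paired_half_test(values_a, values_b):
    """Convenience paired t-test across recordings (used by cohort summaries)."""
    return stats.ttest_rel(np.asarray(values_a, float), np.asarray(values_b, float))
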