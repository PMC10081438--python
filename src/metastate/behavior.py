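"""Linking latent dynamics to natural behavior and sleep.

Behavior decoding follows the held-out-day protocol: linear one-vs-rest
classifiers are trained on the latent (Koopman) coordinates of one held-out
day and tested on the other, then the roles swap and scores are averaged;
the identical protocol is run on the raw activation features so the two
feature sets are directly comparable. Neural-behavioral coincidence tests
whether behavioral change times sit closer to neural bursts than circularly
shifted surrogates allow. Attractor-distance and center-manifold-axis
analyses quantify the hourglass organization: active behaviors depart from
the attractor, and behavior/sleep categories order along the sleep-wake
axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import median_filter
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from ._utils import holm

__all__ = [
    "DecodeResult", "decode_behavior", "CoincidenceResult", "transition_coincidence",
    "attractor_distance_by_state", "AxisOrdering", "axis_ordering",
    "manifold_network_map",
]

logger = logging.getLogger(__name__)

SLEEP_STAGES = ("N1", "N2/N3", "REM")


@dataclass
class DecodeResult:
    auc: dict            # category -> {"koopman": float, "raw": float}
    accuracy: dict       # category -> {"koopman": float, "raw": float} (smoothed)
    train_day: int
    test_day: int
    mean_auc: dict = field(default_factory=dict)


def _fit_score(Xtr, ytr, Xte, yte, smooth: int):
    import warnings

    clf = make_pipeline(
        StandardScaler(),
        LogisticRegressionCV(Cs=5, cv=KFold(3, shuffle=False), max_iter=2000,
                             class_weight="balanced"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(Xtr, ytr)
    prob = clf.predict_proba(Xte)[:, 1]
    auc = roc_auc_score(yte, prob)
    if smooth > 1:
        prob = median_filter(prob, size=smooth, mode="nearest")
    acc = float(np.mean((prob > 0.5) == yte))
    return float(auc), acc


def decode_behavior(koopman_coords, raw_activations, labels, day_index,
                    heldout_days, min_windows: int = 50, smooth_windows: int = 60):
    """One-vs-rest decoding of behavior on the two held-out days.

    Both feature sets run through the identical pipeline (scaling, blocked
    CV over the regularization grid, same folds); predicted probabilities
    are median-smoothed over ``smooth_windows`` (5 min at 5-s windows)
    before the accuracy score, while AUC is window-level. Categories absent
    (or with fewer than ``min_windows`` windows) on either day are skipped
    with a warning. Scores are averaged over the two train/test directions.
    """
    d1, d2 = heldout_days
    day_index = np.asarray(day_index)
    labels = np.asarray(labels).astype(str)
    masks = {d: day_index == d for d in (d1, d2)}
    feats = {"koopman": np.asarray(koopman_coords, float),
             "raw": np.asarray(raw_activations, float)}
    cats = sorted(set(labels[masks[d1]]) | set(labels[masks[d2]]))
    cats = [c for c in cats if c != "unlabeled"]
    auc = {}
    acc = {}
    for cat in cats:
        ok = True
        for d in (d1, d2):
            n_pos = int(np.sum(labels[masks[d]] == cat))
            n_neg = int(np.sum(labels[masks[d]] != cat))
            if n_pos < min_windows or n_neg < min_windows:
                logger.warning("category %r underrepresented on day %s; skipped", cat, d)
                ok = False
        if not ok:
            continue
        auc[cat] = {}
        acc[cat] = {}
        for name, F in feats.items():
            scores, accs = [], []
            for tr, te in ((d1, d2), (d2, d1)):
                a, s = _fit_score(F[masks[tr]], labels[masks[tr]] == cat,
                                  F[masks[te]], labels[masks[te]] == cat,
                                  smooth_windows)
                scores.append(a)
                accs.append(s)
            auc[cat][name] = float(np.mean(scores))
            acc[cat][name] = float(np.mean(accs))
    res = DecodeResult(auc, acc, d1, d2)
    for name in feats:
        vals = [auc[c][name] for c in auc]
        res.mean_auc[name] = float(np.mean(vals)) if vals else np.nan
    return res


@dataclass
class CoincidenceResult:
    statistic: float     # mean |lag| (windows) from behavioral change to nearest burst
    null_mean: float
    null_sd: float
    p: float
    n_changes: int
    n_surrogates: int


def transition_coincidence(burst_times, behavior_change_times, span,
                           n_surrogates: int = 1000, min_shift: float = 1800.0,
                           seed=0) -> CoincidenceResult:
    """Are behavioral changes closer to neural bursts than chance allows?

    All times are in seconds on a common clock; ``span`` is the recording
    length used for circular shifting of the burst train (uniform offsets of
    at least ``min_shift`` seconds). The statistic is the mean distance from
    each behavioral change to its nearest burst; p is the fraction of
    surrogates with a statistic at most the observed one.
    """
    bursts = np.sort(np.asarray(burst_times, float))
    changes = np.sort(np.asarray(behavior_change_times, float))
    if len(bursts) == 0:
        raise ValueError("no neural bursts supplied")
    if len(changes) < 10:
        raise ValueError("need >= 10 behavioral changes")

    def mean_nearest(b):
        idx = np.searchsorted(b, changes)
        left = np.abs(changes - b[np.clip(idx - 1, 0, len(b) - 1)])
        right = np.abs(b[np.clip(idx, 0, len(b) - 1)] - changes)
        return float(np.minimum(left, right).mean())

    observed = mean_nearest(bursts)
    rng = np.random.default_rng(seed)
    lo = min(min_shift, span / 4)
    offsets = rng.uniform(lo, span - lo, size=n_surrogates)
    null = np.array([mean_nearest(np.sort((bursts + off) % span)) for off in offsets])
    p = float((1 + np.sum(null <= observed)) / (n_surrogates + 1))
    return CoincidenceResult(observed, float(null.mean()), float(null.std()), p,
                             len(changes), n_surrogates)


def attractor_distance_by_state(coords, labels, z_star, active_categories=("digital", "social", "physical")):
    """Latent distance to the attractor: active behavior vs wakeful rest.

    Returns per-window distances plus the two group means for one recording;
    cohort-level inference pairs the group means across recordings.
    """
    coords = np.asarray(coords, float)
    labels = np.asarray(labels).astype(str)
    d = np.linalg.norm(coords - np.asarray(z_star)[None, :], axis=1)
    active = np.isin(labels, list(active_categories))
    rest = labels == "wakeful_rest"
    if not rest.any():
        raise ValueError("no wakeful_rest windows")
    if not active.any():
        raise ValueError("no active-behavior windows")
    return {
        "distances": d,
        "active_mean": float(d[active].mean()),
        "rest_mean": float(d[rest].mean()),
    }


@dataclass
class AxisOrdering:
    categories: list
    centroids: dict        # category -> per-recording centroid array
    ci: dict               # category -> (lo, hi) 95% CI across recordings
    neighbor_tests: dict   # (cat_a, cat_b) -> (t, p_adj, significant)
    attractor_position: float


def axis_ordering(along_by_recording, labels_by_recording, neighbor_pairs,
                  attractor_along: float = 0.0, min_windows: int = 20,
                  alpha: float = 0.05) -> AxisOrdering:
    """Category centroids along the center manifold, ordered and tested.

    Parameters
    ----------
    along_by_recording, labels_by_recording : lists, one entry per recording
    neighbor_pairs : category pairs to test (the x-axis neighbors);
        paired t-tests across recordings, Holm corrected.
    """
    if len(along_by_recording) < 2:
        raise ValueError("need >= 2 recordings for confidence intervals")
    per_cat = {}
    for along, labels in zip(along_by_recording, labels_by_recording):
        along = np.asarray(along, float)
        labels = np.asarray(labels).astype(str)
        for cat in np.unique(labels):
            if cat == "unlabeled":
                continue
            m = labels == cat
            if m.sum() < min_windows:
                logger.info("category %r has %d < %d windows; excluded", cat, m.sum(), min_windows)
                continue
            per_cat.setdefault(cat, []).append(float(along[m].mean()))
    n_rec = len(along_by_recording)
    cats = sorted(c for c, v in per_cat.items() if len(v) == n_rec)
    centroids = {c: np.array(per_cat[c]) for c in cats}
    ci = {}
    for c in cats:
        v = centroids[c]
        sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        t = stats.t.ppf(0.975, max(len(v) - 1, 1))
        ci[c] = (float(v.mean() - t * sem), float(v.mean() + t * sem))
    pvals, pairs = [], []
    for a, b in neighbor_pairs:
        if a in centroids and b in centroids:
            va, vb = centroids[a], centroids[b]
            if np.allclose(va, vb):
                pvals.append(1.0)
            else:
                pvals.append(stats.ttest_rel(va, vb).pvalue)
            pairs.append((a, b))
    reject, p_adj = holm(pvals, alpha=alpha)
    tests = {}
    for (a, b), r, p in zip(pairs, reject, p_adj):
        tstat = float(np.mean(centroids[a] - centroids[b]))
        tests[(a, b)] = (tstat, float(p), bool(r))
    return AxisOrdering(cats, centroids, ci, tests, attractor_along)


def manifold_network_map(along_by_recording, group_series_by_recording,
                         alpha: float = 0.05):
    """Spearman correlation of each (network, band) activation with the axis.

    ``group_series_by_recording`` maps recording -> {(network, band): series
    aligned with that recording's along-coordinate}. Per-cell one-sample
    t-tests of the across-recording correlations against zero, Holm
    corrected. Returns {(network, band): {"r": per-recording array,
    "mean_r": float, "p_adj": float, "significant": bool}}.
    """
    cells = {}
    for along, groups in zip(along_by_recording, group_series_by_recording):
        along = np.asarray(along, float)
        for key, series in groups.items():
            r = stats.spearmanr(along, np.asarray(series, float)).statistic
            cells.setdefault(key, []).append(float(r))
    keys = sorted(cells)
    pvals = []
    for k in keys:
        v = np.asarray(cells[k])
        if len(v) < 2 or v.std(ddof=1) == 0:
            pvals.append(1.0 if np.allclose(v, 0) else 0.0 if len(v) > 1 else 1.0)
        else:
            pvals.append(stats.ttest_1samp(v, 0.0).pvalue)
    reject, p_adj = holm(pvals, alpha=alpha)
    return {k: {"r": np.asarray(cells[k]), "mean_r": float(np.mean(cells[k])),
                "p_adj": float(p), "significant": bool(rj)}
            for k, p, rj in zip(keys, p_adj, reject)}
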