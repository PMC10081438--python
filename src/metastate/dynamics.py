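"""Punctuated-equilibrium analysis of activation-space trajectories.

The brain's "speed" is the Euclidean step length between consecutive
windows' activation vectors. Windows in the top 10% of speed are events;
their clustering is tested against a homogeneous Poisson process with rate
lambda = 0.1 events/window (expected inter-event gap 1/lambda = 10 windows).
A hysteresis segmentation splits the grid into stable states and transition
bursts; state segments are clustered into discrete state identities.
Trajectory geometry (length vs displacement), divergence profiles between
transitions grouped by endpoints, the 0-1 chaos statistic and power-law fits
quantify how circuitous, unpredictable and chaotic the transitions are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._utils import cohens_d, contiguous_runs
from .chaos import ChaosResult, chaos01
from .components import ActivationSeries
from .powerlaw import PowerLawFit, fit_powerlaw

__all__ = [
    "SpeedSeries", "compute_speed", "PoissonNullParams", "burst_gap_test",
    "SegmentationResult", "segment_states", "TrajectoryMetrics",
    "trajectory_metrics", "DivergenceProfile", "divergence_profile",
    "chaos01", "ChaosResult", "fit_powerlaw", "PowerLawFit",
]

logger = logging.getLogger(__name__)


@dataclass
class SpeedSeries:
    """values[t] = step length between windows t and t+1 (NaN across gaps)."""

    values: np.ndarray
    valid: np.ndarray  # True where the step spans two retained windows


def compute_speed(a: ActivationSeries) -> SpeedSeries:
    V = np.asarray(a.values, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if V.shape[0] < 2:
        raise ValueError("need at least two retained windows")
    keep = a.grid.keep_mask if a.grid is not None else np.ones(len(V), bool)
    steps = np.linalg.norm(np.diff(V, axis=0), axis=1)
    valid = keep[:-1] & keep[1:]
    steps = np.where(valid, steps, np.nan)
    return SpeedSeries(steps, valid)


@dataclass(frozen=True)
class PoissonNullParams:
    rate: float = 0.1      # events per window; equals the event quantile
    quantile: float = 0.10

    def __post_init__(self):
        if not 0 < self.rate < 1:
            raise ValueError("rate must lie in (0, 1)")


def burst_gap_test(s: SpeedSeries, null: PoissonNullParams = PoissonNullParams(),
                   n_sim: int = 1000, seed=0):
    """Observed vs Poisson-expected mean gap between high-speed events.

    Events are the steps above the ``1 - quantile`` speed quantile. Under a
    homogeneous Poisson process at rate lambda the expected mean inter-event
    gap is ``1/lambda`` windows; the p-value is the fraction of simulated
    Poisson event trains (same length and event count) whose mean gap is at
    most the observed one. Bursting = observed gap below expectation.
    """
    v = s.values[s.valid]
    if len(v) < 1000:
        raise ValueError("need >= 1000 valid steps")
    if np.allclose(v, v[0]):
        raise ValueError("all speeds identical: event quantile undefined")
    thr = np.quantile(v, 1 - null.quantile)
    ev = np.flatnonzero(v >= thr)
    gaps = np.diff(ev)
    observed = float(gaps.mean())
    expected = 1.0 / null.rate
    # The mean gap telescopes to span/(count-1) and so carries almost no
    # clustering information; the p-value therefore uses the median gap
    # (which collapses toward 1 for bursty trains) under the same
    # simulated Poisson event trains.
    obs_median = float(np.median(gaps))
    rng = np.random.default_rng(seed)
    n, k = len(v), len(ev)
    sims = np.empty(n_sim)
    for i in range(n_sim):
        pos = np.sort(rng.choice(n, size=min(k, n), replace=False))
        sims[i] = np.median(np.diff(pos))
    p = float((1 + np.sum(sims <= obs_median)) / (n_sim + 1))
    return observed, expected, p


@dataclass
class SegmentationResult:
    """Alternating (kind, start, stop) half-open segments tiling the grid."""

    segments: list                      # (kind in {"state","transition"}, start, stop)
    state_ids: dict = field(default_factory=dict)  # segment index -> cluster id
    n_state_clusters: int = 0

    def transitions(self):
        return [(s, e) for k, s, e in self.segments if k == "transition"]

    def states(self):
        return [(s, e) for k, s, e in self.segments if k == "state"]

    def labels_per_window(self, n_windows):
        lab = np.full(n_windows, -1, dtype=int)
        for idx, (k, s, e) in enumerate(self.segments):
            if k == "state" and idx in self.state_ids:
                lab[s:e] = self.state_ids[idx]
        return lab


def segment_states(s: SpeedSeries, a: ActivationSeries, high_quantile: float = None,
                   fence_factor: float = 3.0, min_dwell: int = 3,
                   k_range=range(2, 9), seed=0) -> SegmentationResult:
    """Threshold segmentation of the speed series into states and bursts.

    A step enters the transition class when its speed exceeds the high
    threshold. By default the threshold is a Tukey far-out fence,
    ``Q3 + fence_factor * IQR`` of the speed distribution: burst occupancy
    varies strongly between recordings, so a fixed quantile under- or
    over-shoots, while the quartiles are set by the within-state speed mode
    whenever bursts are a minority. ``high_quantile`` overrides this with a
    fixed speed quantile. Brief sub-threshold dips of up to ``min_dwell``
    steps inside a burst are bridged, and isolated single-step crossings are
    discarded. State segments are then clustered into discrete identities by
    k-means on segment-mean activations, with k chosen by silhouette score
    over ``k_range``.
    """
    v = s.values
    n_steps = len(v)
    n_windows = n_steps + 1
    if min_dwell >= n_windows:
        logger.warning("min_dwell >= series length: single-segment output")
        return SegmentationResult([("state", 0, n_windows)], {0: 0}, 1)
    finite = v[np.isfinite(v)]
    if high_quantile is not None:
        hi = np.quantile(finite, high_quantile)
    else:
        q1, q3 = np.quantile(finite, [0.25, 0.75])
        hi = q3 + fence_factor * (q3 - q1)
    in_trans = np.isfinite(v) & (v >= hi)
    # drop isolated single-step crossings first (spurious spikes, not
    # bursts) so they cannot extend a neighboring burst through bridging
    for s0, e0 in contiguous_runs(in_trans):
        if e0 - s0 < 2:
            in_trans[s0:e0] = False
    # bridge dips of <= min_dwell steps between high-speed runs
    runs = contiguous_runs(in_trans)
    for (s0, e0), (s1, e1) in zip(runs[:-1], runs[1:]):
        if s1 - e0 <= min_dwell:
            in_trans[e0:s1] = True
    # a genuine burst contains at least one extreme step
    for s0, e0 in contiguous_runs(in_trans):
        if np.nanmax(v[s0:e0]) < 2.0 * hi:
            in_trans[s0:e0] = False

    # step t spans windows (t, t+1): transition windows = union of both ends
    win_trans = np.zeros(n_windows, dtype=bool)
    for s0, e0 in contiguous_runs(in_trans):
        win_trans[s0:e0 + 1] = True

    segments = []
    t = 0
    while t < n_windows:
        kind = "transition" if win_trans[t] else "state"
        e = t
        while e < n_windows and win_trans[e] == win_trans[t]:
            e += 1
        segments.append((kind, t, e))
        t = e

    V = np.asarray(a.values, dtype=float)
    state_idx = [i for i, (k, s0, e0) in enumerate(segments) if k == "state"]
    means = np.array([np.nanmean(V[s0:e0], axis=0) for i, (k, s0, e0) in enumerate(segments)
                      if k == "state"])
    state_ids = {}
    n_clusters = 0
    if len(means) >= 2:
        best_k, best_score, best_labels = 1, -np.inf, np.zeros(len(means), dtype=int)
        for k in k_range:
            if k >= len(means):
                break
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(means)
            try:
                score = silhouette_score(means, km.labels_)
            except ValueError:
                continue
            if score > best_score:
                best_k, best_score, best_labels = k, score, km.labels_
        n_clusters = best_k
        for i, lab in zip(state_idx, best_labels):
            state_ids[i] = int(lab)
    elif len(means) == 1:
        state_ids[state_idx[0]] = 0
        n_clusters = 1
    return SegmentationResult(segments, state_ids, n_clusters)


@dataclass
class TrajectoryMetrics:
    lengths: np.ndarray
    displacements: np.ndarray
    ratios: np.ndarray            # NaN where displacement ~ 0 (excluded)
    segments: list                # the (start, stop) pairs measured


def trajectory_metrics(intervals, a: ActivationSeries, eps_scale: float = 1e-8) -> TrajectoryMetrics:
    """Length, displacement and circuitousness ratio per trajectory segment.

    ``ratio = length / displacement >= 1`` by the triangle inequality;
    segments whose displacement is below ``eps_scale`` times the activation
    scale have an undefined ratio and are excluded with a log entry.
    """
    V = np.asarray(a.values, dtype=float)
    scale = np.nanstd(V) or 1.0
    eps = eps_scale * scale
    L, D, R, segs = [], [], [], []
    for (s0, e0) in intervals:
        if e0 - s0 < 2:
            continue
        seg = V[s0:e0]
        length = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))
        disp = float(np.linalg.norm(seg[-1] - seg[0]))
        L.append(length)
        D.append(disp)
        if disp <= eps:
            logger.info("segment (%d, %d): displacement ~ 0, ratio undefined", s0, e0)
            R.append(np.nan)
        else:
            R.append(length / disp)
        segs.append((s0, e0))
    return TrajectoryMetrics(np.array(L), np.array(D), np.array(R), segs)


def duration_matched_state_ratios(transitions, states, a: ActivationSeries, seed=0):
    """State-segment circuitousness ratios duration-matched to transitions.

    A raw state-vs-transition ratio comparison is confounded by duration
    (path length grows with segment length while displacement saturates), so
    for each transition of length L a random contiguous subsegment of length
    L is drawn from the state segments and its ratio computed. Returns the
    matched state ratios aligned with the transitions that set the lengths.
    """
    rng = np.random.default_rng(seed)
    V = np.asarray(a.values, dtype=float)
    states = [(s, e) for s, e in states if e - s >= 2]
    if not states:
        raise ValueError("no usable state segments")
    out = []
    for (s0, e0) in transitions:
        L = e0 - s0
        candidates = [(s, e) for s, e in states if e - s >= L]
        if not candidates:
            candidates = [max(states, key=lambda se: se[1] - se[0])]
        s, e = candidates[int(rng.integers(len(candidates)))]
        L_eff = min(L, e - s)
        start = s + int(rng.integers(e - s - L_eff + 1))
        tm = trajectory_metrics([(start, start + L_eff)], a)
        out.append(tm.ratios[0] if len(tm.ratios) else np.nan)
    return np.array(out)


@dataclass
class DivergenceProfile:
    progress: np.ndarray   # fractions 0..1
    d_same: np.ndarray     # mean pairwise distance, shared (start, end)
    d_diff: np.ndarray     # mean pairwise distance, shared start only
    cohens_d: np.ndarray


def _resample_arclength(seg, n_points):
    """Resample a trajectory to n_points equally spaced in arc length."""
    steps = np.linalg.norm(np.diff(seg, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    if arc[-1] == 0:
        return np.repeat(seg[:1], n_points, axis=0)
    arc /= arc[-1]
    grid = np.linspace(0, 1, n_points)
    return np.column_stack([np.interp(grid, arc, seg[:, d]) for d in range(seg.shape[1])])


def divergence_profile(transitions, a: ActivationSeries, n_points: int = 21) -> DivergenceProfile:
    """Do transitions sharing a destination converge before those that do not?

    Parameters
    ----------
    transitions : sequence of ((start_state, end_state), (start_win, stop_win))
        Transition intervals labeled by their flanking state identities.
    n_points : resolution of the arc-length progress grid.

    At each progress fraction the mean pairwise inter-trajectory distance is
    computed among transitions sharing both endpoints (d_same) and among
    transitions sharing only the start state (d_diff); the profile's effect
    size is the standardized difference (d_diff - d_same).
    """
    V = np.asarray(a.values, dtype=float)
    grid = np.linspace(0, 1, n_points)
    resampled, keys = [], []
    for (key, (s0, e0)) in transitions:
        if e0 - s0 < 2:
            continue
        resampled.append(_resample_arclength(V[s0:e0], n_points))
        keys.append(key)
    same_pairs, diff_pairs = [], []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if keys[i] == keys[j]:
                same_pairs.append((i, j))
            elif keys[i][0] == keys[j][0]:
                diff_pairs.append((i, j))
    if len(same_pairs) < 2 or len(diff_pairs) < 2:
        short = "same-(start,end)" if len(same_pairs) < 2 else "same-start-different-end"
        raise ValueError(f"insufficient transition pairs in the {short} group")
    R = np.stack(resampled)  # (n_traj, n_points, d)
    d_same = np.empty(n_points)
    d_diff = np.empty(n_points)
    ds = np.empty(n_points)
    for t in range(n_points):
        ds_same = np.array([np.linalg.norm(R[i, t] - R[j, t]) for i, j in same_pairs])
        ds_diff = np.array([np.linalg.norm(R[i, t] - R[j, t]) for i, j in diff_pairs])
        d_same[t] = ds_same.mean()
        d_diff[t] = ds_diff.mean()
        ds[t] = cohens_d(ds_diff, ds_same)
    return DivergenceProfile(grid, d_same, d_diff, ds)
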