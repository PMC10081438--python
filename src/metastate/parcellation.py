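"""Data-driven channel parcels and their autocorrelation timescales.

Channels are grouped into tightly coherent, spatially compact parcels by
average-linkage agglomerative clustering on distance ``1 - mean coherence``.
When channel coordinates are available, merges between spatially disconnected
groups are disallowed through a radius-graph connectivity constraint. The
number of parcels is either given or chosen by maximizing the modularity of
the thresholded coherence graph.

Each parcel's per-window coherence series (mean of its within-parcel pairs)
is summarized by an exponential autocorrelation fit ``A * exp(-lag / tau)``;
``tau`` is the parcel's timescale. Timescales aggregated by canonical fMRI
network are contrasted across recordings with Holm-corrected paired tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import networkx as nx
from scipy import optimize, stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import radius_neighbors_graph

from ._utils import contiguous_runs, holm
from .bands import WindowGrid
from .coherence import CoherenceTensor

__all__ = [
    "Parcellation",
    "CoherenceParcellation",
    "cluster_channels",
    "ParcelSeries",
    "parcel_series",
    "TimescaleEstimate",
    "estimate_timescale",
    "timescale_contrasts",
]

logger = logging.getLogger(__name__)


@dataclass
class Parcellation:
    """assignment: channel -> parcel id (-1 = excluded); ids contiguous from 0."""

    assignment: np.ndarray
    n_parcels: int
    coords: Optional[np.ndarray] = None

    def channels(self, parcel: int):
        return np.flatnonzero(self.assignment == parcel)


class CoherenceParcellation(ClusterMixin, BaseEstimator):
    """Average-linkage clustering of channels on ``1 - mean coherence``.

    Parameters
    ----------
    n_parcels : int or None
        Number of parcels; None selects it by modularity maximization on the
        coherence graph thresholded at ``graph_quantile``.
    adjacency_radius : float
        Channels closer than this (mm) are considered spatially adjacent;
        only used when coordinates are passed to :meth:`fit`.
    graph_quantile : float
        Edge-inclusion quantile for the modularity graph; only the top
        coherences form edges, since within-parcel pairs are a small
        fraction of all pairs for compact parcels.

    Attributes
    ----------
    labels_ : ndarray
        Parcel id per channel; singleton clusters are merged into their most
        coherent neighbor so every parcel has at least two channels.
    n_parcels_ : int
    """

    def __init__(self, n_parcels=None, adjacency_radius: float = 15.0,
                 graph_quantile: float = 0.90):
        self.n_parcels = n_parcels
        self.adjacency_radius = adjacency_radius
        self.graph_quantile = graph_quantile

    def _auto_k(self, C: np.ndarray) -> int:
        off = C[np.triu_indices_from(C, k=1)]
        thr = np.quantile(off, self.graph_quantile)
        G = nx.Graph()
        G.add_nodes_from(range(C.shape[0]))
        for i, j in zip(*np.triu_indices_from(C, k=1)):
            if C[i, j] >= thr:
                G.add_edge(int(i), int(j), weight=float(C[i, j]))
        comms = nx.algorithms.community.greedy_modularity_communities(G, weight="weight")
        return max(2, min(len(comms), C.shape[0] // 2))

    def fit(self, X, y=None, coords=None):
        """X: symmetric channel x channel mean-coherence matrix in [0, 1]."""
        C = np.asarray(X, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("expected a square coherence matrix")
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("coherence matrix must be symmetric")
        n = C.shape[0]
        k = self.n_parcels if self.n_parcels is not None else self._auto_k(C)
        if n < 2 * k:
            raise ValueError(f"need at least {2 * k} channels for {k} parcels of >= 2 channels")
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        if coords is None:
            model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                            linkage="average")
            labels = model.fit_predict(D)
            spatial_comp = np.zeros(n, dtype=int)
        else:
            labels, spatial_comp = self._fit_spatial(D, np.asarray(coords, float), k)
        labels = self._absorb_singletons(labels, C, spatial_comp)
        # relabel contiguously, deterministic order (first channel occurrence)
        _, labels = np.unique(labels, return_inverse=True)
        order = {}
        final = np.empty_like(labels)
        for ch, lab in enumerate(labels):
            if lab not in order:
                order[lab] = len(order)
            final[ch] = order[lab]
        self.labels_ = final
        self.n_parcels_ = final.max() + 1
        self.coords_ = coords
        return self

    def _fit_spatial(self, D, coords, k):
        """Cluster within spatially connected groups; merges across spatially
        disconnected groups are disallowed outright.

        The adjacency radius defines a graph on channels; each connected
        component is clustered separately (with sklearn's structured
        agglomeration enforcing within-component contiguity), and the parcel
        budget k is allocated to components proportionally to their size.
        """
        import scipy.sparse.csgraph as csgraph

        A = radius_neighbors_graph(coords, self.adjacency_radius, include_self=False)
        n_comp, comp = csgraph.connected_components(A, directed=False)
        if n_comp > k:
            raise ValueError(f"{n_comp} spatially disconnected channel groups "
                             f"but only {k} parcels requested")
        sizes = np.bincount(comp)
        alloc = np.maximum(1, np.round(k * sizes / sizes.sum()).astype(int))
        while alloc.sum() > k:
            alloc[np.argmax(alloc)] -= 1
        while alloc.sum() < k:
            alloc[np.argmax(sizes / alloc)] += 1
        labels = np.empty(D.shape[0], dtype=int)
        offset = 0
        for c in range(n_comp):
            idx = np.flatnonzero(comp == c)
            kc = min(alloc[c], len(idx))
            if kc <= 1 or len(idx) == 1:
                labels[idx] = offset
                offset += 1
                continue
            sub = AgglomerativeClustering(
                n_clusters=kc, metric="precomputed", linkage="average",
                connectivity=A[np.ix_(idx, idx)])
            labels[idx] = offset + sub.fit_predict(D[np.ix_(idx, idx)])
            offset += kc
        return labels, comp

    @staticmethod
    def _absorb_singletons(labels, C, spatial_comp=None):
        """Merge undersized clusters into their most coherent neighbor,
        never crossing spatial components."""
        labels = labels.copy()
        if spatial_comp is None:
            spatial_comp = np.zeros(len(labels), dtype=int)
        stuck = set()  # singletons with no same-component neighbor parcel
        while True:
            ids, counts = np.unique(labels, return_counts=True)
            singles = [i for i, c in zip(ids, counts) if c < 2 and i not in stuck]
            if not singles or len(ids) <= 1:
                return labels
            s = singles[0]
            ch = int(np.flatnonzero(labels == s)[0])
            best, best_val = None, -np.inf
            for other in ids:
                members = labels == other
                if other == s or spatial_comp[members][0] != spatial_comp[ch]:
                    continue
                val = C[ch, members].mean()
                if val > best_val:
                    best, best_val = other, val
            if best is None:  # lone spatial component stays its own parcel
                stuck.add(s)
                continue
            labels[labels == s] = best

    def to_parcellation(self) -> Parcellation:
        return Parcellation(self.labels_, int(self.n_parcels_), self.coords_)


def cluster_channels(mean_coherence, coords=None, k=None, adjacency_radius=15.0) -> Parcellation:
    """Functional wrapper over :class:`CoherenceParcellation`."""
    est = CoherenceParcellation(n_parcels=k, adjacency_radius=adjacency_radius)
    est.fit(mean_coherence, coords=coords)
    return est.to_parcellation()


@dataclass
class ParcelSeries:
    """values: (windows, parcels, bands) mean within-parcel coherence."""

    values: np.ndarray
    grid: WindowGrid
    parcellation: Parcellation


def parcel_series(coh: CoherenceTensor, parc: Parcellation) -> ParcelSeries:
    """Per-window mean of within-parcel pair coherences, per band."""
    pair_lookup = {p: idx for idx, p in enumerate(coh.pair_index)}
    n_w, _, n_b = coh.values.shape
    out = np.full((n_w, parc.n_parcels, n_b), np.nan)
    for p in range(parc.n_parcels):
        chans = parc.channels(p)
        if len(chans) < 2:
            raise ValueError(f"parcel {p} has fewer than 2 channels")
        idx = []
        for a in range(len(chans)):
            for b in range(a + 1, len(chans)):
                key = (int(chans[a]), int(chans[b]))
                if key not in pair_lookup:
                    raise ValueError(f"pair {key} missing from coherence tensor")
                idx.append(pair_lookup[key])
        out[:, p, :] = coh.values[:, idx, :].mean(axis=1)
    out[~coh.grid.keep_mask] = np.nan
    return ParcelSeries(out, coh.grid, parc)


@dataclass
class TimescaleEstimate:
    parcel: int
    band: int
    magnitude: float   # A
    tau: float         # windows
    fit_rmse: float
    identifiable: bool


def _masked_autocorr(x, keep, max_lag):
    """Autocorrelation over contiguous retained runs only."""
    x = np.asarray(x, dtype=float)
    mu = np.nanmean(x[keep])
    var = np.nanvar(x[keep])
    if not var > 0:
        return None
    acf = np.empty(max_lag)
    runs = contiguous_runs(keep)
    for lag in range(1, max_lag + 1):
        num, cnt = 0.0, 0
        for s, e in runs:
            if e - s > lag:
                a = x[s:e - lag] - mu
                b = x[s + lag:e] - mu
                num += np.sum(a * b)
                cnt += len(a)
        acf[lag - 1] = num / (cnt * var) if cnt else np.nan
    return acf


def estimate_timescale(series, keep_mask=None, max_lag: int = 50,
                       parcel: int = -1, band: int = -1) -> TimescaleEstimate:
    """Fit ``A * exp(-lag / tau)`` to the empirical autocorrelation.

    The fit uses lags ``1..max_lag`` computed only across contiguous
    retained runs. The estimate is flagged unidentifiable when the fitted
    magnitude ``A <= 0.1`` or the fit RMSE exceeds 0.1 (e.g. white noise).
    """
    series = np.asarray(series, dtype=float)
    if keep_mask is None:
        keep_mask = np.isfinite(series)
    else:
        keep_mask = np.asarray(keep_mask, bool) & np.isfinite(series)
    if keep_mask.sum() < 10 * max_lag:
        raise ValueError("need >= 10 * max_lag retained windows")
    acf = _masked_autocorr(series, keep_mask, max_lag)
    if acf is None:
        return TimescaleEstimate(parcel, band, np.nan, np.nan, np.nan, False)
    lags = np.arange(1, max_lag + 1, dtype=float)
    ok = np.isfinite(acf)

    def model(l, A, tau):
        return A * np.exp(-l / tau)

    # initial guess from log-linear fit over positive early lags
    pos = ok & (acf > 0)
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(lags[pos], np.log(acf[pos]), 1)
        p0 = [float(np.exp(intercept)), float(-1 / slope) if slope < 0 else max_lag / 2]
    else:
        p0 = [0.5, 5.0]
    if not np.isfinite(p0[0]) or not 1e-3 < p0[0] <= 1:
        p0[0] = 0.5
    if not np.isfinite(p0[1]) or not 1e-3 < p0[1] < 1e5:
        p0[1] = 5.0
    try:
        popt, _ = optimize.curve_fit(model, lags[ok], acf[ok], p0=p0,
                                     bounds=([-1, 1e-6], [1, 1e6]), maxfev=5000)
        A, tau = popt
        rmse = float(np.sqrt(np.mean((model(lags[ok], A, tau) - acf[ok]) ** 2)))
    except RuntimeError:
        A, tau, rmse = np.nan, np.nan, np.inf
    identifiable = bool(np.isfinite(A) and A > 0.1 and rmse < 0.1)
    return TimescaleEstimate(parcel, band, float(A), float(tau), rmse, identifiable)


def timescale_contrasts(tau_by_network: "dict[str, np.ndarray]", alpha: float = 0.05):
    """Pairwise network timescale differences across recordings.

    Parameters
    ----------
    tau_by_network : dict
        network label -> per-recording mean timescale (aligned arrays;
        recordings missing a network carry NaN and are dropped pairwise).

    Returns
    -------
    (labels, diff, reject, p_adj) where ``diff[a, b] > 0`` means network
    ``a`` is slower than network ``b``; Holm correction over the upper
    triangle; ``diff`` is antisymmetric by construction.
    """
    labels = sorted(tau_by_network)
    m = len(labels)
    diff = np.zeros((m, m))
    pvals = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            a = np.asarray(tau_by_network[labels[i]], float)
            b = np.asarray(tau_by_network[labels[j]], float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 2:
                logger.warning("pair (%s, %s): fewer than 2 paired recordings", labels[i], labels[j])
                continue
            d = a[ok] - b[ok]
            diff[i, j] = d.mean()
            diff[j, i] = -d.mean()
            if np.allclose(d, 0):
                pvals[i, j] = 1.0
            else:
                pvals[i, j] = stats.ttest_rel(a[ok], b[ok]).pvalue
    iu = np.triu_indices(m, k=1)
    reject_u, p_adj_u = holm(pvals[iu], alpha=alpha)
    reject = np.zeros((m, m), dtype=bool)
    p_adj = np.full((m, m), np.nan)
    reject[iu] = reject_u
    reject.T[iu] = reject_u
    p_adj[iu] = p_adj_u
    p_adj.T[iu] = p_adj_u
    return labels, diff, reject, p_adj
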