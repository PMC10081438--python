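"""Small shared helpers: effect sizes, multiple-comparison wrappers, runs."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cohens_d",
    "holm",
    "contiguous_runs",
    "circular_shift",
    "rng_from",
]


def cohens_d(a, b):
    """Standardized mean difference (pooled SD) between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return np.nan
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if pooled <= 0:
        return 0.0 if np.isclose(a.mean(), b.mean()) else np.inf * np.sign(a.mean() - b.mean())
    return (a.mean() - b.mean()) / np.sqrt(pooled)


def holm(pvals, alpha: float = 0.05):
    """Holm step-down correction; returns (reject flags, adjusted p)."""
    pvals = np.asarray(pvals, dtype=float)
    ok = np.isfinite(pvals)
    reject = np.zeros(pvals.shape, dtype=bool)
    adj = np.full(pvals.shape, np.nan)
    if ok.any():
        r, p_adj, _, _ = multipletests(pvals[ok], alpha=alpha, method="holm")
        reject[ok] = r
        adj[ok] = p_adj
    return reject, adj


def contiguous_runs(mask):
    """(start, stop) half-open index pairs of True runs in a boolean array."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def circular_shift(x, offset: int):
    """Roll a series circularly along its first axis."""
    return np.roll(np.asarray(x), int(offset), axis=0)


def rng_from(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
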