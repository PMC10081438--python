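"""Gottwald-Melbourne 0-1 test for chaos, correlation method.

For a scalar series ``x`` and a frequency ``c``, the translation variables
``p(n) = sum_{j<=n} x_j cos(jc)`` and ``q(n) = sum_{j<=n} x_j sin(jc)``
perform a bounded walk for regular dynamics and a diffusive walk for chaotic
dynamics. The modified mean-square displacement subtracts the oscillatory
term ``(E x)^2 (1 - cos nc) / (1 - cos c)``, and ``K_c`` is the correlation
between ``n`` and the modified displacement. The statistic ``K`` is the
median of ``K_c`` over random ``c`` drawn in ``(pi/5, 4*pi/5)`` (restricted
to avoid resonance artifacts); K ~ 1 indicates chaos, K ~ 0 regularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChaosResult", "chaos01"]


@dataclass
class ChaosResult:
    K: float
    n_c: int
    method: str = "correlation"
    degenerate: bool = False
    per_c: np.ndarray = None


def _chaos01_scalar(x, n_c, rng):
    x = np.asarray(x, dtype=float)
    N = len(x)
    ncut = max(10, N // 10)
    c = rng.uniform(np.pi / 5, 4 * np.pi / 5, size=n_c)
    j = np.arange(1, N + 1)
    phases = np.outer(c, j)                        # (n_c, N)
    p = np.cumsum(x[None, :] * np.cos(phases), axis=1)
    q = np.cumsum(x[None, :] * np.sin(phases), axis=1)
    Ex2 = x.mean() ** 2
    ns = np.arange(1, ncut + 1)
    K_c = np.empty(n_c)
    D = np.empty((n_c, ncut))
    for i, n in enumerate(ns):
        dp = p[:, n:] - p[:, :-n]
        dq = q[:, n:] - q[:, :-n]
        M = np.mean(dp ** 2 + dq ** 2, axis=1)
        D[:, i] = M - Ex2 * (1 - np.cos(n * c)) / (1 - np.cos(c))
    for k in range(n_c):
        sd = D[k].std()
        K_c[k] = 0.0 if sd == 0 else np.corrcoef(ns, D[k])[0, 1]
    return K_c


def chaos01(x, n_c: int = 100, subsample: int = 1, max_samples: int = 5000,
            seed=0) -> ChaosResult:
    """0-1 chaos statistic of a scalar or multivariate series.

    Parameters
    ----------
    x : array (n,) or (n, d)
        Multivariate input is reduced by running the test per component and
        taking the median of the component statistics.
    n_c : number of random test frequencies.
    subsample : stride applied before testing (maps sampled flows toward the
        map-like regime the test expects).
    max_samples : cap on the series length after subsampling (the test is
        O(n^2/10); longer inputs are decimated evenly to the cap).

    A constant series has no dynamics to classify; by convention K = 0 with
    the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = x[::subsample]
    if max_samples is not None and x.shape[0] > max_samples:
        stride = int(np.ceil(x.shape[0] / max_samples))
        x = x[::stride]
    if x.shape[0] < 500:
        raise ValueError("need >= 500 samples after subsampling")
    rng = np.random.default_rng(seed)
    Ks, all_c = [], []
    degenerate = True
    for d in range(x.shape[1]):
        col = x[:, d]
        if col.std() == 0:
            Ks.append(0.0)
            continue
        degenerate = False
        K_c = _chaos01_scalar(col, n_c, rng)
        all_c.append(K_c)
        Ks.append(float(np.median(K_c)))
    if degenerate:
        return ChaosResult(0.0, n_c, degenerate=True)
    return ChaosResult(float(np.median(Ks)), n_c,
                       per_c=np.concatenate(all_c) if all_c else None)
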