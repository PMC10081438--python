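"""Power-law fitting with KS model selection and likelihood-ratio tests.

Implements the Clauset-Shalizi-Newman procedure: the lower cutoff ``xmin``
is chosen to minimize the Kolmogorov-Smirnov distance between the tail data
and the fitted power law; the exponent ``alpha`` comes from maximum
likelihood (closed form in the continuous case, numerical with the Hurwitz
zeta normalizer in the discrete case). Goodness of fit is a semiparametric
bootstrap p-value (p < 0.1 conventionally rejects the power law), and the
power law is compared against exponential and lognormal alternatives with
Vuong's normalized likelihood-ratio test (positive statistic favors the
power law).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = ["PowerLawFit", "fit_powerlaw"]

_MIN_TAIL = 100


@dataclass
class PowerLawFit:
    alpha: float
    xmin: float
    ks_stat: float
    bootstrap_p: float
    discrete: bool
    n_tail: int
    lr_vs_exponential: tuple = None   # (normalized LR, two-sided p); > 0 favors power law
    lr_vs_lognormal: tuple = None
    bootstrap_n: int = 0
    alternatives: dict = field(default_factory=dict)


def _alpha_continuous(x, xmin):
    return 1.0 + len(x) / np.sum(np.log(x / xmin))


def _loglik_discrete(alpha, x, xmin):
    return -alpha * np.sum(np.log(x)) - len(x) * np.log(special.zeta(alpha, xmin))


def _alpha_discrete(x, xmin):
    res = optimize.minimize_scalar(lambda a: -_loglik_discrete(a, x, xmin),
                                   bounds=(1.01, 10.0), method="bounded")
    return float(res.x)


def _ks_continuous(x, xmin, alpha):
    x = np.sort(x)
    cdf = 1.0 - (x / xmin) ** (1.0 - alpha)
    emp_hi = np.arange(1, len(x) + 1) / len(x)
    emp_lo = np.arange(0, len(x)) / len(x)
    return float(max(np.max(np.abs(emp_hi - cdf)), np.max(np.abs(emp_lo - cdf))))


def _ks_discrete(x, xmin, alpha):
    kmax = int(x.max())
    ks = np.arange(int(xmin), kmax + 1)
    pmf = ks.astype(float) ** (-alpha) / special.zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    emp = np.searchsorted(np.sort(x), ks, side="right") / len(x)
    return float(np.max(np.abs(emp - cdf)))


def _fit_fixed_xmin(x, xmin, discrete):
    tail = x[x >= xmin]
    if discrete:
        alpha = _alpha_discrete(tail, xmin)
        ks = _ks_discrete(tail, xmin, alpha)
    else:
        alpha = _alpha_continuous(tail, xmin)
        ks = _ks_continuous(tail, xmin, alpha)
    return alpha, ks, len(tail)


def _scan_xmin(x, discrete, max_candidates=50):
    cands = np.unique(x)
    cands = cands[cands < np.quantile(x, 0.95)]  # keep a real tail
    if len(cands) == 0:
        cands = np.unique(x)[:1]
    if len(cands) > max_candidates:
        idx = np.unique(np.linspace(0, len(cands) - 1, max_candidates).astype(int))
        cands = cands[idx]
    best = None
    for xm in cands:
        if np.sum(x >= xm) < _MIN_TAIL:
            continue
        alpha, ks, n_tail = _fit_fixed_xmin(x, xm, discrete)
        if best is None or ks < best[1]:
            best = (alpha, ks, xm, n_tail)
    if best is None:
        raise ValueError("tail too short: fewer than 100 samples above every candidate xmin")
    return best


def _sample_powerlaw(rng, n, xmin, alpha, discrete):
    u = rng.random(n)
    if discrete:
        # inverse CDF on a truncated pmf table (cap far in the tail)
        cap = int(max(1000, xmin * 1000))
        ks = np.arange(int(xmin), cap + 1, dtype=float)
        pmf = ks ** (-alpha)
        cdf = np.cumsum(pmf / pmf.sum())
        return ks[np.searchsorted(cdf, u)]
    return xmin * (1 - u) ** (-1.0 / (alpha - 1.0))


def _vuong(l1, l2):
    """Normalized LR of pointwise log-likelihoods; >0 favors model 1."""
    d = l1 - l2
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0
    R = d.sum() / (sd * np.sqrt(n))
    p = 2 * stats.norm.sf(abs(R))
    return float(R), float(p)


def _pointwise_loglik_power(x, xmin, alpha, discrete):
    if discrete:
        return -alpha * np.log(x) - np.log(special.zeta(alpha, xmin))
    return np.log((alpha - 1) / xmin) - alpha * np.log(x / xmin)


def _pointwise_loglik_exponential(x, xmin, discrete):
    if discrete:
        # geometric on {xmin, xmin+1, ...}
        sh = x - xmin
        p = 1.0 / (1.0 + sh.mean()) if sh.mean() > 0 else 1 - 1e-12
        return sh * np.log(1 - p) + np.log(p)
    lam = 1.0 / max(np.mean(x - xmin), 1e-12)
    return np.log(lam) - lam * (x - xmin)


def _pointwise_loglik_lognormal(x, xmin, discrete):
    lx = np.log(x)

    def nll(theta):
        mu, sig = theta
        if sig <= 0:
            return np.inf
        tail = stats.norm.sf((np.log(xmin) - mu) / sig)
        if tail <= 0:
            return np.inf
        ll = stats.norm.logpdf(lx, mu, sig) - lx - np.log(tail)
        return -np.sum(ll)

    res = optimize.minimize(nll, x0=[lx.mean(), max(lx.std(), 0.1)], method="Nelder-Mead")
    mu, sig = res.x
    tail = stats.norm.sf((np.log(xmin) - mu) / max(sig, 1e-12))
    return stats.norm.logpdf(lx, mu, max(sig, 1e-12)) - lx - np.log(max(tail, 1e-300))


def fit_powerlaw(samples, discrete=None, xmin=None, alternatives=("exponential", "lognormal"),
                 n_bootstrap: int = 100, seed=0) -> PowerLawFit:
    """Fit a power-law tail and test it against alternative distributions.

    Parameters
    ----------
    samples : positive values (window counts should be passed as integers;
        ``discrete`` is inferred from the dtype when not given)
    xmin : fix the lower cutoff instead of scanning
    n_bootstrap : semiparametric bootstrap replicates for the KS p-value
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if discrete is None:
        discrete = bool(np.allclose(x, np.round(x)))
    if discrete:
        x = np.round(x)
    if xmin is not None:
        alpha, ks, n_tail = _fit_fixed_xmin(x, xmin, discrete)
        if n_tail < _MIN_TAIL:
            raise ValueError("tail too short: fewer than 100 samples above xmin")
        best_xmin = float(xmin)
    else:
        alpha, ks, best_xmin, n_tail = _scan_xmin(x, discrete)

    rng = np.random.default_rng(seed)
    body = x[x < best_xmin]
    p_tail = n_tail / len(x)
    boot_ks = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        n_from_tail = rng.binomial(len(x), p_tail)
        parts = [_sample_powerlaw(rng, n_from_tail, best_xmin, alpha, discrete)]
        if len(body):
            parts.append(rng.choice(body, size=len(x) - n_from_tail, replace=True))
        xb = np.concatenate(parts)
        try:
            if xmin is not None:
                _, boot_ks[b], _ = _fit_fixed_xmin(xb, xmin, discrete)
            else:
                _, boot_ks[b], _, _ = _scan_xmin(xb, discrete)
        except ValueError:
            boot_ks[b] = np.inf
    bootstrap_p = float((1 + np.sum(boot_ks >= ks)) / (n_bootstrap + 1))

    tail = x[x >= best_xmin]
    lp = _pointwise_loglik_power(tail, best_xmin, alpha, discrete)
    fit = PowerLawFit(float(alpha), float(best_xmin), ks, bootstrap_p, discrete,
                      int(n_tail), bootstrap_n=n_bootstrap)
    for alt in alternatives:
        if alt == "exponential":
            la = _pointwise_loglik_exponential(tail, best_xmin, discrete)
            fit.lr_vs_exponential = _vuong(lp, la)
            fit.alternatives["exponential"] = fit.lr_vs_exponential
        elif alt == "lognormal":
            la = _pointwise_loglik_lognormal(tail, best_xmin, discrete)
            fit.lr_vs_lognormal = _vuong(lp, la)
            fit.alternatives["lognormal"] = fit.lr_vs_lognormal
        else:
            raise ValueError(f"unknown alternative {alt!r}")
    return fit
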