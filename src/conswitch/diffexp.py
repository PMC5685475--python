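"""Negative-binomial likelihood-ratio test for two-group count data.

Per feature (gene or peak) a NB GLM with log link and library-size
offsets is fitted twice — one mean per group (full) and a single common
mean (null) — at a fixed per-feature dispersion, and the LRT statistic
2*(ll_full - ll_null) is referred to chi-square with 1 df.

Dispersion is a per-feature method-of-moments estimate shrunk 50/50
toward a trimmed-mean common dispersion, a simple self-contained
stand-in for the shrinkage estimators used by dedicated count-model
packages.  The Poisson model is the dispersion -> 0 limit and is used
directly below a small dispersion floor.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

_POISSON_EPS = 1e-10


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def estimate_dispersions(counts: np.ndarray, size_factors: np.ndarray,
                         groups: np.ndarray, shrink: float = 0.5,
                         trim: float = 0.25) -> np.ndarray:
    """Moment dispersions shrunk toward the trimmed-mean common value.

    phi solves var = mu + phi * mu^2 on size-factor-normalized counts,
    pooled within groups.
    """
    z = counts / size_factors[None, :]
    phi = np.zeros(counts.shape[0])
    ss = np.zeros(counts.shape[0])
    mu_sq = np.zeros(counts.shape[0])
    n_tot = 0
    mean_all = np.zeros(counts.shape[0])
    for g in np.unique(groups):
        cols = z[:, groups == g]
        m = cols.mean(axis=1)
        ss += ((cols - m[:, None]) ** 2).sum(axis=1)
        mu_sq += m ** 2 * cols.shape[1]
        mean_all += m * cols.shape[1]
        n_tot += cols.shape[1]
    var = ss / max(n_tot - len(np.unique(groups)), 1)
    mu = mean_all / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var - mu) / np.where(mu > 0, mu ** 2, 1.0)
    phi = np.clip(np.nan_to_num(phi, nan=0.0), 0.0, 100.0)
    informative = mu > 0
    if informative.any():
        common = float(stats.trim_mean(phi[informative], trim))
    else:
        common = 0.0
    return np.clip(shrink * common + (1 - shrink) * phi, _POISSON_EPS, 100.0)


def _fit_mean(counts: np.ndarray, size_factors: np.ndarray,
              phi: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """MLE of the per-feature rate q with mu_ij = s_j * q_i, vectorized
    Newton on b = log q."""
    y = counts
    s = size_factors[None, :]
    total = y.sum(axis=1)
    q0 = np.maximum(total / size_factors.sum(), 1e-8)
    b = np.log(q0)
    phi_col = phi[:, None]
    for _ in range(n_iter):
        mu = s * np.exp(b)[:, None]
        denom = 1.0 + phi_col * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + phi_col * y) / denom ** 2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return np.exp(b)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of NB log-pmf (Poisson below the dispersion floor)."""
    phi_col = phi[:, None]
    mu = np.maximum(mu, 1e-12)
    poisson_rows = phi <= _POISSON_EPS
    r = 1.0 / np.maximum(phi_col, _POISSON_EPS)
    ll_nb = (special.gammaln(y + r) - special.gammaln(r)
             - special.gammaln(y + 1.0)
             + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    ll_pois = y * np.log(mu) - mu - special.gammaln(y + 1.0)
    out = ll_nb.sum(axis=1)
    out[poisson_rows] = ll_pois[poisson_rows].sum(axis=1)
    return out


def nb_lrt_test(counts: np.ndarray, group_labels: np.ndarray,
                size_factors: np.ndarray | None = None,
                dispersion: np.ndarray | float | None = None,
                ) -> dict[str, np.ndarray]:
    """Two-group NB LRT per feature.

    Parameters
    ----------
    counts : (features, samples) non-negative integers.
    group_labels : length-samples array with exactly two distinct values;
        each group needs >= 2 samples.
    size_factors : optional library-size factors; default column sums
        scaled to mean 1.
    dispersion : optional fixed dispersion(s); default the shrunk moment
        estimator.

    Returns dict with ``stat``, ``p_value``, ``fdr``, ``dispersion`` and
    ``all_zero`` (features with no counts anywhere get p = 1, flagged).
    """
    counts = np.asarray(counts, dtype=float)
    group_labels = np.asarray(group_labels)
    levels = np.unique(group_labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    in_a = group_labels == levels[0]
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if size_factors is None:
        lib = counts.sum(axis=0)
        if np.any(lib == 0):
            raise ValueError("sample with zero total counts")
        size_factors = lib / lib.mean()
    size_factors = np.asarray(size_factors, dtype=float)

    groups01 = in_a.astype(int)
    if dispersion is None:
        phi = estimate_dispersions(counts, size_factors, groups01)
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float),
                              (counts.shape[0],)).copy()
        phi = np.clip(phi, 0.0, 100.0)

    q_null = _fit_mean(counts, size_factors, phi)
    q_a = _fit_mean(counts[:, in_a], size_factors[in_a], phi)
    q_b = _fit_mean(counts[:, ~in_a], size_factors[~in_a], phi)

    mu_null = size_factors[None, :] * q_null[:, None]
    ll_null = _nb_loglik(counts, mu_null, phi)
    ll_full = (_nb_loglik(counts[:, in_a],
                          size_factors[None, in_a] * q_a[:, None], phi)
               + _nb_loglik(counts[:, ~in_a],
                            size_factors[None, ~in_a] * q_b[:, None], phi))

    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(stat, df=1)
    all_zero = counts.sum(axis=1) == 0
    p[all_zero] = 1.0
    stat[all_zero] = 0.0
    return {"stat": stat, "p_value": p, "fdr": benjamini_hochberg(p),
            "dispersion": phi, "all_zero": all_zero}
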