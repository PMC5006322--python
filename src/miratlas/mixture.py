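"""Two-component Poisson mixture fitted by EM.

Used to separate "expressed" (high-intensity) from "background"
(low-intensity) animal-level counts of a single miRNA across tissues: the
component with the larger intensity models high counts, the one with the
smaller intensity models background noise, and the per-observation
posterior of the high component decides which tissues a miRNA is
expressed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp


@dataclass
class MixtureFit:
    """Result of a two-component Poisson mixture EM fit.

    Components are ordered so ``lambda_high >= lambda_low``.  ``collapsed``
    marks degenerate data (all observations equal, or a single component
    preferred by BIC); a collapsed fit has ``pi_high`` in {0, 1} and both
    intensities equal to the sample mean.
    """

    lambda_low: float
    lambda_high: float
    pi_high: float
    posterior_high: np.ndarray
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    collapsed: bool = False


def _poisson_loglik(x: np.ndarray, lam: float) -> np.ndarray:
    if lam <= 0:
        # Poisson(0) is a point mass at zero
        return np.where(x == 0, 0.0, -np.inf)
    return x * np.log(lam) - lam - gammaln(x + 1)


def _mixture_loglik(x: np.ndarray, lam_lo: float, lam_hi: float, pi_hi: float) -> float:
    if pi_hi <= 0:
        return float(_poisson_loglik(x, lam_lo).sum())
    if pi_hi >= 1:
        return float(_poisson_loglik(x, lam_hi).sum())
    comp = np.stack(
        [np.log1p(-pi_hi) + _poisson_loglik(x, lam_lo), np.log(pi_hi) + _poisson_loglik(x, lam_hi)]
    )
    return float(logsumexp(comp, axis=0).sum())


def fit_poisson_mixture(
    observations,
    *,
    max_iter: int = 1000,
    tol: float = 1e-8,
    collapse_by_bic: bool = True,
) -> MixtureFit:
    """Fit a two-component Poisson mixture to non-negative integer counts.

    EM runs until the log-likelihood change drops below ``tol`` (or
    ``max_iter``); the trace is recorded and is non-decreasing up to
    floating-point noise.  If BIC prefers a single Poisson (or the data are
    constant) the fit collapses to one component with ``pi_high`` = 1.
    """
    x = np.asarray(observations, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-D vector of at least 4 observations")
    if (x < 0).any() or not np.allclose(x, np.round(x)):
        raise ValueError("observations must be non-negative integers")
    n = x.size
    mean = float(x.mean())

    def collapsed_fit() -> MixtureFit:
        ll = _mixture_loglik(x, mean, mean, 1.0)
        return MixtureFit(
            lambda_low=mean,
            lambda_high=mean,
            pi_high=1.0,
            posterior_high=np.ones(n),
            loglik=ll,
            loglik_trace=[ll],
            converged=True,
            collapsed=True,
        )

    if np.all(x == x[0]):
        return collapsed_fit()

    # moment-style init: split at the mean, use half-means as intensities
    hi_mask = x > mean
    lam_hi = float(x[hi_mask].mean()) if hi_mask.any() else mean * 2 + 1
    lam_lo = float(x[~hi_mask].mean()) if (~hi_mask).all() or (~hi_mask).any() else mean / 2
    if lam_hi <= lam_lo:
        lam_hi = lam_lo + 1.0
    pi_hi = float(np.clip(hi_mask.mean(), 1e-3, 1 - 1e-3))

    trace: list[float] = []
    converged = False
    post_hi = np.full(n, pi_hi)
    for _ in range(max_iter):
        log_lo = np.log1p(-pi_hi) + _poisson_loglik(x, lam_lo)
        log_hi = np.log(pi_hi) + _poisson_loglik(x, lam_hi)
        norm = logsumexp(np.stack([log_lo, log_hi]), axis=0)
        trace.append(float(norm.sum()))
        post_hi = np.exp(log_hi - norm)
        w_hi = post_hi.sum()
        w_lo = n - w_hi
        pi_hi = float(np.clip(w_hi / n, 1e-12, 1 - 1e-12))
        lam_hi = float((post_hi * x).sum() / w_hi) if w_hi > 0 else lam_hi
        lam_lo = float(((1 - post_hi) * x).sum() / w_lo) if w_lo > 0 else lam_lo
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    loglik = _mixture_loglik(x, lam_lo, lam_hi, pi_hi)

    if lam_hi < lam_lo:
        lam_lo, lam_hi = lam_hi, lam_lo
        pi_hi = 1 - pi_hi
        post_hi = 1 - post_hi

    if collapse_by_bic:
        bic2 = -2 * loglik + 3 * np.log(n)
        bic1 = -2 * _mixture_loglik(x, mean, mean, 1.0) + np.log(n)
        if bic1 <= bic2:
            return collapsed_fit()

    return MixtureFit(
        lambda_low=lam_lo,
        lambda_high=lam_hi,
        pi_high=pi_hi,
        posterior_high=post_hi,
        loglik=loglik,
        loglik_trace=trace,
        converged=converged,
    )


def mixture_loglik(observations, lambda_low: float, lambda_high: float, pi_high: float) -> float:
    """Log-likelihood of a parameter triple (exposed for oracle comparison)."""
    x = np.asarray(observations, dtype=float)
    return _mixture_loglik(x, lambda_low, lambda_high, pi_high)
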