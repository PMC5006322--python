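"""Non-negative matrix factorization of the miRNA x organ count matrix.

X (N miRNAs x 14 organs) is decomposed as X ~ W H with W (N x k) and
H (k x organs) non-negative, minimizing the generalized Kullback-Leibler
divergence — the natural objective for count data.  Multiplicative updates
guarantee a non-increasing objective; several random restarts keep the
best local optimum.  Each column of W defines a miRNA group and the
corresponding row of H its expression pattern over organs, so a factor
whose H mass concentrates on one organ nominates its top-loading miRNAs
as organ-specific candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy

_EPS = 1e-12


@dataclass
class NmfFit:
    """A KL-NMF factorization with its objective trace."""

    W: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: list[float]
    seed: int
    mirnas: list[str] = field(default_factory=list)
    organs: list[str] = field(default_factory=list)

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(X || WH) = sum x log(x/wh) - x + wh."""
    WH = np.maximum(WH, _EPS)
    return float((xlogy(X, X / WH) - X + WH).sum())


def _mu_run(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n, m = X.shape
    scale = np.sqrt(X.mean() / k)
    W = rng.random((n, k)) * scale + _EPS
    H = rng.random((k, m)) * scale + _EPS
    trace = [kl_divergence(X, W @ H)]
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        W *= (X / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
        WH = np.maximum(W @ H, _EPS)
        H *= W.T @ (X / WH) / np.maximum(W.sum(axis=0), _EPS)[:, None]
        obj = kl_divergence(X, W @ H)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / max(prev, _EPS) < tol:
            break
        if prev <= tol:  # exact factorization reached
            break
    return W, H, trace


def nmf_factorize(
    organ_matrix: pd.DataFrame | np.ndarray,
    k: int = 14,
    seed: int = 0,
    *,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NmfFit:
    """Factorize a non-negative organ-level count matrix by KL-NMF.

    Runs ``n_restarts`` seeded random initializations of the multiplicative
    updates and keeps the lowest-divergence fit.  Convergence: relative
    objective change < ``tol`` or ``max_iter`` iterations.
    """
    if isinstance(organ_matrix, pd.DataFrame):
        mirnas = list(organ_matrix.index)
        organs = list(organ_matrix.columns)
        X = organ_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(organ_matrix, dtype=float)
        mirnas, organs = [], []
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    if not (X > 0).any():
        raise ValueError("cannot factorize an all-zero matrix")
    if k < 1 or k > X.shape[1]:
        raise ValueError(f"rank k must be in 1..{X.shape[1]}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(max(1, n_restarts)):
        W, H, trace = _mu_run(X, k, rng, max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, trace = best
    return NmfFit(W=W, H=H, k=k, objective_trace=trace, seed=seed, mirnas=mirnas, organs=organs)


def organ_specific_candidates(
    fit: NmfFit,
    organs: list[str] | None = None,
    *,
    dominance: float = 0.5,
) -> dict[str, str]:
    """Map each miRNA to its candidate organ via factor membership.

    A miRNA belongs to the factor maximizing its W row; the factor maps to
    the organ maximizing its H row.  A candidate is emitted only when that
    organ carries more than ``dominance`` of the factor's H mass (a flat
    factor nominates nobody).
    """
    organs = organs if organs is not None else fit.organs
    if not organs:
        raise ValueError("organ labels required")
    mirnas = fit.mirnas if fit.mirnas else [str(i) for i in range(fit.W.shape[0])]
    out: dict[str, str] = {}
    h_mass = fit.H.sum(axis=1)
    for i, mir in enumerate(mirnas):
        j = int(fit.W[i].argmax())
        if h_mass[j] <= 0:
            continue
        share = fit.H[j] / h_mass[j]
        o = int(share.argmax())
        if share[o] > dominance:
            out[mir] = organs[o]
    return out
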