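"""Serum qPCR biomarker analysis.

Covers the downstream half of a biomarker qualification study: Ct-level
QC against negative controls, spike-in normalized delta-delta-Ct fold
changes, a repeated-measures two-way ANOVA with autocorrelated
within-animal errors (generalized least squares with an AR(1) working
correlation), and the qPCR-versus-sequencing validation correlation.

Fold-change conventions follow the two study designs: a "vehicle" mode
references the control group at the matched timepoint (rat design) and a
"predose" mode references the pre-dose timepoint with its fold change
fixed at 1 (dog design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import QpcrStudy


# ---------------------------------------------------------------------------
# Ct quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcResult:
    accepted: bool
    reason: str


def _detected(ct) -> bool:
    return ct is not None and not (isinstance(ct, float) and math.isnan(ct))


def qc_ct(
    target_ct,
    ntc_ct=None,
    no_rt_ct=None,
    *,
    melt_multi_peak: bool = False,
    margin: float = 10.0,
) -> QcResult:
    """Accept or reject a Ct measurement against its negative controls.

    Accept iff the target Ct is at least ``margin`` cycles below every
    *detected* control (undetected controls — None/NaN — impose no bound),
    and the assay's melt curve has a single peak.  An undetected target is
    rejected as non-amplifying.  ``no_rt_ct`` may be a single value or an
    iterable of replicate no-RT wells.
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    if not _detected(target_ct):
        return QcResult(False, "no_amplification")
    if melt_multi_peak:
        return QcResult(False, "multi_peak_melt_curve")
    controls = []
    if ntc_ct is not None:
        controls.append(("ntc", ntc_ct))
    if no_rt_ct is not None:
        if np.iterable(no_rt_ct) and not isinstance(no_rt_ct, (str, bytes)):
            controls.extend(("no_rt", c) for c in no_rt_ct)
        else:
            controls.append(("no_rt", no_rt_ct))
    for name, ct in controls:
        if _detected(ct) and (ct - target_ct) < margin:
            return QcResult(False, f"within_{margin:g}ct_of_{name}")
    return QcResult(True, "ok")


# ---------------------------------------------------------------------------
# spike-in normalized fold changes
# ---------------------------------------------------------------------------

def spike_normalized_fold_change(
    study: QpcrStudy,
    reference: str = "vehicle",
    *,
    ref_group: str | None = None,
) -> pd.DataFrame:
    """Per-observation delta-delta-Ct fold changes normalized to a spike-in.

    delta-Ct = Ct_target - Ct_spike per (animal, timepoint); delta-delta-Ct
    subtracts the mean reference delta-Ct — the control group at the
    matched timepoint (``reference='vehicle'``) or the earliest timepoint
    pooled over groups (``reference='predose'``) — and FC = 2**(-ddCt).
    Observations lacking a spike-in well are excluded (count reported in
    ``attrs['n_missing_spike']``).  The result is invariant to any
    per-sample constant added to both Ct values.
    """
    if reference not in ("vehicle", "predose"):
        raise ValueError("reference must be 'vehicle' or 'predose'")
    wells = study.sample_wells()
    spike = wells[wells["target"] == study.spike].set_index(["animal", "timepoint"])["ct"]
    targets = wells[wells["target"] != study.spike].copy()
    key = list(zip(targets["animal"], targets["timepoint"]))
    targets["spike_ct"] = [spike.get(k, np.nan) for k in key]
    n_missing = int(targets["spike_ct"].isna().sum())
    targets = targets.dropna(subset=["spike_ct", "ct"])
    targets["dct"] = targets["ct"] - targets["spike_ct"]

    out = []
    for target, sub in targets.groupby("target", sort=False):
        sub = sub.copy()
        if reference == "vehicle":
            rg = ref_group if ref_group is not None else sub["group"].iloc[0]
            ref_means = sub[sub["group"] == rg].groupby("timepoint")["dct"].mean()
            sub["ddct"] = sub["dct"] - sub["timepoint"].map(ref_means)
        else:
            t0 = sub["timepoint"].min()
            sub["ddct"] = sub["dct"] - sub.loc[sub["timepoint"] == t0, "dct"].mean()
        sub["log2fc"] = -sub["ddct"]
        sub["fc"] = 2.0 ** sub["log2fc"]
        out.append(sub)
    result = pd.concat(out, ignore_index=True)[
        ["animal", "group", "timepoint", "target", "dct", "ddct", "log2fc", "fc"]
    ]
    result.attrs["n_missing_spike"] = n_missing
    result.attrs["reference"] = reference
    return result


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with AR(1) errors
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeResult:
    group: str
    timepoint: float
    target: str
    log2fc: float
    ci_low: float
    ci_high: float
    p_value: float
    is_reference: bool = False

    @property
    def fc(self) -> float:
        return 2.0 ** self.log2fc


@dataclass
class RepeatedAnovaFit:
    """A GLS fit of group x time cell means with within-animal correlation."""

    results: list[FoldChangeResult]
    rho: float
    sigma: float
    df: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": r.group,
                    "timepoint": r.timepoint,
                    "target": r.target,
                    "log2fc": r.log2fc,
                    "fc": r.fc,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "is_reference": r.is_reference,
                }
                for r in self.results
            ]
        )


def _estimate_rho(resid: pd.Series, animals: pd.Series, order: pd.Series) -> float:
    """Moment estimate of lag-1 autocorrelation of within-animal residuals.

    The denominator averages the squared residuals entering the lag pairs
    (not all T of them), which removes the (T-1)/T attenuation of the
    naive ACF at short series.
    """
    num = 0.0
    den = 0.0
    for _, idx in resid.groupby(animals).groups.items():
        r = resid.loc[idx].to_numpy()[np.argsort(order.loc[idx].to_numpy())]
        if len(r) < 2:
            continue
        num += float((r[:-1] * r[1:]).sum())
        den += 0.5 * float((r[:-1] ** 2).sum() + (r[1:] ** 2).sum())
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, -0.95, 0.95))


def _whiten_ar1(y: np.ndarray, X: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Innovation transform for one animal's time-ordered series."""
    zy = y.copy().astype(float)
    zX = X.copy().astype(float)
    if len(y) > 1:
        zy[1:] = y[1:] - rho * y[:-1]
        zX[1:] = X[1:] - rho * X[:-1]
    zy[0] *= np.sqrt(1 - rho**2)
    zX[0] *= np.sqrt(1 - rho**2)
    return zy, zX


def _whiten_cs(y: np.ndarray, X: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    T = len(y)
    R = np.full((T, T), rho) + (1 - rho) * np.eye(T)
    L = np.linalg.cholesky(R)
    Li = np.linalg.inv(L)
    return Li @ y, Li @ X


def fit_repeated_anova(
    fold_changes: pd.DataFrame,
    reference: str = "vehicle",
    *,
    ref_group: str | None = None,
    correlation: str = "ar1",
    conf_level: float = 0.95,
) -> dict[str, RepeatedAnovaFit]:
    """Fit log2 fold changes to a group x time ANOVA with repeated measures.

    ``fold_changes`` needs columns animal, group, timepoint, target,
    log2fc (the output of :func:`spike_normalized_fold_change`).  Cell
    means are estimated by generalized least squares: the within-animal
    error correlation (AR(1) by default, compound symmetry via
    ``correlation='cs'``) is estimated from OLS residuals, the data are
    whitened per animal and refit.  Each non-reference cell is reported as
    a *contrast* against the reference cell — the control group at the
    matched time (vehicle mode) or the group's earliest timepoint (predose
    mode) — with a t-based confidence interval and p-value; reference
    cells are emitted with FC fixed at 1 and no interval.  Returns one fit
    per target.
    """
    if correlation not in ("ar1", "cs"):
        raise ValueError("correlation must be 'ar1' or 'cs'")
    req = {"animal", "group", "timepoint", "target", "log2fc"}
    if not req.issubset(fold_changes.columns):
        raise ValueError(f"fold_changes must have columns {sorted(req)}")
    fits: dict[str, RepeatedAnovaFit] = {}
    for target, sub in fold_changes.groupby("target", sort=False):
        fits[target] = _fit_one_target(
            sub, target, reference, ref_group, correlation, conf_level
        )
    return fits


def _fit_one_target(
    data: pd.DataFrame,
    target: str,
    reference: str,
    ref_group: str | None,
    correlation: str,
    conf_level: float,
) -> RepeatedAnovaFit:
    data = data.reset_index(drop=True)
    groups = list(dict.fromkeys(data["group"]))
    times = sorted(data["timepoint"].unique())
    if len(times) < 2:
        raise ValueError("need >= 2 timepoints for a repeated-measures fit")
    cells = [(g, t) for g in groups for t in times]
    cell_index = {c: j for j, c in enumerate(cells)}
    sizes = data.groupby(["group", "timepoint"]).size()
    for c in cells:
        if c not in sizes.index or sizes[c] < 1:
            raise ValueError(f"empty design cell {c}")
    if data.groupby(["group", "timepoint"])["animal"].nunique().min() < 2:
        raise ValueError("need >= 2 animals per group")

    n = len(data)
    X = np.zeros((n, len(cells)))
    for i, (g, t) in enumerate(zip(data["group"], data["timepoint"])):
        X[i, cell_index[(g, t)]] = 1.0
    y = data["log2fc"].to_numpy(dtype=float)

    # OLS cell means -> residuals -> working correlation
    beta_ols = np.array(
        [data.loc[X[:, j] == 1, "log2fc"].mean() for j in range(len(cells))]
    )
    resid = pd.Series(y - X @ beta_ols, index=data.index)
    rho = _estimate_rho(resid, data["animal"], data["timepoint"])

    # whiten per animal in time order
    whiten = _whiten_ar1 if correlation == "ar1" else _whiten_cs
    Zy = np.empty_like(y)
    ZX = np.empty_like(X)
    for _, idx in data.groupby("animal").groups.items():
        idx = np.asarray(list(idx))
        order = np.argsort(data.loc[idx, "timepoint"].to_numpy())
        idx = idx[order]
        zy, zX = whiten(y[idx], X[idx], rho)
        Zy[idx] = zy
        ZX[idx] = zX

    XtX = ZX.T @ ZX
    XtXi = np.linalg.pinv(XtX)
    beta = XtXi @ ZX.T @ Zy
    df = n - len(cells)
    if df <= 0:
        raise ValueError("not enough observations for residual degrees of freedom")
    rss = float(((Zy - ZX @ beta) ** 2).sum())
    s2 = rss / df
    cov = s2 * XtXi
    tcrit = stats.t.ppf(0.5 + conf_level / 2, df)

    if reference == "vehicle":
        rg = ref_group if ref_group is not None else groups[0]
        if rg not in groups:
            raise ValueError(f"reference group {rg!r} not in design")
        ref_of = {(g, t): (rg, t) for g, t in cells}
    elif reference == "predose":
        t0 = times[0]
        ref_of = {(g, t): (g, t0) for g, t in cells}
    else:
        raise ValueError("reference must be 'vehicle' or 'predose'")

    results: list[FoldChangeResult] = []
    for g, t in cells:
        j = cell_index[(g, t)]
        rj = cell_index[ref_of[(g, t)]]
        if rj == j:
            results.append(
                FoldChangeResult(g, t, target, 0.0, 0.0, 0.0, np.nan, is_reference=True)
            )
            continue
        c = np.zeros(len(cells))
        c[j], c[rj] = 1.0, -1.0
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        p = float(2 * stats.t.sf(abs(est) / se, df)) if se > 0 else np.nan
        results.append(
            FoldChangeResult(g, t, target, est, est - tcrit * se, est + tcrit * se, p)
        )
    return RepeatedAnovaFit(results=results, rho=rho, sigma=float(np.sqrt(s2)), df=df)


# ---------------------------------------------------------------------------
# qPCR vs sequencing validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    pearson: float
    spearman: float
    n_pairs: int
    flagged: bool
    reason: str = ""


def correlate_qpcr_seq(ct_by_tissue: pd.Series, counts_by_tissue: pd.Series) -> CorrelationResult:
    """Correlate Ct with sequencing abundance across tissues for one target.

    Counts are log10(count+1)-transformed before the Pearson correlation
    (Ct is itself a log-scale quantity); Spearman is reported alongside so
    the transform choice is auditable.  A perfect agreement is -1: Ct
    decreases as abundance increases.  Undetected Ct values are excluded;
    fewer than 3 surviving pairs or a constant series is undefined.
    """
    joined = pd.concat(
        [ct_by_tissue.rename("ct"), counts_by_tissue.rename("count")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        return CorrelationResult(np.nan, np.nan, len(joined), True, "fewer_than_3_pairs")
    x = np.log10(joined["count"].to_numpy(dtype=float) + 1.0)
    y = joined["ct"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, len(joined), True, "constant_series")
    pearson = float(stats.pearsonr(y, x).statistic)
    spearman = float(stats.spearmanr(y, x).statistic)
    return CorrelationResult(pearson, spearman, len(joined), False)
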