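"""Tissue-specific and tissue-enriched miRNA classification.

Three independent definitions of specificity/enrichment are implemented,
one per analysis site, plus their cross-method comparison:

* **rule** — a tissue is "expressed" for a miRNA when a quorum of animals
  (8 of 10, proportionally 4 of 5 for single-sex tissues) shows a raw
  count above 1; exactly one expressed tissue = specific, a few (2-5) =
  enriched.  A sex rule (>1 in >= 4/5 of one sex, 0/5 in the other, in
  exactly one mixed-sex tissue) yields sex-specific calls.  Precedence:
  specific > sex_specific > enriched.
* **nmf_mixture** — KL-NMF of the organ-level matrix nominates
  organ-specific candidates; a two-component Poisson mixture over each
  candidate's animal-level counts then decides which tissues are "high"
  (majority of animals with posterior >= 0.5), refining the organ call to
  specific (one high tissue) or enriched (a few).
* **percentage** — the share of a miRNA's total reads carried by a single
  tissue (or tissue group): > 90 % = specific, > 50 % = enriched.
* **demir** — one-vs-rest quasi-Poisson significance (see
  :mod:`miratlas.demir`).

:func:`venn_compare` reports all set intersections between methods'
enriched id sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import fit_poisson_mixture
from .nmf import NmfFit, nmf_factorize, organ_specific_candidates
from .organs import SEX_RESTRICTED, organs_of
from .quantify import AtlasCounts, aggregate_organ, aggregate_tissue


@dataclass
class ClassificationCall:
    """A per-miRNA specificity call from one method."""

    mirna: str
    label: str  # specific | enriched | sex_specific | none
    tissues: tuple[str, ...] = ()
    organs: tuple[str, ...] = ()
    method: str = "rule"
    score: float | None = None
    sex: str | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.label == "specific" and len(self.tissues) != 1:
            raise ValueError(f"{self.mirna}: specific calls carry exactly one tissue")


def calls_frame(calls: list[ClassificationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": c.mirna,
                "label": c.label,
                "tissues": ";".join(c.tissues),
                "organs": ";".join(c.organs),
                "method": c.method,
                "score": c.score,
                "sex": c.sex or "",
            }
            for c in calls
        ]
    )


def enriched_ids(calls: list[ClassificationCall], *, include_specific: bool = True) -> set[str]:
    """The miRNA id set a method would contribute to the enrichment Venn."""
    labels = {"enriched", "specific"} if include_specific else {"enriched"}
    return {c.mirna for c in calls if c.label in labels}


# ---------------------------------------------------------------------------
# rule-based (animal quorum) classifier
# ---------------------------------------------------------------------------

def classify_rule_based(
    atlas: AtlasCounts,
    *,
    expressed_threshold: float = 1.0,
    quorum_frac: float = 0.8,
    enriched_max_tissues: int = 5,
    sex_quorum: int = 4,
) -> list[ClassificationCall]:
    """Classify miRNAs by the animal-quorum expression rule on raw counts.

    A tissue counts as expressed when at least ``ceil(quorum_frac * n)``
    of its ``n`` animals exceed ``expressed_threshold`` (8 of 10 at the
    defaults; 4 of 5 for single-sex tissues).  Exactly one expressed tissue
    gives specific; 2..``enriched_max_tissues`` give enriched.  The sex
    rule (>= ``sex_quorum`` of one sex above threshold, none of the other)
    is evaluated per mixed-sex tissue and fires when exactly one tissue
    matches and the plain rule called nothing stronger.
    """
    samples = atlas.samples
    counts = atlas.counts
    tissues = list(dict.fromkeys(samples["tissue"]))
    expressed_mask = counts > expressed_threshold

    quorum: dict[str, int] = {}
    for tissue in tissues:
        n = int((samples["tissue"] == tissue).sum())
        q = math.ceil(quorum_frac * n)
        if q > n:
            raise ValueError(f"quorum {q} exceeds {n} animals in {tissue}")
        quorum[tissue] = q

    n_expr = pd.DataFrame(index=counts.index)
    for tissue in tissues:
        cols = samples.index[samples["tissue"] == tissue]
        n_expr[tissue] = expressed_mask[cols].sum(axis=1)
    is_expressed = pd.DataFrame(
        {t: n_expr[t] >= quorum[t] for t in tissues}, index=counts.index
    )

    # sex rule per mixed-sex tissue
    sex_hits: dict[str, list[tuple[str, str]]] = {m: [] for m in counts.index}
    for tissue in tissues:
        if tissue in SEX_RESTRICTED:
            continue
        males = samples.index[(samples["tissue"] == tissue) & (samples["sex"] == "M")]
        females = samples.index[(samples["tissue"] == tissue) & (samples["sex"] == "F")]
        if len(males) == 0 or len(females) == 0:
            continue
        m_cnt = expressed_mask[males].sum(axis=1)
        f_cnt = expressed_mask[females].sum(axis=1)
        m_hit = (m_cnt >= sex_quorum) & (f_cnt == 0)
        f_hit = (f_cnt >= sex_quorum) & (m_cnt == 0)
        for mir in counts.index[m_hit]:
            sex_hits[mir].append((tissue, "M"))
        for mir in counts.index[f_hit]:
            sex_hits[mir].append((tissue, "F"))

    organ_map = atlas.organ_map()
    calls: list[ClassificationCall] = []
    for mir in counts.index:
        expr = tuple(t for t in tissues if is_expressed.at[mir, t])
        if len(expr) == 1:
            label, tset = "specific", expr
        elif len(sex_hits[mir]) == 1 and len(expr) == 0:
            tissue, sex = sex_hits[mir][0]
            calls.append(
                ClassificationCall(
                    mir, "sex_specific", (tissue,), (organ_map[tissue],), "rule", sex=sex
                )
            )
            continue
        elif 2 <= len(expr) <= enriched_max_tissues:
            label, tset = "enriched", expr
        else:
            label, tset = "none", ()
        calls.append(
            ClassificationCall(
                mir,
                label,
                tset,
                tuple(dict.fromkeys(organ_map[t] for t in tset)),
                "rule",
                score=float(len(expr)),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# NMF + Poisson mixture classifier
# ---------------------------------------------------------------------------

def refine_tissue_specific(
    candidates: dict[str, str],
    atlas: AtlasCounts,
    *,
    posterior_cutoff: float = 0.5,
    enriched_max_tissues: int = 5,
) -> list[ClassificationCall]:
    """Refine organ-specific candidates to tissue level via Poisson mixtures.

    For each candidate miRNA a two-component Poisson mixture is fitted to
    its animal-level counts across all tissues; a tissue is "high" when a
    majority of its animals have posterior(high) >= ``posterior_cutoff``.
    Exactly one high tissue = specific; 2..``enriched_max_tissues`` =
    enriched; a collapsed mixture or a diffuse high set yields no call.
    """
    samples = atlas.samples
    tissues = list(dict.fromkeys(samples["tissue"]))
    organ_map = atlas.organ_map()
    calls: list[ClassificationCall] = []
    for mir, organ in candidates.items():
        x = atlas.counts.loc[mir].to_numpy()
        fit = fit_poisson_mixture(np.round(x).astype(int))
        if fit.collapsed:
            calls.append(ClassificationCall(mir, "none", method="nmf_mixture", flagged=True))
            continue
        high = fit.posterior_high >= posterior_cutoff
        high_tissues = []
        for tissue in tissues:
            mask = (samples["tissue"] == tissue).to_numpy()
            if mask.sum() and high[mask].sum() > mask.sum() / 2:
                high_tissues.append(tissue)
        if len(high_tissues) == 1:
            calls.append(
                ClassificationCall(
                    mir,
                    "specific",
                    tuple(high_tissues),
                    (organ_map[high_tissues[0]],),
                    "nmf_mixture",
                    score=fit.lambda_high,
                )
            )
        elif 2 <= len(high_tissues) <= enriched_max_tissues:
            calls.append(
                ClassificationCall(
                    mir,
                    "enriched",
                    tuple(high_tissues),
                    tuple(dict.fromkeys(organ_map[t] for t in high_tissues)),
                    "nmf_mixture",
                    score=fit.lambda_high,
                )
            )
        else:
            calls.append(ClassificationCall(mir, "none", method="nmf_mixture"))
    return calls


def classify_nmf_mixture(
    atlas: AtlasCounts,
    *,
    k: int = 14,
    seed: int = 0,
    dominance: float = 0.5,
    enriched_max_tissues: int = 5,
) -> tuple[list[ClassificationCall], NmfFit]:
    """Full NMF route: organ matrix -> factorize -> candidates -> refine."""
    tissue_mat = aggregate_tissue(atlas)
    organ_mat = aggregate_organ(tissue_mat, atlas.organ_map())
    k = min(k, organ_mat.shape[1])
    fit = nmf_factorize(organ_mat, k=k, seed=seed)
    candidates = organ_specific_candidates(fit, dominance=dominance)
    calls = refine_tissue_specific(
        candidates, atlas, enriched_max_tissues=enriched_max_tissues
    )
    called = {c.mirna for c in calls}
    for mir in atlas.mirnas:
        if mir not in called:
            calls.append(ClassificationCall(mir, "none", method="nmf_mixture"))
    return calls, fit


# ---------------------------------------------------------------------------
# percentage-of-reads classifier
# ---------------------------------------------------------------------------

def classify_percentage(
    tissue_matrix: pd.DataFrame,
    *,
    specific_threshold: float = 90.0,
    enriched_threshold: float = 50.0,
    organ_map: dict[str, str] | None = None,
) -> list[ClassificationCall]:
    """Classify by the read share of a single tissue or tissue group.

    Share = 100 * tissue count / miRNA total; > ``specific_threshold``
    (90 %) = specific, else > ``enriched_threshold`` (50 %) = enriched.
    With an ``organ_map``, shares are evaluated per tissue group (summed
    within organ) and calls carry the group's member tissues.  Zero-total
    miRNAs are reported as none, flagged.
    """
    if organ_map is not None:
        groups = organs_of(organ_map)
        mat = tissue_matrix.T.groupby(
            pd.Series({t: organ_map[t] for t in tissue_matrix.columns})
        ).sum().T
        members = {g: [t for t in groups[g] if t in tissue_matrix.columns] for g in mat.columns}
    else:
        mat = tissue_matrix
        members = {t: [t] for t in tissue_matrix.columns}

    totals = mat.sum(axis=1)
    calls: list[ClassificationCall] = []
    for mir in mat.index:
        total = totals[mir]
        if total <= 0:
            calls.append(ClassificationCall(mir, "none", method="percentage", flagged=True))
            continue
        shares = 100.0 * mat.loc[mir] / total
        top = shares.idxmax()
        share = float(shares[top])
        tset = tuple(members[top])
        oset = (top,) if organ_map is not None else ()
        if share > specific_threshold and len(tset) == 1:
            calls.append(
                ClassificationCall(mir, "specific", tset, oset, "percentage", score=share)
            )
        elif share > enriched_threshold:
            calls.append(
                ClassificationCall(mir, "enriched", tset, oset, "percentage", score=share)
            )
        else:
            calls.append(ClassificationCall(mir, "none", method="percentage", score=share))
    return calls


# ---------------------------------------------------------------------------
# cross-method comparison
# ---------------------------------------------------------------------------

def venn_compare(call_sets: dict[str, set[str]]) -> pd.DataFrame:
    """All singleton, pairwise, ... full intersections of named id sets.

    One row per non-empty combination of set names, with the intersection
    size and the sorted shared ids.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least 2 call sets to compare")
    names = list(call_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(call_sets[n] for n in combo))
            rows.append(
                {
                    "sets": "&".join(combo),
                    "n_sets": r,
                    "size": len(inter),
                    "ids": ";".join(sorted(inter)),
                }
            )
    return pd.DataFrame(rows)
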