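"""Synthetic atlas generators with planted ground truth.

Every downstream stage of the pipeline (read processing, quantification,
the three tissue-specificity classifiers, the serum qPCR analysis) is
exercisable on data produced here, with the truth recorded alongside:

* toy precursor hairpin sets, tiered by species with some tier-exclusive
  records, mimicking the rat -> mouse -> human -> C. elegans cascade;
* small-RNA reads as mature-arm subsequences shifted by sampled 5'/3'
  isomiR offsets, with the 3' sequencing adapter appended;
* animal-level atlas count matrices drawn from a two-component Poisson
  model — Poisson(lambda_high) in a miRNA's enriched tissues,
  Poisson(lambda_low) background elsewhere — over 23 tissues / 14 organs
  and 5 male + 5 female animals (215 samples), the design of the rat body
  atlas; an optional gamma-mixed (negative-binomial) overdispersion knob
  supports quasi-Poisson power studies;
* qPCR time-course studies with AR(1) within-animal noise, spike-in wells
  and NTC / no-RT / water-extraction control wells.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .organs import DEFAULT_ORGAN_MAP, DEFAULT_TISSUES, SEX_RESTRICTED, validate_organ_map
from .quantify import AtlasCounts
from .reads import MatureWindow, PrecursorRecord

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# precursor sets and reads
# ---------------------------------------------------------------------------

def _random_hairpin(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _make_precursor(
    rng: np.random.Generator, species: str, idx: int, *, both_arms_p: float = 0.75
) -> PrecursorRecord:
    length = int(rng.integers(60, 91))
    seq = _random_hairpin(rng, length)
    windows: list[MatureWindow] = []
    len5 = int(rng.integers(19, 26))
    start5 = int(rng.integers(2, 6))
    len3 = int(rng.integers(19, 26))
    end3 = length - int(rng.integers(1, 5))
    start3 = end3 - len3 + 1
    name = f"{species[:3]}-mir-{idx}"
    w5 = MatureWindow(f"{species[:3]}-miR-{idx}-5p", "5p", start5, start5 + len5 - 1)
    w3 = MatureWindow(f"{species[:3]}-miR-{idx}-3p", "3p", start3, end3)
    if rng.random() < both_arms_p:
        windows = [w5, w3]
    else:
        windows = [w5 if rng.random() < 0.5 else w3]
    return PrecursorRecord(name=name, species=species, sequence=seq, mature_windows=windows)


def generate_precursor_set(
    n_precursors: int,
    species_tiers: list[str],
    seed: int,
    *,
    shared_fraction: float = 0.7,
) -> list[tuple[str, list[PrecursorRecord]]]:
    """Generate a tiered precursor collection.

    The first tier holds ``n_precursors`` hairpins.  Each later tier carries
    a ``shared_fraction`` subset of the first tier's hairpins (same sequence,
    renamed with the tier's species prefix) plus at least one tier-exclusive
    new hairpin, so the cross-species cascade always has something to find.
    """
    if n_precursors < 1:
        raise ValueError("n_precursors must be >= 1")
    if not species_tiers:
        raise ValueError("species_tiers must be non-empty")
    rng = np.random.default_rng(seed)
    base = [_make_precursor(rng, species_tiers[0], i + 1) for i in range(n_precursors)]
    tiers: list[tuple[str, list[PrecursorRecord]]] = [(species_tiers[0], base)]
    next_idx = n_precursors + 1
    for species in species_tiers[1:]:
        records: list[PrecursorRecord] = []
        for prec in base:
            if rng.random() < shared_fraction:
                idx = prec.name.rsplit("-", 1)[1]
                records.append(
                    PrecursorRecord(
                        name=f"{species[:3]}-mir-{idx}",
                        species=species,
                        sequence=prec.sequence,
                        mature_windows=[
                            MatureWindow(
                                f"{species[:3]}-miR-{idx}-{w.arm}", w.arm, w.start, w.end
                            )
                            for w in prec.mature_windows
                        ],
                    )
                )
        n_new = max(1, n_precursors // 5)
        for _ in range(n_new):
            records.append(_make_precursor(rng, species, next_idx))
            next_idx += 1
        tiers.append((species, records))
    return tiers


@dataclass(frozen=True)
class SimulatedRead:
    """A generated read with its provenance for truth checking."""

    sequence: str
    precursor: str
    true_mature: str
    offset5: int
    offset3: int


def generate_reads(
    precursors: list[PrecursorRecord],
    isomir_profile: dict[tuple[int, int], float],
    adapter: str,
    n_reads: int,
    seed: int,
) -> list[SimulatedRead]:
    """Simulate small-RNA reads from annotated mature arms.

    Each read is a mature-window subsequence shifted by a sampled
    (5' offset, 3' offset) pair from ``isomir_profile`` (a distribution over
    offset pairs; negative 5' offsets extend upstream, positive 3' offsets
    extend downstream), with the 3' adapter appended.  Offsets are clipped
    to hairpin bounds.  Reads are uniform-quality; no sequencing-error
    substitutions are simulated.
    """
    if not precursors:
        raise ValueError("precursor set must be non-empty")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    offsets = list(isomir_profile)
    probs = np.array([isomir_profile[o] for o in offsets], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("isomir_profile probabilities must sum to a positive value")
    probs = probs / probs.sum()
    arms = [
        (prec, w) for prec in precursors for w in prec.mature_windows
    ]
    if not arms:
        raise ValueError("no mature windows annotated in precursor set")
    rng = np.random.default_rng(seed)
    arm_idx = rng.integers(0, len(arms), size=n_reads)
    off_idx = rng.choice(len(offsets), size=n_reads, p=probs)
    reads: list[SimulatedRead] = []
    for ai, oi in zip(arm_idx, off_idx):
        prec, w = arms[ai]
        d5, d3 = offsets[oi]
        start = max(1, w.start + d5)
        end = min(len(prec.sequence), w.end + d3)
        insert = prec.sequence[start - 1 : end]
        reads.append(
            SimulatedRead(
                sequence=insert + adapter.upper().replace("U", "T"),
                precursor=prec.name,
                true_mature=w.name,
                offset5=start - w.start,
                offset3=end - w.end,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# atlas count matrices
# ---------------------------------------------------------------------------

@dataclass
class AtlasDesign:
    """Design of a planted atlas count matrix.

    ``enrichment_patterns`` maps each miRNA to the set of tissues where it
    is drawn from the high Poisson component; the empty set means pure
    background.  ``sex_patterns`` maps a miRNA to ``(tissue, sex)``: the
    named sex draws high counts in that tissue while the opposite sex emits
    exact zeros there.  ``library_scale`` multiplies the Poisson mean per
    sample (scalar, or mapping sample id -> factor).  ``overdispersion`` > 0
    gamma-mixes the Poisson rate (variance = mu + overdispersion * mu^2).
    """

    n_mirnas: int
    enrichment_patterns: dict[str, frozenset[str]]
    sex_patterns: dict[str, tuple[str, str]] = field(default_factory=dict)
    tissues: list[str] = field(default_factory=lambda: list(DEFAULT_TISSUES))
    organ_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ORGAN_MAP))
    n_animals_per_sex: int = 5
    lambda_high: float = 500.0
    lambda_low: float = 1.0
    library_scale: float | dict[str, float] = 1.0
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lambda_high > self.lambda_low >= 0):
            raise ValueError("require lambda_high > lambda_low >= 0")
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        validate_organ_map(self.organ_map, self.tissues)
        for mir, tset in self.enrichment_patterns.items():
            unknown = set(tset) - set(self.tissues)
            if unknown:
                raise ValueError(f"{mir}: unknown tissues in enrichment pattern {unknown}")

    @property
    def mirnas(self) -> list[str]:
        return [f"miR-{i + 1:03d}" for i in range(self.n_mirnas)]


@dataclass
class TruthLabels:
    """Planted per-miRNA labels, recomputable from the design patterns."""

    table: pd.DataFrame  # index mirna; columns label, tissues, sex

    @classmethod
    def from_design(cls, design: AtlasDesign) -> "TruthLabels":
        rows = []
        for mir in design.mirnas:
            if mir in design.sex_patterns:
                tissue, sex = design.sex_patterns[mir]
                rows.append((mir, "sex_specific", tissue, sex))
                continue
            tset = sorted(design.enrichment_patterns.get(mir, frozenset()))
            if len(tset) == 0:
                rows.append((mir, "none", "", ""))
            elif len(tset) == 1:
                rows.append((mir, "specific", tset[0], ""))
            else:
                rows.append((mir, "enriched", ";".join(tset), ""))
        table = pd.DataFrame(rows, columns=["mirna", "label", "tissues", "sex"]).set_index("mirna")
        return cls(table)

    def ids_with_label(self, *labels: str) -> set[str]:
        return set(self.table.index[self.table["label"].isin(labels)])


def atlas_samples(
    tissues: list[str],
    organ_map: dict[str, str],
    n_animals_per_sex: int = 5,
) -> pd.DataFrame:
    """Sample sheet for a full animal panel (single-sex tissues respected)."""
    rows = []
    animals = [(f"M{i + 1}", "M") for i in range(n_animals_per_sex)] + [
        (f"F{i + 1}", "F") for i in range(n_animals_per_sex)
    ]
    for tissue in tissues:
        for animal, sex in animals:
            restricted = SEX_RESTRICTED.get(tissue)
            if restricted is not None and sex != restricted:
                continue
            rows.append(
                {
                    "sample": f"{animal}_{tissue}",
                    "animal": animal,
                    "sex": sex,
                    "tissue": tissue,
                    "organ": organ_map[tissue],
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def generate_atlas_counts(design: AtlasDesign) -> tuple[AtlasCounts, TruthLabels]:
    """Draw an animal-level count matrix from the planted two-component model.

    Counts for (miRNA, animal, tissue) come from Poisson(lambda_high * scale)
    when the tissue is in the miRNA's enrichment set, Poisson(lambda_low *
    scale) otherwise.  Sex-specific patterns emit exact zeros in the
    opposite sex within their tissue.  Fixed seed implies a byte-identical
    matrix on re-run.
    """
    rng = np.random.default_rng(design.seed)
    samples = atlas_samples(design.tissues, design.organ_map, design.n_animals_per_sex)
    mirnas = design.mirnas
    n, m = len(mirnas), len(samples)

    if isinstance(design.library_scale, dict):
        scale = np.array([design.library_scale.get(s, 1.0) for s in samples.index])
    else:
        scale = np.full(m, float(design.library_scale))

    tissue_arr = samples["tissue"].to_numpy()
    sex_arr = samples["sex"].to_numpy()
    lam = np.full((n, m), design.lambda_low, dtype=float)
    for i, mir in enumerate(mirnas):
        if mir in design.sex_patterns:
            tissue, sex = design.sex_patterns[mir]
            in_tissue = tissue_arr == tissue
            lam[i, in_tissue & (sex_arr == sex)] = design.lambda_high
            lam[i, in_tissue & (sex_arr != sex)] = 0.0
        else:
            for tissue in design.enrichment_patterns.get(mir, frozenset()):
                lam[i, tissue_arr == tissue] = design.lambda_high
    mu = lam * scale[None, :]
    if design.overdispersion > 0:
        shape = 1.0 / design.overdispersion
        mu = mu * rng.gamma(shape, 1.0 / shape, size=mu.shape)
    counts = rng.poisson(mu)
    atlas = AtlasCounts(
        counts=pd.DataFrame(counts, index=mirnas, columns=samples.index),
        samples=samples,
    )
    return atlas, TruthLabels.from_design(design)


def random_design(
    n_mirnas: int = 300,
    n_specific: int = 10,
    n_enriched: int = 30,
    n_sex_specific: int = 0,
    *,
    lambda_high: float = 500.0,
    lambda_low: float = 1.0,
    enriched_tissue_range: tuple[int, int] = (2, 4),
    seed: int = 0,
    **kwargs,
) -> AtlasDesign:
    """Random planted design mirroring the atlas study conditions.

    Specific miRNAs occupy one random tissue.  Enriched miRNAs occupy 2-4
    tissues drawn within a single multi-tissue organ, so that all three
    institutional definitions of enrichment (animal-quorum rule, read-share
    within a tissue group, one-vs-rest differential expression) describe the
    same planted object.  Sex-specific miRNAs occupy one mixed-sex tissue in
    one sex.  The remainder are pure background.
    """
    if n_specific + n_enriched + n_sex_specific > n_mirnas:
        raise ValueError("more planted miRNAs than n_mirnas")
    rng = np.random.default_rng(seed)
    tissues = kwargs.get("tissues", list(DEFAULT_TISSUES))
    organ_map = kwargs.get("organ_map", dict(DEFAULT_ORGAN_MAP))
    by_organ: dict[str, list[str]] = {}
    for t in tissues:
        by_organ.setdefault(organ_map[t], []).append(t)
    multi = [o for o, ts in by_organ.items() if len(ts) >= 2]
    mixed = [t for t in tissues if t not in SEX_RESTRICTED]

    mirnas = [f"miR-{i + 1:03d}" for i in range(n_mirnas)]
    order = list(rng.permutation(n_mirnas))
    patterns: dict[str, frozenset[str]] = {}
    sex_patterns: dict[str, tuple[str, str]] = {}
    pos = 0
    for _ in range(n_specific):
        mir = mirnas[order[pos]]
        patterns[mir] = frozenset([tissues[rng.integers(len(tissues))]])
        pos += 1
    lo, hi = enriched_tissue_range
    for _ in range(n_enriched):
        mir = mirnas[order[pos]]
        organ = multi[rng.integers(len(multi))]
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(by_organ[organ]))
        k = max(k, 2)
        chosen = rng.choice(by_organ[organ], size=k, replace=False)
        patterns[mir] = frozenset(chosen.tolist())
        pos += 1
    for _ in range(n_sex_specific):
        mir = mirnas[order[pos]]
        sex_patterns[mir] = (mixed[rng.integers(len(mixed))], "M" if rng.random() < 0.5 else "F")
        pos += 1
    return AtlasDesign(
        n_mirnas=n_mirnas,
        enrichment_patterns=patterns,
        sex_patterns=sex_patterns,
        lambda_high=lambda_high,
        lambda_low=lambda_low,
        seed=int(rng.integers(2**31)),
        **{k: v for k, v in kwargs.items() if k in ("tissues", "organ_map", "n_animals_per_sex", "library_scale", "overdispersion")},
    )


# ---------------------------------------------------------------------------
# qPCR studies
# ---------------------------------------------------------------------------

@dataclass
class QpcrStudy:
    """A qPCR Ct table over animals x timepoints x targets.

    ``wells`` columns: animal, group, timepoint, target, ct, well_type
    (sample / ntc / no_rt / water).  Undetected wells carry NaN Ct.
    ``truth`` (optional) is the planted log2 fold-change table indexed by
    (group, timepoint).
    """

    wells: pd.DataFrame
    spike: str
    truth: pd.DataFrame | None = None
    melt_multi_peak: dict[str, bool] = field(default_factory=dict)

    def sample_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["well_type"] == "sample"]


def _ar1_noise(rng: np.random.Generator, n_series: int, length: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) noise, one series per row."""
    eps = np.empty((n_series, length))
    eps[:, 0] = rng.normal(0.0, sigma, size=n_series)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for t in range(1, length):
        eps[:, t] = rho * eps[:, t - 1] + rng.normal(0.0, innov_sd, size=n_series)
    return eps


def generate_qpcr_study(
    groups: list[str],
    timepoints: list[float],
    n_animals: int,
    true_log2fc: dict[tuple[str, float], float],
    rho: float,
    sigma: float,
    seed: int,
    *,
    target: str = "miR-216a-5p",
    spike: str = "cel-miR-55-3p",
    spike_ct: float = 20.0,
    baseline_dct: float = 8.0,
) -> QpcrStudy:
    """Simulate a spike-in normalized qPCR time-course study.

    Per animal, the target's delta-Ct (Ct_target - Ct_spike) trajectory is
    ``baseline_dct - true_log2fc[group, time] + AR(1) noise`` (one extra
    qPCR cycle = one doubling, so a fold change of 2^f lowers delta-Ct by
    f).  A per-(animal, time) extraction shift is added to both the spike
    and the target Ct so that the study exercises the delta-Ct cancellation
    invariance.  NTC, two no-RT and a water-extraction control well are
    included; NTC / no-RT are undetected (NaN).
    """
    if not abs(rho) < 1:
        raise ValueError("require |rho| < 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n_animals < 1 or not groups or not timepoints:
        raise ValueError("need >= 1 animal, group and timepoint")
    rng = np.random.default_rng(seed)
    tps = sorted(timepoints)
    rows = []
    for group in groups:
        eps = _ar1_noise(rng, n_animals, len(tps), rho, sigma)
        for a in range(n_animals):
            animal = f"{group}_a{a + 1}"
            for j, t in enumerate(tps):
                shift = rng.normal(0.0, 1.0)
                dct = baseline_dct - true_log2fc.get((group, t), 0.0) + eps[a, j]
                rows.append((animal, group, t, spike, spike_ct + shift, "sample"))
                rows.append((animal, group, t, target, spike_ct + shift + dct, "sample"))
    rows.append(("", "", np.nan, target, np.nan, "ntc"))
    rows.append(("", "", np.nan, target, np.nan, "no_rt"))
    rows.append(("", "", np.nan, target, np.nan, "no_rt"))
    rows.append(("water", "", np.nan, spike, spike_ct, "water"))
    wells = pd.DataFrame(
        rows, columns=["animal", "group", "timepoint", "target", "ct", "well_type"]
    )
    truth = pd.DataFrame(
        [(g, t, true_log2fc.get((g, t), 0.0)) for g in groups for t in tps],
        columns=["group", "timepoint", "log2fc"],
    ).set_index(["group", "timepoint"])
    return QpcrStudy(wells=wells, spike=spike, truth=truth)
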