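"""isomiR identification from small-RNA reads against precursor hairpins.

Raw reads are adapter-trimmed, collapsed to unique sequences per sample,
exact-matched (no mismatches, no gaps) against precursor hairpin sets and
named by their mapping footprint: ``<precursor>_<arm>_<start>_<end>`` with
1-based inclusive coordinates (e.g. ``miR-127_3p_57_78``).  A sequence whose
footprint overlaps an annotated mature arm is assigned that mature name; a
footprint matching several precursors with distinct mature names receives a
composite ``;``-joined name (e.g. ``let-7a-5p;let-7f-5p``) to mark the
ambiguity; a footprint on a precursor but outside any annotated mature
window is assigned ``<precursor>-pre``.  Sequences unmatched in the first
species tier cascade to later tiers (rat -> mouse -> human -> C. elegans),
which recovers conserved miRNAs not yet annotated in the primary species.
Multi-locus sequences have their counts divided evenly across loci so that
total read count is conserved.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from fractions import Fraction

import pandas as pd

_VALID_SEQ = re.compile(r"^[ACGT]+$")


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class MatureWindow:
    """An annotated mature arm inside a hairpin (1-based inclusive)."""

    name: str
    arm: str  # "5p" or "3p"
    start: int
    end: int


@dataclass
class PrecursorRecord:
    """A hairpin sequence with annotated mature-arm windows."""

    name: str
    species: str
    sequence: str
    mature_windows: list[MatureWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_seq(self.sequence)
        for w in self.mature_windows:
            if not (1 <= w.start <= w.end <= len(self.sequence)):
                raise ValueError(
                    f"{self.name}: mature window {w.name} [{w.start},{w.end}] "
                    f"outside hairpin of length {len(self.sequence)}"
                )
            if w.arm not in ("5p", "3p"):
                raise ValueError(f"{self.name}: arm must be 5p or 3p, got {w.arm!r}")
        for a, b in zip(self.mature_windows, self.mature_windows[1:]):
            if min(a.end, b.end) >= max(a.start, b.start):
                raise ValueError(f"{self.name}: mature windows overlap")

    def mature_sequence(self, window: MatureWindow) -> str:
        return self.sequence[window.start - 1 : window.end]


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its multiplicity, id form ``NNN_#_x#``."""

    id: str
    sequence: str
    count: int


@dataclass(frozen=True)
class Locus:
    """An exact-match placement of a sequence on a precursor (1-based incl.)."""

    precursor: str
    start: int
    end: int


@dataclass
class IsomiRAssignment:
    """One mapped locus of a unique sequence.

    ``count`` is the (possibly fractional) per-locus count after multi-locus
    division; ``count * n_loci`` restores the original integer read count.
    ``assigned_mature`` is shared by all loci of the sequence and is either a
    single mature name, a ``;``-joined composite, or ``<precursor>-pre``.
    """

    sequence: str
    isomir_name: str
    assigned_mature: str
    species_tier: str
    count: float
    n_loci: int


@dataclass(frozen=True)
class TrimProfile:
    """Adapter-trimming policy of one analysis site.

    Quality filtering (q20 in the Lilly profile) applies to FASTQ input only
    and is a no-op on FASTA; it is carried as configuration.
    """

    name: str
    min_len: int
    max_len: int | None
    match_prefix_len: int = 8
    drop_n: bool = False
    strict_adapter: bool = False  # discard reads with no adapter occurrence
    quality_cutoff: int | None = None


TRIM_PROFILES: dict[str, TrimProfile] = {
    "lilly": TrimProfile("lilly", min_len=17, max_len=None, match_prefix_len=10,
                         drop_n=True, quality_cutoff=20),
    "maastricht": TrimProfile("maastricht", min_len=16, max_len=35,
                              match_prefix_len=8),
    "niehs": TrimProfile("niehs", min_len=14, max_len=24, match_prefix_len=8),
}


def trim_adapter(
    read: str,
    adapter: str,
    *,
    min_len: int,
    max_len: int | None = None,
    match_prefix_len: int = 8,
    drop_n: bool = False,
    strict_adapter: bool = False,
) -> tuple[str | None, str]:
    """Trim the 3' adapter off one read.

    The read is truncated at the first occurrence of the adapter's first
    ``match_prefix_len`` bases (a perfect-match hit).  Returns
    ``(trimmed_sequence, "kept")`` or ``(None, reason)`` where reason is one
    of ``empty``, ``contains_n``, ``no_adapter``, ``too_short``, ``too_long``.
    Reads with no adapter hit are kept untrimmed if within the length window
    unless ``strict_adapter`` is set (the trimmer cannot prove read-through).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if match_prefix_len > len(adapter):
        raise ValueError("match_prefix_len exceeds adapter length")
    seq = normalize_seq(read)
    if not seq:
        return None, "empty"
    probe = normalize_seq(adapter)[:match_prefix_len]
    pos = seq.find(probe)
    if pos >= 0:
        seq = seq[:pos]
    elif strict_adapter:
        return None, "no_adapter"
    if drop_n and "N" in seq:
        return None, "contains_n"
    if len(seq) < min_len:
        return None, "too_short"
    if max_len is not None and len(seq) > max_len:
        return None, "too_long"
    return seq, "kept"


def trim_reads(
    reads: list[str], adapter: str, profile: TrimProfile | str
) -> tuple[list[str], dict[str, int]]:
    """Apply a trimming profile to a read list.

    Returns the kept sequences and a discard report keyed by reason; the
    report itemizes every read so counts are conserved:
    ``len(reads) == len(kept) + sum(discards.values())``.
    """
    if isinstance(profile, str):
        profile = TRIM_PROFILES[profile]
    kept: list[str] = []
    discards: Counter[str] = Counter()
    for read in reads:
        seq, reason = trim_adapter(
            read,
            adapter,
            min_len=profile.min_len,
            max_len=profile.max_len,
            match_prefix_len=profile.match_prefix_len,
            drop_n=profile.drop_n,
            strict_adapter=profile.strict_adapter,
        )
        if seq is None:
            discards[reason] += 1
        else:
            kept.append(seq)
    return kept, dict(discards)


def collapse_reads(reads: list[str], sample_code: str) -> list[CollapsedRead]:
    """Combine identical sequences from one sample into single records.

    Ids take the form ``NNN_#_x#``: the alphabetic sample code, a unique
    integer (first-occurrence order) and the multiplicity.
    """
    if not sample_code.isalpha():
        raise ValueError(f"sample_code must be alphabetic, got {sample_code!r}")
    counts: Counter[str] = Counter(normalize_seq(r) for r in reads)
    return [
        CollapsedRead(id=f"{sample_code}_{i}_x{n}", sequence=seq, count=n)
        for i, (seq, n) in enumerate(counts.items(), start=1)
    ]


def find_occurrences(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions of needle."""
    hits: list[int] = []
    pos = haystack.find(needle)
    while pos >= 0:
        hits.append(pos + 1)
        pos = haystack.find(needle, pos + 1)
    return hits


def map_exact(
    sequences: list[str], precursors: list[PrecursorRecord]
) -> dict[str, list[Locus]]:
    """Exact-match each sequence against every precursor (no mismatch/gap).

    Every occurrence across all precursors is reported with 1-based
    inclusive coordinates; a sequence absent everywhere maps to ``[]``.
    """
    out: dict[str, list[Locus]] = {}
    for seq in sequences:
        norm = normalize_seq(seq)
        if norm in out:
            continue
        loci = [
            Locus(prec.name, start, start + len(norm) - 1)
            for prec in precursors
            for start in find_occurrences(norm, prec.sequence)
        ]
        out[norm] = loci
    return out


def _window_arm(prec: PrecursorRecord, start: int) -> str:
    """Arm of a locus with no mature overlap: hairpin-midpoint rule."""
    return "5p" if start <= len(prec.sequence) / 2 else "3p"


def classify_locus(
    prec: PrecursorRecord,
    start: int,
    end: int,
    *,
    start_tol: int = 3,
    min_overlap: float = 0.75,
) -> tuple[list[str], str]:
    """Mature names associated with one locus, and the locus arm.

    A locus is associated with a mature window when its start lies within
    ``start_tol`` nt of the window start and it covers at least
    ``min_overlap`` of the window — the operational isomiR tolerance for
    "aligned with an expected mature sequence".  No association yields an
    empty list (the caller falls back to ``<precursor>-pre``).
    """
    matures: list[str] = []
    arm = ""
    for w in prec.mature_windows:
        overlap = min(end, w.end) - max(start, w.start) + 1
        if abs(start - w.start) <= start_tol and overlap >= min_overlap * (w.end - w.start + 1):
            matures.append(w.name)
            arm = w.arm
    if not arm:
        arm = _window_arm(prec, start)
    return matures, arm


def assign_isomir(
    sequence: str,
    loci: list[Locus],
    precursors: dict[str, PrecursorRecord],
    *,
    count: int = 1,
    species_tier: str = "",
    start_tol: int = 3,
    min_overlap: float = 0.75,
) -> list[IsomiRAssignment]:
    """Name one mapped sequence and build one assignment row per locus.

    The composite ``assigned_mature`` is the lexicographically sorted,
    deduplicated union of per-locus identities (mature names where a locus
    overlaps a mature window, ``<precursor>-pre`` otherwise), so it is
    invariant to precursor input order.  Counts are left undivided; apply
    :func:`divide_multilocus_counts` for fractional per-locus counts.
    """
    if not loci:
        raise ValueError("assign_isomir requires at least one locus")
    identities: set[str] = set()
    rows: list[IsomiRAssignment] = []
    per_locus: list[tuple[Locus, str]] = []
    for locus in loci:
        prec = precursors[locus.precursor]
        matures, arm = classify_locus(
            prec, locus.start, locus.end, start_tol=start_tol, min_overlap=min_overlap
        )
        identities.update(matures if matures else [f"{prec.name}-pre"])
        per_locus.append((locus, arm))
    composite = ";".join(sorted(identities))
    for locus, arm in per_locus:
        rows.append(
            IsomiRAssignment(
                sequence=normalize_seq(sequence),
                isomir_name=f"{locus.precursor}_{arm}_{locus.start}_{locus.end}",
                assigned_mature=composite,
                species_tier=species_tier,
                count=float(count),
                n_loci=len(loci),
            )
        )
    return rows


def cross_species_assign(
    collapsed: list[CollapsedRead],
    tiered_precursors: list[tuple[str, list[PrecursorRecord]]],
    *,
    start_tol: int = 3,
    min_overlap: float = 0.75,
) -> tuple[list[IsomiRAssignment], list[CollapsedRead]]:
    """Assign sequences against species tiers in order; first hit wins.

    Each collapsed read is searched in tier order (e.g. rat, mouse, human,
    C. elegans) and assigned at the first tier yielding at least one exact
    locus, with that tier recorded.  Reads unmatched at every tier are
    returned as unidentified.
    """
    if not tiered_precursors:
        raise ValueError("at least one species tier required")
    assignments: list[IsomiRAssignment] = []
    pending = list(collapsed)
    for species, precs in tiered_precursors:
        if not pending:
            break
        index = {p.name: p for p in precs}
        hits = map_exact([r.sequence for r in pending], precs)
        still: list[CollapsedRead] = []
        for read in pending:
            loci = hits[normalize_seq(read.sequence)]
            if loci:
                assignments.extend(
                    assign_isomir(
                        read.sequence,
                        loci,
                        index,
                        count=read.count,
                        species_tier=species,
                        start_tol=start_tol,
                        min_overlap=min_overlap,
                    )
                )
            else:
                still.append(read)
        pending = still
    return assignments, pending


def divide_multilocus_counts(
    assignments: list[IsomiRAssignment],
) -> list[IsomiRAssignment]:
    """Divide each sequence's total count evenly across its mapped loci.

    Per-locus count = total / n_loci (fractions allowed); summing the
    divided counts over loci restores the original count exactly.
    """
    out: list[IsomiRAssignment] = []
    for a in assignments:
        if a.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        out.append(replace(a, count=a.count / a.n_loci))
    return out


def assignments_frame(assignments: list[IsomiRAssignment]) -> pd.DataFrame:
    """Tabulate assignments (sequence, isomir_name, assigned_mature, ...)."""
    return pd.DataFrame(
        [
            {
                "sequence": a.sequence,
                "isomir_name": a.isomir_name,
                "assigned_mature": a.assigned_mature,
                "species_tier": a.species_tier,
                "count": a.count,
                "n_loci": a.n_loci,
            }
            for a in assignments
        ],
        columns=["sequence", "isomir_name", "assigned_mature", "species_tier", "count", "n_loci"],
    )


def isomir_fraction_of_mature(table: pd.DataFrame) -> pd.DataFrame:
    """Express each isomiR as a percentage of its parent mature total.

    ``table`` needs columns ``assigned_mature``, ``isomir_name``, ``count``.
    Percentages within a parent sum to 100 (within rounding).  Rows whose
    parent total is zero are flagged ``undefined`` rather than reported as 0.
    """
    required = {"assigned_mature", "isomir_name", "count"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    grouped = table.groupby(["assigned_mature", "isomir_name"], sort=False)["count"].sum()
    df = grouped.reset_index()
    totals = df.groupby("assigned_mature")["count"].transform("sum")
    df["undefined"] = totals <= 0
    with pd.option_context("mode.chained_assignment", None):
        df["percent_of_mature"] = 100.0 * df["count"] / totals.where(totals > 0)
    return df


def process_sample(
    raw_reads: list[str],
    sample_code: str,
    adapter: str,
    tiered_precursors: list[tuple[str, list[PrecursorRecord]]],
    profile: TrimProfile | str = "maastricht",
    *,
    start_tol: int = 3,
    min_overlap: float = 0.75,
) -> tuple[pd.DataFrame, dict[str, int], list[CollapsedRead]]:
    """Full per-sample pipeline: trim -> collapse -> tiered assign -> divide.

    Returns the assignment table (fractional counts), the discard report and
    the unidentified collapsed reads.
    """
    kept, discards = trim_reads(raw_reads, adapter, profile)
    collapsed = collapse_reads(kept, sample_code)
    assigned, unidentified = cross_species_assign(
        collapsed, tiered_precursors, start_tol=start_tol, min_overlap=min_overlap
    )
    divided = divide_multilocus_counts(assigned)
    return assignments_frame(divided), discards, unidentified
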