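"""Shared fixtures: a hand-built precursor set covering every isomiR
naming branch, and small planted atlases."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from miratlas.organs import DEFAULT_ORGAN_MAP, DEFAULT_TISSUES
from miratlas.quantify import AtlasCounts
from miratlas.reads import MatureWindow, PrecursorRecord
from miratlas.synthetic import atlas_samples

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _hairpin_with(rng, planted: dict[int, str], length: int) -> str:
    """Random hairpin with given segments planted at 1-based positions."""
    seq = list(_rand_seq(rng, length))
    for start, segment in planted.items():
        seq[start - 1 : start - 1 + len(segment)] = list(segment)
    return "".join(seq)


@pytest.fixture(scope="session")
def branch_precursors():
    """Ten precursors exercising every assignment branch.

    Returns (rat_tier, mouse_tier, planted) where ``planted`` maps branch
    names to the sequences that trigger them.
    """
    rng = np.random.default_rng(20160830)
    let7 = _rand_seq(rng, 22)          # shared 5p mature of let-7a / let-7f
    multi = _rand_seq(rng, 20)         # planted at 2 loci in 2 precursors
    shared_rm = _rand_seq(rng, 22)     # in both rat and mouse tiers
    mouse_only = _rand_seq(rng, 22)    # only in the mouse tier

    let7a = PrecursorRecord(
        "let-7a", "rat", _hairpin_with(rng, {6: let7}, 72),
        [MatureWindow("let-7a-5p", "5p", 6, 27)],
    )
    let7f = PrecursorRecord(
        "let-7f", "rat", _hairpin_with(rng, {4: let7}, 70),
        [MatureWindow("let-7f-5p", "5p", 4, 25)],
    )
    mir134 = PrecursorRecord(
        "mir-134", "rat", _rand_seq(rng, 70),
        [MatureWindow("miR-134-5p", "5p", 5, 26), MatureWindow("miR-134-3p", "3p", 45, 66)],
    )
    mir127 = PrecursorRecord(
        "miR-127", "rat", _rand_seq(rng, 80),
        [MatureWindow("miR-127-5p", "5p", 6, 27), MatureWindow("miR-127-3p", "3p", 57, 78)],
    )
    mir500 = PrecursorRecord(
        "miR-500", "rat", _hairpin_with(rng, {10: multi}, 68),
        [MatureWindow("miR-500-5p", "5p", 10, 29)],
    )
    mir501 = PrecursorRecord(
        "miR-501", "rat", _hairpin_with(rng, {40: multi}, 66),
        [MatureWindow("miR-501-3p", "3p", 40, 59)],
    )
    mir502_rat = PrecursorRecord(
        "rno-mir-502", "rat", _hairpin_with(rng, {7: shared_rm}, 64),
        [MatureWindow("rno-miR-502-5p", "5p", 7, 28)],
    )
    mir502_mouse = PrecursorRecord(
        "mmu-mir-502", "mouse", _hairpin_with(rng, {7: shared_rm}, 64),
        [MatureWindow("mmu-miR-502-5p", "5p", 7, 28)],
    )
    mir600_mouse = PrecursorRecord(
        "mmu-mir-600", "mouse", _hairpin_with(rng, {5: mouse_only}, 66),
        [MatureWindow("mmu-miR-600-5p", "5p", 5, 26)],
    )
    filler = PrecursorRecord(
        "mir-999", "rat", _rand_seq(rng, 60),
        [MatureWindow("miR-999-5p", "5p", 3, 24)],
    )

    rat = [let7a, let7f, mir134, mir127, mir500, mir501, mir502_rat, filler]
    mouse = [mir502_mouse, mir600_mouse]

    planted = {
        "composite": let7,
        "pre": mir134.sequence[30:52],           # inside mir-134, off both arms
        "named_isomir": mir127.sequence[56:78],  # exactly miR-127_3p_57_78
        "multilocus": multi,
        "rat_and_mouse": shared_rm,
        "mouse_only": mouse_only,
        "nowhere": "ACGT" * 6,
    }
    # planted sequences must occur only where intended
    all_seqs = {p.name: p.sequence for p in rat + mouse}
    assert sum(planted["composite"] in s for s in all_seqs.values()) == 2
    assert sum(planted["multilocus"] in s for s in all_seqs.values()) == 2
    assert sum(planted["mouse_only"] in s for s in all_seqs.values()) == 1
    assert all(planted["nowhere"] not in s for s in all_seqs.values())
    return rat, mouse, planted


def random_atlas(rng: np.random.Generator, n_mirnas: int = 50, max_count: int = 6) -> AtlasCounts:
    """A small random atlas over the default 215-sample panel."""
    samples = atlas_samples(tissues=DEFAULT_TISSUES, organ_map=DEFAULT_ORGAN_MAP)
    counts = pd.DataFrame(
        rng.integers(0, max_count, size=(n_mirnas, len(samples))),
        index=[f"miR-{i:03d}" for i in range(n_mirnas)],
        columns=samples.index,
    )
    return AtlasCounts(counts=counts, samples=samples)
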