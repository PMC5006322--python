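"""Read processing: trimming, collapsing, exact mapping, isomiR naming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from miratlas.reads import (
    IsomiRAssignment,
    Locus,
    assign_isomir,
    collapse_reads,
    cross_species_assign,
    divide_multilocus_counts,
    isomir_fraction_of_mature,
    map_exact,
    trim_adapter,
    trim_reads,
)
from tests.conftest import ADAPTER, _rand_seq


class TestTrimAdapter:
    def test_truncates_at_adapter_prefix_and_keeps_in_window(self):
        read = "ACGTACGTACGTACGT" + ADAPTER[:8] + "AC"
        seq, reason = trim_adapter(read, ADAPTER, min_len=16, max_len=35)
        assert (seq, reason) == ("ACGTACGTACGTACGT", "kept")

    def test_trimmed_below_window_is_discarded(self):
        read = "ACGTACGTACGTACG" + ADAPTER[:8]  # 15 nt insert
        seq, reason = trim_adapter(read, ADAPTER, min_len=16, max_len=35)
        assert seq is None and reason == "too_short"

    def test_no_adapter_kept_when_in_window_else_discarded(self):
        assert trim_adapter("A" * 20, ADAPTER, min_len=16, max_len=35)[0] == "A" * 20
        assert trim_adapter("A" * 40, ADAPTER, min_len=16, max_len=35)[1] == "too_long"
        assert trim_adapter("A" * 20, ADAPTER, min_len=16, max_len=35,
                            strict_adapter=True)[1] == "no_adapter"

    def test_ambiguous_bases_discarded_when_requested(self):
        read = "ACGTNCGTACGTACGTAA" + ADAPTER[:10]
        assert trim_adapter(read, ADAPTER, min_len=17, drop_n=True)[1] == "contains_n"
        assert trim_adapter(read, ADAPTER, min_len=16, max_len=35)[1] == "kept"

    def test_empty_read_is_discard_not_error(self):
        assert trim_adapter("", ADAPTER, min_len=16)[1] == "empty"

    def test_discard_report_conserves_reads(self):
        rng = np.random.default_rng(0)
        reads = [_rand_seq(rng, int(rng.integers(10, 45))) for _ in range(300)]
        kept, discards = trim_reads(reads, ADAPTER, "maastricht")
        assert len(kept) + sum(discards.values()) == len(reads)


class TestCollapseReads:
    def test_worked_example(self):
        s1, s2 = "ACGTACGTACGTACGTAC", "TTTTACGTACGTACGTAC"
        out = collapse_reads([s1, s1, s1, s2], "LIV")
        assert {(r.id, r.sequence, r.count) for r in out} == {
            ("LIV_1_x3", s1, 3),
            ("LIV_2_x1", s2, 1),
        }

    def test_empty_input(self):
        assert collapse_reads([], "LIV") == []

    def test_nonalphabetic_code_rejected(self):
        with pytest.raises(ValueError):
            collapse_reads(["ACGT"], "L1V")

    @given(st.lists(st.sampled_from(["ACGTACGT", "ACGTACGA", "TTTTACGT"]), max_size=60))
    def test_count_conservation(self, reads):
        out = collapse_reads(reads, "LIV")
        assert sum(r.count for r in out) == len(reads)
        assert len({r.sequence for r in out}) == len(out)


class TestMapExact:
    def test_mature_window_maps_to_its_coordinates(self, branch_precursors):
        rat, _, _ = branch_precursors
        prec = rat[3]  # miR-127
        w = prec.mature_windows[1]
        seq = prec.mature_sequence(w)
        loci = map_exact([seq], rat)[seq]
        assert Locus("miR-127", w.start, w.end) in loci

    def test_absent_sequence_maps_nowhere(self, branch_precursors):
        rat, _, planted = branch_precursors
        assert map_exact([planted["nowhere"]], rat)[planted["nowhere"]] == []

    def test_equals_bruteforce_scan(self, branch_precursors):
        rat, mouse, planted = branch_precursors
        precs = rat + mouse
        rng = np.random.default_rng(1)
        seqs = [_rand_seq(rng, int(rng.integers(16, 26))) for _ in range(60)]
        seqs += [p.sequence[5:27] for p in precs] + list(planted.values())
        got = map_exact(seqs, precs)
        for seq in {s.upper().replace("U", "T") for s in seqs}:
            expect = [
                Locus(p.name, i + 1, i + len(seq))
                for p in precs
                for i in range(len(p.sequence) - len(seq) + 1)
                if p.sequence[i : i + len(seq)] == seq
            ]
            assert got[seq] == expect


class TestAssignIsomir:
    def test_composite_name_for_shared_mature(self, branch_precursors):
        rat, _, planted = branch_precursors
        index = {p.name: p for p in rat}
        seq = planted["composite"]
        loci = map_exact([seq], rat)[seq]
        rows = assign_isomir(seq, loci, index)
        assert all(r.assigned_mature == "let-7a-5p;let-7f-5p" for r in rows)

    def test_pre_fallback_outside_mature_windows(self, branch_precursors):
        rat, _, planted = branch_precursors
        index = {p.name: p for p in rat}
        seq = planted["pre"]
        loci = map_exact([seq], rat)[seq]
        rows = assign_isomir(seq, loci, index)
        assert rows[0].assigned_mature == "mir-134-pre"

    def test_isomir_name_records_precursor_arm_and_coordinates(self, branch_precursors):
        rat, _, planted = branch_precursors
        index = {p.name: p for p in rat}
        seq = planted["named_isomir"]
        loci = map_exact([seq], rat)[seq]
        rows = assign_isomir(seq, loci, index)
        assert rows[0].isomir_name == "miR-127_3p_57_78"
        assert rows[0].assigned_mature == "miR-127-3p"

    def test_composite_invariant_to_precursor_order(self, branch_precursors):
        rat, _, planted = branch_precursors
        seq = planted["multilocus"]
        for order in (rat, rat[::-1]):
            index = {p.name: p for p in order}
            loci = map_exact([seq], order)[seq]
            rows = assign_isomir(seq, loci, index)
            assert rows[0].assigned_mature == "miR-500-5p;miR-501-3p"

    def test_zero_loci_is_an_error(self, branch_precursors):
        rat, _, _ = branch_precursors
        with pytest.raises(ValueError):
            assign_isomir("ACGT" * 5, [], {p.name: p for p in rat})


class TestCrossSpeciesAssign:
    def test_first_tier_wins_and_tier_recorded(self, branch_precursors):
        rat, mouse, planted = branch_precursors
        collapsed = collapse_reads(
            [planted["rat_and_mouse"], planted["mouse_only"], planted["nowhere"]], "ABC"
        )
        assigned, unidentified = cross_species_assign(
            collapsed, [("rat", rat), ("mouse", mouse)]
        )
        tiers = {a.sequence: a.species_tier for a in assigned}
        assert tiers[planted["rat_and_mouse"]] == "rat"
        assert tiers[planted["mouse_only"]] == "mouse"
        assert [u.sequence for u in unidentified] == [planted["nowhere"]]


class TestMultilocusDivision:
    def test_worked_examples(self):
        row = IsomiRAssignment("A" * 20, "x_5p_1_20", "x-5p", "rat", 12.0, 3)
        assert divide_multilocus_counts([row])[0].count == 4.0
        row = IsomiRAssignment("A" * 20, "x_5p_1_20", "x-5p", "rat", 10.0, 4)
        assert divide_multilocus_counts([row])[0].count == 2.5

    def test_division_conserves_counts(self, branch_precursors):
        rat, mouse, planted = branch_precursors
        rng = np.random.default_rng(2)
        reads = []
        for seq in (planted["composite"], planted["multilocus"], planted["named_isomir"]):
            reads += [seq] * int(rng.integers(1, 30))
        collapsed = collapse_reads(reads, "XYZ")
        assigned, _ = cross_species_assign(collapsed, [("rat", rat), ("mouse", mouse)])
        divided = divide_multilocus_counts(assigned)
        assert sum(a.count for a in divided) == pytest.approx(len(reads))
        for a in divided:
            assert a.count * a.n_loci == pytest.approx(
                next(c.count for c in collapsed if c.sequence == a.sequence)
            )


class TestIsomirFraction:
    def test_worked_examples(self):
        table = pd.DataFrame(
            {
                "assigned_mature": ["p", "p", "q"],
                "isomir_name": ["a", "b", "c"],
                "count": [75.0, 25.0, 7.0],
            }
        )
        out = isomir_fraction_of_mature(table).set_index("isomir_name")
        assert out.loc["a", "percent_of_mature"] == pytest.approx(75.0)
        assert out.loc["b", "percent_of_mature"] == pytest.approx(25.0)
        assert out.loc["c", "percent_of_mature"] == pytest.approx(100.0)

    def test_per_parent_sums_to_100(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {
                "assigned_mature": rng.choice(["p", "q", "r"], size=60),
                "isomir_name": [f"iso{i}" for i in range(60)],
                "count": rng.integers(1, 500, size=60).astype(float),
            }
        )
        out = isomir_fraction_of_mature(table)
        sums = out.groupby("assigned_mature")["percent_of_mature"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_zero_parent_flagged_not_zero(self):
        table = pd.DataFrame(
            {"assigned_mature": ["z"], "isomir_name": ["a"], "count": [0.0]}
        )
        out = isomir_fraction_of_mature(table)
        assert bool(out["undefined"].iloc[0])
        assert np.isnan(out["percent_of_mature"].iloc[0])
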