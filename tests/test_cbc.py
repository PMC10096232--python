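from itertools import product

import pytest

from its_structphylo.cbc import (cbc_matrix, classify_pair_change,
                                 classify_unpaired_change, events_to_dataframe,
                                 tabulate_events)
from its_structphylo.synthdata import (SynthConfig, generate_family,
                                       make_toy_cbc_set, recover_planted_counts)

_ALLOWED = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def oracle_classify(a, b):
    """Independently coded truth table for pair-state changes."""
    if a == b:
        return "silent"
    a_ok, b_ok = a in _ALLOWED, b in _ALLOWED
    if not (a_ok and b_ok):
        return "Nst"
    left_changed = a[0] != b[0]
    right_changed = a[1] != b[1]
    if left_changed and right_changed:
        return "CBC"
    return "hCBC"


class TestPairClassifier:
    def test_agrees_with_256_case_truth_table(self):
        states = list(product("ACGU", repeat=2))
        for a in states:
            for b in states:
                assert classify_pair_change(a, b) == oracle_classify(a, b), (a, b)

    def test_symmetric(self):
        states = list(product("ACGU", repeat=2))
        for a in states:
            for b in states:
                assert classify_pair_change(a, b) == classify_pair_change(b, a)

    @pytest.mark.parametrize("a,b,expected", [
        (("U", "G"), ("A", "U"), "CBC"),      # wobble to Watson-Crick, both partners
        (("U", "A"), ("U", "G"), "hCBC"),     # one partner, pairing kept
        (("A", "U"), ("A", "U"), "silent"),
        (("U", "A"), ("C", "A"), "Nst"),      # C:A is not an allowed pair
        (("G", "C"), ("A", "G"), "Nst"),      # double change to a non-pair: one Nst
    ])
    def test_printed_transitions(self, a, b, expected):
        assert classify_pair_change(a, b) == expected

    def test_lenient_mode_admits_weak_ca_pair(self):
        assert classify_pair_change(("U", "A"), ("C", "A"), lenient=True) == "hCBC"

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            classify_pair_change(("N", "A"), ("U", "A"))


class TestUnpairedClassifier:
    def test_silent_and_nst(self):
        assert classify_unpaired_change("A", "A") == "silent"
        assert classify_unpaired_change("A", "G") == "Nst"


class TestToyExemplars:
    def test_cego_vs_taverniera_is_cbc(self, toy_cbc):
        aln, groups = toy_cbc
        events, _ = tabulate_events(aln, groups=groups, mode="taxon_pairwise")
        klass = {frozenset((e.a, e.b)): e.klass for e in events
                 if e.aligned_col == 38}
        assert klass[frozenset(("CEGO", "Taverniera"))] == "CBC"

    def test_pabulare_vs_cego_is_hcbc(self, toy_cbc):
        aln, groups = toy_cbc
        events, _ = tabulate_events(aln, groups=groups, mode="taxon_pairwise")
        klass = {frozenset((e.a, e.b)): e.klass for e in events
                 if e.aligned_col == 38}
        assert klass[frozenset(("H_pabulare", "CEGO"))] == "hCBC"

    def test_unprinted_columns_silent(self, toy_cbc):
        aln, groups = toy_cbc
        events, _ = tabulate_events(aln, groups=groups, mode="taxon_pairwise")
        printed = {38, 46, 84, 96, 147}
        assert {e.aligned_col for e in events} <= printed

    def test_alhagi_cbc_at_148_186(self, toy_cbc):
        aln, groups = toy_cbc
        events, _ = tabulate_events(aln, groups=groups, mode="taxon_pairwise")
        ev = [e for e in events if e.aligned_col == 147
              and frozenset((e.a, e.b)) == frozenset(("Alhagi", "CEGO"))]
        assert len(ev) == 1 and ev[0].klass == "CBC"
        assert ev[0].partner_col == 185

    def test_identical_records_no_events(self, toy_cbc):
        aln, groups = toy_cbc
        sub_taxa = ["CEGO", "clade_S"]  # identical exemplars
        from its_structphylo.seqstruct_align import SeqStructAlignment
        sub = SeqStructAlignment(taxa=sub_taxa,
                                 rows={t: aln.rows[t] for t in sub_taxa},
                                 records={t: aln.records[t] for t in sub_taxa})
        events, _ = tabulate_events(sub, groups=groups)
        assert events == []


class TestGroupLevel:
    def test_group_consensus_states_classified(self, toy_cbc):
        aln, groups = toy_cbc
        events, tables = tabulate_events(aln, groups=groups, mode="group_level")
        cbc_pairs = {frozenset((e.a, e.b)) for e in events
                     if e.klass == "CBC" and e.aligned_col == 38}
        assert frozenset(("CEGO", "Taverniera")) in cbc_pairs
        assert frozenset(("S", "Taverniera")) in cbc_pairs

    def test_polymorphic_groups_excluded_and_listed(self, toy_cbc):
        aln, groups = toy_cbc
        # group M contains clade_M (C:G), H_pabulare (U:G), H_elymaiticum (C:G)
        # at column 38 -> polymorphic under unanimity threshold
        events, tables = tabulate_events(aln, groups=groups, mode="group_level")
        exc = [e for e in tables["exceptions"] if e[0] == "M" and 38 in e[1]]
        assert exc and "H_pabulare" in exc[0][3]
        assert not any(e.aligned_col == 38 and "M" in (e.a, e.b) for e in events)

    def test_unmapped_taxon_rejected(self, toy_cbc):
        aln, groups = toy_cbc
        from its_structphylo.io_formats import GroupMap
        bad = GroupMap({t: g for t, g in groups.assignments.items() if t != "Alhagi"})
        with pytest.raises(ValueError, match="Alhagi"):
            tabulate_events(aln, groups=bad, mode="group_level")


class TestPlantedRecovery:
    def test_recovered_counts_equal_planted_counts(self):
        for seed in range(10):
            _, truth = generate_family(SynthConfig(n_taxa=6, seed=seed))
            assert recover_planted_counts(truth) == truth.planted_counts(), seed

    def test_event_classes_partition_differences(self, small_family):
        """Every aligned difference between two taxa is accounted for by
        exactly one CBC/hCBC/Nst/indel event."""
        _, truth = small_family
        aln = truth.alignment
        a, b = aln.taxa[0], aln.taxa[1]
        from its_structphylo.seqstruct_align import SeqStructAlignment
        sub = SeqStructAlignment(taxa=[a, b],
                                 rows={a: aln.rows[a], b: aln.rows[b]},
                                 records={a: aln.records[a], b: aln.records[b]})
        events, _ = tabulate_events(sub, paired_cols=[
            pq for pq in truth.paired_cols])
        paired_set = {c for pq in truth.paired_cols for c in pq}
        n_diff = 0
        for c in range(aln.width):
            sa, sb = aln.rows[a][c], aln.rows[b][c]
            ba = sa[0] if sa else None
            bb = sb[0] if sb else None
            if ba != bb:
                n_diff += 1
        # each paired-site event covers a column pair; count event columns
        covered = 0
        for ev in events:
            cols = (ev.aligned_col,) if ev.partner_col is None else (ev.aligned_col,
                                                                     ev.partner_col)
            for c in cols:
                sa, sb = aln.rows[a][c], aln.rows[b][c]
                ba = sa[0] if sa else None
                bb = sb[0] if sb else None
                if ba != bb:
                    covered += 1
        assert covered == n_diff


class TestCbcMatrix:
    def test_zero_without_events(self, toy_cbc):
        aln, _ = toy_cbc
        m = cbc_matrix([], aln.taxa)
        assert (m.values == 0).all()

    def test_symmetric_counts(self, toy_cbc):
        aln, groups = toy_cbc
        events, _ = tabulate_events(aln, groups=groups)
        m = cbc_matrix(events, aln.taxa)
        assert (m.values == m.values.T).all()
        assert (m.values.diagonal() == 0).all()
        assert m.loc["Alhagi", "CEGO"] >= 1

    def test_catalog_is_one_based(self, toy_cbc):
        aln, groups = toy_cbc
        events, _ = tabulate_events(aln, groups=groups)
        df = events_to_dataframe(events)
        row = df[(df.aligned_col == 39)].iloc[0]
        assert row.partner_col == 70  # printed coordinate convention
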