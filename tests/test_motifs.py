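import random
import re

import pytest

from its_structphylo.annotation import annotate_regions, default_anchors
from its_structphylo.io_formats import IUPAC_CODES, Region
from its_structphylo.motifs import (DEFAULT_GC_BOUNDS, DEFAULT_LEN_BOUNDS,
                                    PACKAGED_MOTIFS, TwoBlockPattern, scan_motif,
                                    motif_ii_distances, screen_pseudogene)
from its_structphylo.synthdata import SynthConfig, generate_family
from its_structphylo import templates


def _iupac_regex(pattern):
    return re.compile("".join(
        f"[{''.join(sorted(IUPAC_CODES[c]))}]" for c in pattern))


class TestScanMotif:
    def test_degenerate_position_matches(self):
        hits = scan_motif("AAGUGCCAA", "GYGCC")
        assert len(hits) == 1 and hits[0].start == 2

    def test_overlapping_hits_in_printed_uggu_region(self):
        # the printed motif-region string carries two GGU occurrences
        hits = scan_motif("GAUCGACGGUGGUUG", "GGU")
        assert [h.start for h in hits] == [7, 10]

    def test_absent_pattern_empty(self):
        assert scan_motif("AAAAAA", "GGCGC") == []

    def test_two_block_pattern_reports_spacer(self):
        hits = scan_motif("AA" + "GGCGC" + "AUCG" + "GUGCCAAGGAA" + "AA",
                          PACKAGED_MOTIFS["ITS1_core"])
        assert len(hits) == 1 and hits[0].spacer_len == 4
        assert hits[0].start == 2 and hits[0].end == 2 + 5 + 4 + 11

    def test_mismatch_budget(self):
        m1 = templates.MOTIF_5_8S_I
        mutated = "A" + m1[1:]
        assert scan_motif(mutated, m1, 0) == []
        hits = scan_motif(mutated, m1, 1)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif("ACGU", "AXC")

    def test_equals_regex_oracle_on_random_sequences(self):
        rng = random.Random(31)
        patterns = [p for p in (templates.MOTIF_5_8S_I, templates.MOTIF_5_8S_II,
                                templates.MOTIF_5_8S_III, "GYGCCAAGGAA", "CAUAU",
                                "GGCGC") ]
        for _ in range(1000):
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randrange(20, 80)))
            for pat in patterns:
                got = [h.start for h in scan_motif(seq, pat)]
                rx = _iupac_regex(pat)
                expected = [m.start() for m in re.finditer(
                    f"(?=({rx.pattern}))", seq)]
                assert got == expected, (seq, pat)


class TestPseudogeneScreen:
    def _record_and_annotation(self, seed=0, **kw):
        recs, truth = generate_family(SynthConfig(n_taxa=2, seed=seed, **kw))
        rec = recs[0]
        ann = annotate_regions(rec, default_anchors())
        return rec, ann

    def test_generated_records_pass(self):
        rec, ann = self._record_and_annotation()
        v = screen_pseudogene(rec, ann)
        assert v.passed and v.reasons == []

    def test_ablated_motif_fails_with_reason(self):
        rec, ann = self._record_and_annotation()
        s, _ = ann.intervals[Region.FIVE_EIGHT_S]
        seq = list(rec.seq)
        for k in range(3):  # 3 substitutions in Motif I, budget 1
            seq[s + k] = {"C": "G", "G": "C", "A": "U", "U": "A"}[seq[s + k]]
        mutated = rec.with_(seq="".join(seq), pairs=frozenset())
        v = screen_pseudogene(mutated, ann, motif_budget=1)
        assert not v.passed
        assert any("Motif I" in r for r in v.reasons)

    def test_length_bound_violation_reported(self):
        rec, ann = self._record_and_annotation()
        bounds = dict(DEFAULT_LEN_BOUNDS)
        bounds[Region.FIVE_EIGHT_S] = (162, 162)  # packaged root 5.8S is 161 nt
        v = screen_pseudogene(rec, ann, len_bounds=bounds)
        assert not v.passed
        assert any("5.8S length out of range" in r for r in v.reasons)

    def test_monotone_in_bounds(self):
        """Relaxing any bound never turns a pass into a fail."""
        rec, ann = self._record_and_annotation()
        tight_gc = {r: (0.50, 0.52) for r in DEFAULT_GC_BOUNDS}
        v_tight = screen_pseudogene(rec, ann, gc_bounds=tight_gc)
        loose_gc = {r: (0.0, 1.0) for r in DEFAULT_GC_BOUNDS}
        v_loose = screen_pseudogene(rec, ann, gc_bounds=loose_gc)
        if v_tight.passed:
            assert v_loose.passed

    def test_pseudogene_rate_flags_and_fails(self):
        recs, truth = generate_family(SynthConfig(n_taxa=6, seed=4, pseudogene_rate=1.0))
        assert all(truth.pseudogene_flags.values())
        for rec in recs:
            ann = annotate_regions(rec, default_anchors())
            assert not screen_pseudogene(rec, ann).passed


class TestMotifIIDistance:
    def test_both_conventions_reported(self):
        tpl = templates.five8s_template()
        d = motif_ii_distances(tpl.seq)
        assert d["from_aagaa_start"] - d["from_aagaa_end"] == 5
        assert d["from_aagaa_end"] == 25  # generator layout convention
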