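import pytest

from its_structphylo.annotation import (Anchor, AnchorSet, UnannotatableError,
                                        annotate_regions, default_anchors,
                                        harmonize_boundaries)
from its_structphylo.io_formats import Region, RegionAnnotation, SeqStructRecord
from its_structphylo.synthdata import SynthConfig, generate_family
from its_structphylo import templates


class TestAnnotateRegions:
    def test_recovers_truth_boundaries_across_seeds(self):
        for seed in range(20):
            recs, truth = generate_family(SynthConfig(n_taxa=4, seed=seed))
            for rec in recs:
                ann = annotate_regions(rec, default_anchors())
                for reg in (Region.ITS1, Region.FIVE_EIGHT_S, Region.ITS2):
                    assert ann.intervals[reg] == truth.intervals[rec.id][reg], \
                        (seed, rec.id, reg)

    def test_concatenated_regions_form_contiguous_substring(self, small_family):
        recs, _ = small_family
        for rec in recs:
            ann = annotate_regions(rec, default_anchors())
            joined = "".join(ann.subsequence(rec.seq, r)
                             for r in (Region.ITS1, Region.FIVE_EIGHT_S, Region.ITS2))
            assert joined in rec.seq

    def test_mutated_boundary_anchor_flagged_unresolved(self, small_family):
        recs, truth = small_family
        rec = recs[0]
        s, e = truth.intervals[rec.id][Region.ITS2]
        seq = rec.seq[:s] + "CGUAU" + rec.seq[s + 5:]  # CAUAU -> CGUAU
        mutated = rec.with_(seq=seq, pairs=frozenset())
        ann = annotate_regions(mutated, default_anchors())
        assert "FIVE_EIGHT_S_end" in ann.unresolved
        assert Region.ITS2 not in ann.intervals

    def test_duplicate_anchor_uses_leftmost_in_window_with_warning(self, small_family):
        recs, truth = small_family
        rec = recs[0]
        s, _ = truth.intervals[rec.id][Region.ITS2]
        # plant a second exact CAUAU 10 nt downstream of the true one, inside
        # the search window
        seq = rec.seq[: s + 10] + "CAUAU" + rec.seq[s + 15:]
        doubled = rec.with_(seq=seq, pairs=frozenset())
        ann = annotate_regions(doubled, default_anchors())
        assert ann.intervals[Region.ITS2][0] == s  # leftmost hit
        assert any("CAUAU" in w or "hits" in w for w in ann.warnings)

    def test_too_short_sequence_rejected(self):
        rec = SeqStructRecord(id="s", seq="ACGU" * 20, region=Region.FULL_ITS)
        with pytest.raises(UnannotatableError, match="shorter"):
            annotate_regions(rec, default_anchors())

    def test_no_anchor_at_all_unannotatable(self):
        rec = SeqStructRecord(id="s", seq="AC" * 300, region=Region.FULL_ITS)
        with pytest.raises(UnannotatableError, match="no anchor"):
            annotate_regions(rec, default_anchors())

    def test_non_full_its_record_rejected(self):
        rec = SeqStructRecord(id="s", seq="ACGU" * 200, region=Region.ITS2)
        with pytest.raises(ValueError, match="FULL_ITS"):
            annotate_regions(rec)


class TestHarmonize:
    def _anchor_ann(self):
        return RegionAnnotation(record_id="r", intervals={
            Region.ITS1: (0, 240),
            Region.FIVE_EIGHT_S: (240, 401),
            Region.ITS2: (401, 623),
        })

    def test_external_5_8s_start_upstream_gives_positive_trim(self):
        ext = RegionAnnotation(record_id="r", intervals={
            Region.ITS1: (0, 237),
            Region.FIVE_EIGHT_S: (237, 401),  # starts 3 nt upstream
            Region.ITS2: (401, 623),
        })
        out = harmonize_boundaries(self._anchor_ann(), ext)
        assert out.trims[Region.FIVE_EIGHT_S] == +3
        assert out.intervals == self._anchor_ann().intervals  # anchor-based kept

    def test_identical_annotations_zero_trims(self):
        out = harmonize_boundaries(self._anchor_ann(), self._anchor_ann())
        assert all(v == 0 for v in out.trims.values())

    def test_external_its2_end_downstream_gives_negative_trim(self):
        ext = RegionAnnotation(record_id="r", intervals={
            Region.ITS1: (0, 240),
            Region.FIVE_EIGHT_S: (240, 401),
            Region.ITS2: (401, 625),  # ends 2 nt downstream
        })
        out = harmonize_boundaries(self._anchor_ann(), ext)
        assert out.trims[Region.ITS2] == -2

    def test_different_records_rejected(self):
        other = RegionAnnotation(record_id="other", intervals={Region.ITS1: (0, 240)})
        with pytest.raises(ValueError, match="different records"):
            harmonize_boundaries(self._anchor_ann(), other)


class TestAnchorTypes:
    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            Anchor("x", "", "FIVE_EIGHT_S_start")

    def test_missing_required_anchor_rejected(self, small_family):
        recs, _ = small_family
        only_end = AnchorSet([Anchor("b", templates.BOUNDARY_5_8S_ITS2,
                                     "FIVE_EIGHT_S_end")])
        with pytest.raises(ValueError, match="anchor set"):
            annotate_regions(recs[0], only_end)
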