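import random

import pytest

from its_structphylo.io_formats import SeqStructRecord
from its_structphylo.seqstruct_align import (JointScore, align_seqstruct, decode12,
                                             encode12, paired_columns,
                                             read_paired_fasta, _gotoh,
                                             _profile_colscore)


def _random_record(rng, rid, n=None):
    n = n or rng.randrange(8, 40)
    seq = "".join(rng.choice("ACGU") for _ in range(n))
    pairs = set()
    used = set()
    for _ in range(n // 4):
        i, j = sorted(rng.sample(range(n), 2))
        if j - i < 4 or used & set(range(i, j + 1)):
            continue
        pairs.add((i, j))
        used.update(range(i, j + 1))
    return SeqStructRecord(id=rid, seq=seq, pairs=frozenset(pairs))


class TestEncoding:
    def test_example(self):
        rec = SeqStructRecord(id="r", seq="GAAAAC", pairs={(0, 5)})
        assert encode12(rec) == ["G(", "A.", "A.", "A.", "A.", "C)"]

    def test_all_unpaired(self):
        rec = SeqStructRecord(id="r", seq="ACGU")
        assert all(s[1] == "." for s in encode12(rec))

    def test_round_trip_many_random_records(self):
        rng = random.Random(5)
        for k in range(1000):
            rec = _random_record(rng, f"r{k}")
            back = decode12(encode12(rec))
            assert back.seq == rec.seq and back.pairs == rec.pairs


def _bruteforce_best_score(statesA, statesB, score):
    """Exhaustive best global alignment score with affine gaps, by explicit
    enumeration of all monotone alignment paths."""
    best = [float("-inf")]

    def rec(i, j, cur, last):
        if i == len(statesA) and j == len(statesB):
            best[0] = max(best[0], cur)
            return
        if i < len(statesA) and j < len(statesB):
            rec(i + 1, j + 1, cur + score.score(statesA[i], statesB[j]), "M")
        if i < len(statesA):
            pen = score.gap_extend if last == "X" else score.gap_open
            rec(i + 1, j, cur - pen, "X")
        if j < len(statesB):
            pen = score.gap_extend if last == "Y" else score.gap_open
            rec(i, j + 1, cur - pen, "Y")

    rec(0, 0, 0.0, "start")
    return best[0]


def _path_score(path, statesA, statesB, score):
    total = 0.0
    last = "start"
    for ia, ib in path:
        if ia is not None and ib is not None:
            total += score.score(statesA[ia], statesB[ib])
            last = "M"
        elif ia is not None:
            total -= score.gap_extend if last == "X" else score.gap_open
            last = "X"
        else:
            total -= score.gap_extend if last == "Y" else score.gap_open
            last = "Y"
    return total


class TestPairwiseDP:
    def test_dp_matches_exhaustive_oracle_on_toys(self):
        rng = random.Random(9)
        score = JointScore()
        colscore = _profile_colscore(score)
        for _ in range(25):
            a = _random_record(rng, "a", rng.randrange(3, 8))
            b = _random_record(rng, "b", rng.randrange(3, 8))
            sa, sb = encode12(a), encode12(b)
            oracle = _bruteforce_best_score(sa, sb, score)
            path = _gotoh([(s,) for s in sa], [(s,) for s in sb], colscore,
                          score.gap_open, score.gap_extend)
            assert _path_score(path, sa, sb, score) == pytest.approx(oracle)


class TestProgressive:
    def test_identical_records_align_without_gaps(self):
        a = SeqStructRecord(id="a", seq="GGGAAACCCAU", pairs={(0, 8), (1, 7)})
        b = a.with_(id="b")
        aln = align_seqstruct([a, b])
        assert aln.width == 11
        assert all(s is not None for t in aln.taxa for s in aln.rows[t])

    def test_loop_insertion_yields_single_gap_column(self):
        a = SeqStructRecord(id="a", seq="GGGAAACCCAU", pairs={(0, 8), (1, 7), (2, 6)})
        b = SeqStructRecord(id="b", seq="GGGAAAACCCAU", pairs={(0, 9), (1, 8), (2, 7)})
        aln = align_seqstruct([a, b])
        gap_cols = [c for c in range(aln.width)
                    if any(aln.rows[t][c] is None for t in aln.taxa)]
        assert len(gap_cols) == 1 and 3 <= gap_cols[0] <= 6  # inside the loop

    def test_single_record_rejected(self):
        a = SeqStructRecord(id="a", seq="GGGAAACCC", pairs={(0, 8)})
        with pytest.raises(ValueError):
            align_seqstruct([a])

    def test_order_invariance_up_to_row_permutation(self):
        rng = random.Random(13)
        recs = [_random_record(rng, f"r{k}", 20) for k in range(4)]
        aln1 = align_seqstruct(recs)
        aln2 = align_seqstruct(list(reversed(recs)))
        assert {t: aln1.rows[t] for t in aln1.taxa} == {t: aln2.rows[t] for t in aln2.taxa}

    def test_round_trip_through_paired_fasta(self, tmp_path, small_family):
        _, truth = small_family
        aln = truth.alignment
        p = tmp_path / "a.ssfasta"
        aln.write_paired_fasta(p)
        back = read_paired_fasta(p)
        assert back.taxa == aln.taxa
        assert back.base_matrix() == aln.base_matrix()


class TestPairedColumns:
    def test_unanimous_pairing_reported(self):
        recs = [SeqStructRecord(id=f"r{k}", seq="GGGAAACCCAU", pairs={(2, 9)})
                for k in range(4)]
        aln = align_seqstruct(recs)
        assert paired_columns(aln, 1.0) == [(2, 9)]

    def test_threshold_excludes_minority_pairing(self):
        paired = [SeqStructRecord(id=f"p{k}", seq="GGGAAACCCAU", pairs={(2, 9)})
                  for k in range(2)]
        unpaired = [SeqStructRecord(id=f"u{k}", seq="GGGAAACCCAU") for k in range(2)]
        aln = align_seqstruct(paired + unpaired)
        assert paired_columns(aln, 0.8) == []
        assert paired_columns(aln, 0.5) == [(2, 9)]

    def test_generated_family_truth_recovered(self, small_family):
        _, truth = small_family
        assert paired_columns(truth.alignment, 0.5) == truth.paired_cols
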