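"""Packaged synthetic ITS templates and motif constants.

The ITS2 template is a synthetic flank-extended structure embodying the
canonical eukaryote ITS2 architecture: four helices radiating from a central
loop, closed by a proximal stem formed between the 3' end of 5.8S and the 5'
end of 28S, with the conserved landmarks (UGGU on the 5' side of Helix III
near the apex, a U-U mismatch in Helix II, an AAA spacer between helices II
and III).  The 5.8S template carries the three conserved angiosperm motifs
and folds into four hairpins around one central loop.  Both are synthetic
stand-ins constructed to these published architectural constraints, not real
accessions; user-supplied templates can replace them everywhere.

All sequences are built programmatically so complementarity and nesting hold
by construction; an import-time audit asserts each diagnostic motif occurs
exactly once in the assembled root amplicon.
"""

from __future__ import annotations

import random

from .io_formats import Region, SeqStructRecord, StructSource

__all__ = [
    "MOTIF_5_8S_I",
    "MOTIF_5_8S_II",
    "MOTIF_5_8S_III",
    "BOUNDARY_5_8S_ITS2",
    "ITS1_CORE_BLOCK1",
    "ITS1_CORE_BLOCK2",
    "UGGU_VARIANTS",
    "revcomp",
    "its2_template",
    "five8s_template",
    "root_amplicon",
]

MOTIF_5_8S_I = "CGAUGAAGAACGUAGC"
MOTIF_5_8S_II = "GAAUUGCAGAAUCC"
MOTIF_5_8S_III = "UUUGAACGCA"
BOUNDARY_5_8S_ITS2 = "CAUAU"
ITS1_CORE_BLOCK1 = "GGCGC"
ITS1_CORE_BLOCK2 = "GYGCCAAGGAA"
ITS1_CORE_INSTANCE = "GGCGCAAUCGUGCCAAGGAA"  # block1 + 4 nt spacer + block2 (Y=U)
UGGU_VARIANTS = ("UGGGU", "UGGU", "UGG", "GGU")

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _filler(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


# forbidden substrings that must appear only where deliberately placed
_FORBIDDEN = [MOTIF_5_8S_I, MOTIF_5_8S_II, MOTIF_5_8S_III, BOUNDARY_5_8S_ITS2,
              "GGCGC", "GUGCCAAGGAA", "GCGCCAAGGAA"]


def _clean_filler(rng: random.Random, n: int, context_before: str = "", context_after: str = "") -> str:
    """Deterministic filler that does not create any forbidden motif, even at
    the junctions with its context."""
    before = context_before[-20:]
    after = context_after[:20]
    for _ in range(500):
        cand = _filler(rng, n)
        joined = before + cand + after
        # a new occurrence is one not already fully inside the fixed context
        if all(joined.count(m) == before.count(m) + after.count(m) for m in _FORBIDDEN):
            return cand
    raise RuntimeError("could not generate clean filler")  # pragma: no cover


class _Builder:
    def __init__(self):
        self.seq: list[str] = []
        self.pairs: list[tuple[int, int]] = []

    @property
    def pos(self) -> int:
        return len(self.seq)

    def add(self, s: str) -> int:
        start = self.pos
        self.seq.extend(s)
        return start

    def helix(self, arm5: str, loop: str, mismatch_at: int | None = None) -> None:
        """Append arm5 + loop + revcomp(arm5); if ``mismatch_at`` is given,
        that arm position becomes a U-U mismatch (left unpaired)."""
        a5 = self.add(arm5)
        self.add(loop)
        arm3 = revcomp(arm5)
        a3 = self.add(arm3)
        n = len(arm5)
        for k in range(n):
            if mismatch_at is not None and k == mismatch_at:
                continue
            self.pairs.append((a5 + k, a3 + (n - 1 - k)))

    def mismatch_helix(self, s1: str, s2: str, loop: str) -> None:
        """Helix of two stacked segments separated by a 1-nt U/U mismatch on
        each strand (merged into one helix by the decomposition rule)."""
        arm5 = s1 + "U" + s2
        arm3 = revcomp(s2) + "U" + revcomp(s1)
        a5 = self.add(arm5)
        self.add(loop)
        a3 = self.add(arm3)
        n1, n2 = len(s1), len(s2)
        off2 = n1 + 1
        for k in range(n1):
            self.pairs.append((a5 + k, a3 + len(arm3) - 1 - k))
        for k in range(n2):
            self.pairs.append((a5 + off2 + k, a3 + (n2 - 1 - k)))


def _assemble(rng: random.Random):
    """Build the full root amplicon ITS1 + 5.8S + ITS2 + 28S-head, returning
    (sequence, pairs, intervals) with the flank-extended ITS2 template layout
    embedded."""
    b = _Builder()
    # --- ITS1 (240 nt): unpaired, carries the angiosperm core motif at 60
    its1_start = b.pos
    pre = _clean_filler(rng, 60)
    b.add(pre)
    b.add(ITS1_CORE_INSTANCE)
    b.add(_clean_filler(rng, 240 - 60 - len(ITS1_CORE_INSTANCE), context_before="".join(b.seq)))
    its1_end = b.pos

    # --- 5.8S (161 nt): motifs I-III at fixed offsets; last 25 nt end with
    #     the 5' arm of the proximal stem
    p5 = "GGUCGCAGGAUC"
    f58_start = b.pos
    b.add(MOTIF_5_8S_I)  # [0:16]; AAGAA at 5..9
    b.add(_clean_filler(rng, 19, context_before="".join(b.seq)))  # [16:35]
    b.add(MOTIF_5_8S_II)  # Motif II starts 25 nt after the end of AAGAA
    # four hairpin helices (6 bp arms, 4-nt loops) around the central loop
    b.helix("GGAUGC", "AUCA")
    b.helix("GCCAGA", "CUAG")
    b.helix("GGUCAC", "AAUG")
    b.helix("GAGGCU", "UUAC")
    b.add(_clean_filler(rng, 7, context_before="".join(b.seq)))  # pad to [., 120)
    b.add(MOTIF_5_8S_III)  # [120:130]
    b.add(_clean_filler(rng, 19, context_before="".join(b.seq)))  # [130:149]
    prox5_start = b.add(p5)  # [149:161]
    f58_end = b.pos
    assert f58_end - f58_start == 161

    # --- ITS2 core (222 nt)
    its2_start = b.pos
    b.add(BOUNDARY_5_8S_ITS2)
    b.add(_clean_filler(rng, 8, context_before="".join(b.seq)))
    b.helix("GGAUCAUGAACUGC", "GCAAUC")  # Helix I: 14 bp
    b.add("ACGC")
    b.mismatch_helix("GGCAAUG", "CAGUAUGC", "CUUCG")  # Helix II, U-U mismatch
    b.add("AAA")  # conserved spacer between helices II and III
    b.helix("GCAGAUGUCAAUGCUAGGCAAUCG" + "UGGU", "GAAAUC")  # Helix III, UGGU near apex
    b.add("AGC")
    b.helix("GGAUACUAGC", "CAAGUG")  # Helix IV: 10 bp
    pad = 222 - (b.pos - its2_start)
    assert pad >= 0
    b.add(_clean_filler(rng, pad, context_before="".join(b.seq)))
    its2_end = b.pos

    # --- 28S head (25 nt): proximal-stem 3' arm then filler
    s28_start = b.add(revcomp(p5))
    b.add(_clean_filler(rng, 13, context_before="".join(b.seq)))
    s28_end = b.pos
    for k in range(len(p5)):
        b.pairs.append((prox5_start + k, s28_start + len(p5) - 1 - k))

    seq = "".join(b.seq)
    intervals = {
        Region.ITS1: (its1_start, its1_end),
        Region.FIVE_EIGHT_S: (f58_start, f58_end),
        Region.ITS2: (its2_start, its2_end),
        Region.OTHER: (its2_end, s28_end),  # 28S head
    }
    # audit: each diagnostic motif occurs exactly once
    for m in (MOTIF_5_8S_I, MOTIF_5_8S_II, MOTIF_5_8S_III, BOUNDARY_5_8S_ITS2,
              ITS1_CORE_INSTANCE):
        assert seq.count(m) == 1, f"motif {m} occurs {seq.count(m)} times"
    return seq, frozenset(b.pairs), intervals


# fixed internal seed: the packaged template is a constant, not a sample
_ROOT_SEQ, _ROOT_PAIRS, _ROOT_INTERVALS = _assemble(random.Random(20230301))


def root_amplicon() -> tuple[SeqStructRecord, dict]:
    """The packaged root amplicon (ITS1 + 5.8S + ITS2 + 28S head) with its
    structure and truth intervals."""
    rec = SeqStructRecord(id="root", seq=_ROOT_SEQ, pairs=_ROOT_PAIRS,
                          region=Region.FULL_ITS, source=StructSource.TEMPLATE_MODELED)
    return rec, dict(_ROOT_INTERVALS)


def its2_template(flank_len: int = 25) -> SeqStructRecord:
    """Flank-extended ITS2 template: last ``flank_len`` nt of 5.8S + ITS2 +
    first ``flank_len`` nt of the 28S head, four helices + proximal stem."""
    s, e = _ROOT_INTERVALS[Region.ITS2]
    lo, hi = s - flank_len, e + flank_len
    if lo < _ROOT_INTERVALS[Region.FIVE_EIGHT_S][0] or hi > _ROOT_INTERVALS[Region.OTHER][1]:
        raise ValueError("flank_len exceeds packaged flank lengths")
    pairs = frozenset((i - lo, j - lo) for i, j in _ROOT_PAIRS if lo <= i and j < hi)
    return SeqStructRecord(id="its2-template", seq=_ROOT_SEQ[lo:hi], pairs=pairs,
                           region=Region.ITS2, source=StructSource.TEMPLATE_MODELED)


def five8s_template() -> SeqStructRecord:
    """Packaged 5.8S template: four hairpin helices around a central loop,
    carrying the three conserved angiosperm motifs."""
    s, e = _ROOT_INTERVALS[Region.FIVE_EIGHT_S]
    pairs = frozenset((i - s, j - s) for i, j in _ROOT_PAIRS if s <= i and j < e)
    return SeqStructRecord(id="5.8s-template", seq=_ROOT_SEQ[s:e], pairs=pairs,
                           region=Region.FIVE_EIGHT_S, source=StructSource.TEMPLATE_MODELED)
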