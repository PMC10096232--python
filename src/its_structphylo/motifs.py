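"""Diagnostic motif scanning and the rDNA pseudogene screen.

Functional rDNA copies carry a set of strongly conserved landmarks: the
angiosperm universal core motif in ITS1 (GGCGC, a short spacer, then
GYGCCAAGGAA), three 5.8S motifs (I: CGAUGAAGAACGUAGC, II: GAAUUGCAGAAUCC,
III: UUUGAACGCA), and the ITS2 structural landmarks (a UGGU-variant block on
the 5' side of Helix III, a U-U mismatch in Helix II, an AAA spacer between
helices II and III).  Copies missing these motifs, or with aberrant GC
content or region lengths, are flagged as putative pseudogenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import IUPAC_CODES, MotifHit, Region, RegionAnnotation, SeqStructRecord
from . import templates

__all__ = [
    "scan_motif",
    "TwoBlockPattern",
    "PseudogeneVerdict",
    "screen_pseudogene",
    "PACKAGED_MOTIFS",
    "motif_ii_distances",
]


@dataclass(frozen=True)
class TwoBlockPattern:
    """Two IUPAC blocks separated by a bounded spacer, e.g. the ITS1 core
    motif GGCGC-(3..6 nt)-GYGCCAAGGAA."""

    block1: str
    block2: str
    min_spacer: int
    max_spacer: int


#: Packaged diagnostic motifs (RNA alphabet).
PACKAGED_MOTIFS: dict[str, object] = {
    "ITS1_core": TwoBlockPattern("GGCGC", "GYGCCAAGGAA", 3, 6),
    "5.8S_motif_I": templates.MOTIF_5_8S_I,
    "5.8S_motif_II": templates.MOTIF_5_8S_II,
    "5.8S_motif_III": templates.MOTIF_5_8S_III,
    "ITS2_boundary": templates.BOUNDARY_5_8S_ITS2,
    "ITS2_UGGU": ("UGGGU", "UGGU", "UGG", "GGU"),
    "ITS2_AAA_spacer": "AAA",
}


def _validate_pattern(pattern: str) -> None:
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC character(s) {sorted(bad)} in pattern {pattern!r}")


def _mismatches(window: str, pattern: str, budget: int) -> int | None:
    mm = 0
    for b, p in zip(window, pattern):
        if b not in IUPAC_CODES.get(p, ()):  # degenerate positions honored
            mm += 1
            if mm > budget:
                return None
    return mm


def _scan_block(seq: str, pattern: str, max_mismatches: int, name: str) -> list[MotifHit]:
    _validate_pattern(pattern)
    L = len(pattern)
    hits = []
    for s in range(len(seq) - L + 1):
        mm = _mismatches(seq[s : s + L], pattern, max_mismatches)
        if mm is not None:
            hits.append(MotifHit(motif_name=name, pattern=pattern, start=s, end=s + L,
                                 mismatches=mm))
    return hits


def scan_motif(seq: str, pattern, max_mismatches: int = 0,
               name: str = "motif") -> list[MotifHit]:
    """Scan ``seq`` for an IUPAC ``pattern`` (string or
    :class:`TwoBlockPattern`) allowing up to ``max_mismatches``.

    All hits are reported left-to-right and may overlap; for two-block
    patterns the hit spans both blocks and reports ``spacer_len``, and the
    mismatch budget is shared across the blocks.
    """
    seq = seq.upper().replace("T", "U")
    if isinstance(pattern, TwoBlockPattern):
        out = []
        h1 = _scan_block(seq, pattern.block1, max_mismatches, name)
        for a in h1:
            for spacer in range(pattern.min_spacer, pattern.max_spacer + 1):
                s2 = a.end + spacer
                if s2 + len(pattern.block2) > len(seq):
                    continue
                mm2 = _mismatches(seq[s2 : s2 + len(pattern.block2)], pattern.block2,
                                  max_mismatches - a.mismatches)
                if mm2 is not None:
                    out.append(MotifHit(
                        motif_name=name,
                        pattern=f"{pattern.block1}-(n{spacer})-{pattern.block2}",
                        start=a.start, end=s2 + len(pattern.block2),
                        mismatches=a.mismatches + mm2, spacer_len=spacer))
        return sorted(out, key=lambda h: (h.start, h.end))
    return _scan_block(seq, str(pattern), max_mismatches, name)


@dataclass
class PseudogeneVerdict:
    record_id: str
    passed: bool
    reasons: list = field(default_factory=list)

    def __post_init__(self):
        if self.passed != (not self.reasons):
            raise ValueError("verdict must pass exactly when there are no reasons")


# Default bounds: 5.8S length from the observed conserved range; spacer
# lengths and GC bounds bracket the values reported for functional copies.
DEFAULT_LEN_BOUNDS: dict[Region, tuple[int, int]] = {
    Region.ITS1: (200, 280),
    Region.FIVE_EIGHT_S: (160, 162),
    Region.ITS2: (200, 240),
}
DEFAULT_GC_BOUNDS: dict[Region, tuple[float, float]] = {
    Region.ITS1: (0.45, 0.60),
    Region.FIVE_EIGHT_S: (0.45, 0.60),
    Region.ITS2: (0.45, 0.60),
}


def _gc(seq: str) -> float:
    counted = [b for b in seq if b in "ACGU"]
    if not counted:
        return 0.0
    return sum(1 for b in counted if b in "GC") / len(counted)


def screen_pseudogene(record: SeqStructRecord, annotation: RegionAnnotation,
                      gc_bounds: dict | None = None,
                      len_bounds: dict | None = None,
                      motif_budget: int = 1) -> PseudogeneVerdict:
    """Apply the functional-copy screen to one annotated record.

    Passes iff 5.8S motifs I-III are present within ``motif_budget``
    mismatches, the ITS1 core motif is present, and each region's GC content
    and length fall inside the bounds.  ``reasons`` enumerates every failure.
    """
    gc_bounds = gc_bounds or DEFAULT_GC_BOUNDS
    len_bounds = len_bounds or DEFAULT_LEN_BOUNDS
    needed = (Region.ITS1, Region.FIVE_EIGHT_S, Region.ITS2)
    for reg in needed:
        if reg not in annotation.intervals:
            raise ValueError(f"annotation unresolved for {reg.value}")
    reasons: list[str] = []
    subs = {reg: annotation.subsequence(record.seq, reg) for reg in needed}

    for label, pattern in (("5.8S Motif I", PACKAGED_MOTIFS["5.8S_motif_I"]),
                           ("5.8S Motif II", PACKAGED_MOTIFS["5.8S_motif_II"]),
                           ("5.8S Motif III", PACKAGED_MOTIFS["5.8S_motif_III"])):
        if not scan_motif(subs[Region.FIVE_EIGHT_S], pattern, motif_budget, label):
            reasons.append(f"{label} missing")
    if not scan_motif(subs[Region.ITS1], PACKAGED_MOTIFS["ITS1_core"], motif_budget,
                      "ITS1 core"):
        reasons.append("ITS1 core motif missing")

    for reg in needed:
        n = len(subs[reg])
        lo, hi = len_bounds[reg]
        if not lo <= n <= hi:
            reasons.append(f"{reg.value} length out of range ({n} not in [{lo},{hi}])")
        g = _gc(subs[reg])
        glo, ghi = gc_bounds[reg]
        if not glo <= g <= ghi:
            reasons.append(f"{reg.value} GC out of range ({g:.3f} not in [{glo},{ghi}])")
    return PseudogeneVerdict(record_id=record.id, passed=not reasons, reasons=reasons)


def motif_ii_distances(five8s_seq: str) -> dict | None:
    """Distances from the conserved AAGAA block to 5.8S Motif II, measured
    both from the start and from the end of AAGAA (both conventions are
    reported because the literature leaves the reference point ambiguous)."""
    seq = five8s_seq.upper().replace("T", "U")
    a = seq.find("AAGAA")
    hits = scan_motif(seq, PACKAGED_MOTIFS["5.8S_motif_II"], 1, "Motif II")
    if a < 0 or not hits:
        return None
    m2 = hits[0].start
    return {"from_aagaa_start": m2 - a, "from_aagaa_end": m2 - (a + 5)}
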