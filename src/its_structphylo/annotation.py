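"""Motif-anchor annotation of ITS1, 5.8S, and ITS2 within full amplicons.

Region boundaries are located from conserved anchor motifs rather than
profile HMMs: the 5.8S gene starts at its Motif I block, the 5.8S-ITS2
boundary sits at the conserved CAUAU pentamer (RNA form of CATAT), and the
ITS2 end is marked by the proximal-stem anchor at the start of 28S.  Each
anchor carries a mismatch budget and an expected position window; an anchor
that cannot be located within budget and window leaves its boundary
"unresolved" instead of guessing.  :func:`harmonize_boundaries` reconciles an
external annotation convention with the anchor-based one and records the
signed nucleotide trims per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import MotifHit, Region, RegionAnnotation, SeqStructRecord
from .motifs import scan_motif
from . import templates

__all__ = ["Anchor", "AnchorSet", "default_anchors", "annotate_regions",
           "harmonize_boundaries", "UnannotatableError"]


class UnannotatableError(ValueError):
    pass


# Boundary identifiers
ITS1_START = "ITS1_start"
FIVE8S_START = "FIVE_EIGHT_S_start"
FIVE8S_END = "FIVE_EIGHT_S_end"
ITS2_END = "ITS2_end"


@dataclass(frozen=True)
class Anchor:
    name: str
    pattern: str
    edge: str  # one of the boundary identifiers above
    max_mismatches: int = 0
    expected_pos: int | None = None  # expected boundary position, None = anywhere
    window: int = 30  # +- tolerance around expected_pos

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("anchor pattern must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class AnchorSet:
    anchors: list

    def by_edge(self, edge: str):
        return [a for a in self.anchors if a.edge == edge]


# Nominal region lengths used only to center anchor search windows.
NOMINAL_ITS1 = 240
NOMINAL_5_8S = 161
NOMINAL_ITS2 = 222
MIN_REGION_LENGTHS = {Region.ITS1: 100, Region.FIVE_EIGHT_S: 150, Region.ITS2: 150}


def default_anchors(its1_len: int = NOMINAL_ITS1,
                    five8s_len: int = NOMINAL_5_8S,
                    its2_len: int = NOMINAL_ITS2,
                    window: int = 30) -> AnchorSet:
    """Packaged anchors: 5.8S Motif I marks the 5.8S start, CAUAU the
    5.8S-ITS2 boundary, and the 28S proximal-stem arm the ITS2 end."""
    p28 = templates.revcomp("GGUCGCAGGAUC")  # 28S proximal-stem anchor, configurable
    return AnchorSet([
        Anchor("5.8S_motif_I_start", templates.MOTIF_5_8S_I, FIVE8S_START, 1,
               expected_pos=its1_len, window=window),
        Anchor("5.8S_ITS2_boundary_CAUAU", templates.BOUNDARY_5_8S_ITS2, FIVE8S_END, 0,
               expected_pos=its1_len + five8s_len, window=window),
        Anchor("28S_proximal_stem", p28, ITS2_END, 1,
               expected_pos=its1_len + five8s_len + its2_len, window=window),
    ])


def _locate(seq: str, anchor: Anchor, warnings: list) -> MotifHit | None:
    hits = scan_motif(seq, anchor.pattern, anchor.max_mismatches, anchor.name)
    if anchor.expected_pos is not None:
        lo = anchor.expected_pos - anchor.window
        hi = anchor.expected_pos + anchor.window
        hits = [h for h in hits if lo <= h.start <= hi]
    if not hits:
        return None
    exact = [h for h in hits if h.mismatches == 0]
    pool = exact or hits
    if len(pool) > 1:
        warnings.append(f"anchor {anchor.name}: {len(pool)} hits in window, using leftmost")
    return pool[0]


def annotate_regions(record: SeqStructRecord, anchors: AnchorSet | None = None) -> RegionAnnotation:
    """Locate ITS1, 5.8S, and ITS2 inside a full amplicon via anchor motifs.

    The ITS1 start is the sequence start; the 5.8S start and 5.8S-ITS2
    boundary come from their anchors; the ITS2 end comes from the 28S anchor
    when present, else the sequence end (flagged unresolved).  A boundary
    whose anchor is not found within its mismatch budget and window is
    flagged unresolved rather than guessed.
    """
    if record.region is not Region.FULL_ITS:
        raise ValueError("annotate_regions expects a FULL_ITS record")
    anchors = anchors or default_anchors()
    need = sum(MIN_REGION_LENGTHS.values())
    if len(record.seq) < need:
        raise UnannotatableError(
            f"sequence of length {len(record.seq)} shorter than the minimum "
            f"combined region length {need}")
    if not anchors.by_edge(FIVE8S_START) or not anchors.by_edge(FIVE8S_END):
        raise ValueError("anchor set must include 5.8S start and 5.8S end anchors")

    warnings: list[str] = []
    unresolved: list[str] = []
    found: dict[str, MotifHit] = {}
    for edge in (FIVE8S_START, FIVE8S_END, ITS2_END):
        for anchor in anchors.by_edge(edge):
            hit = _locate(record.seq, anchor, warnings)
            if hit is not None:
                found[edge] = hit
                break
        else:
            if anchors.by_edge(edge):
                unresolved.append(edge)

    if not found:
        raise UnannotatableError(f"record {record.id!r}: no anchor found at all")

    intervals: dict[Region, tuple[int, int]] = {}
    hits: list[MotifHit] = list(found.values())
    fs = found[FIVE8S_START].start if FIVE8S_START in found else None
    fe = found[FIVE8S_END].start if FIVE8S_END in found else None
    ie = found[ITS2_END].start if ITS2_END in found else len(record.seq)
    if ITS2_END not in found and ITS2_END not in unresolved:
        unresolved.append(ITS2_END)
    if fs is not None and fs > 0:
        intervals[Region.ITS1] = (0, fs)
    if fs is not None and fe is not None and fe > fs:
        intervals[Region.FIVE_EIGHT_S] = (fs, fe)
    if fe is not None and ie > fe:
        intervals[Region.ITS2] = (fe, ie)
    return RegionAnnotation(record_id=record.id, intervals=intervals, anchors=hits,
                            unresolved=unresolved, warnings=warnings)


def harmonize_boundaries(ann: RegionAnnotation, external: RegionAnnotation) -> RegionAnnotation:
    """Reconcile an external annotation with the anchor-based one.

    The returned annotation keeps the anchor-based intervals; ``trims``
    records, per region, the signed nt difference between the external and
    anchor-based conventions on the edge where they disagree (positive =
    external boundary extends upstream of the anchor-based one, i.e. those
    nucleotides are pruned; negative = downstream).  The start edge is
    compared for ITS1 and 5.8S, the end edge for ITS2; when both edges of a
    region disagree both are reported via the warnings list.
    """
    if ann.record_id != external.record_id:
        raise ValueError("annotations refer to different records")
    trims: dict[Region, int] = {}
    warnings = list(ann.warnings)
    for reg in (Region.ITS1, Region.FIVE_EIGHT_S, Region.ITS2):
        if reg not in ann.intervals or reg not in external.intervals:
            continue
        (s, e) = ann.intervals[reg]
        (xs, xe) = external.intervals[reg]
        if reg is Region.ITS2:
            trims[reg] = e - xe  # end edge; positive = external ends upstream
            if xs != s:
                warnings.append(f"{reg.value}: start edges also differ by {s - xs:+d} nt")
        else:
            trims[reg] = s - xs
            if xe != e:
                warnings.append(f"{reg.value}: end edges also differ by {e - xe:+d} nt")
    return RegionAnnotation(record_id=ann.record_id, intervals=dict(ann.intervals),
                            anchors=list(ann.anchors), trims=trims,
                            unresolved=list(ann.unresolved), warnings=warnings)
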