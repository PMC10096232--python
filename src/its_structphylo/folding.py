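"""Nested secondary-structure prediction by dynamic programming.

The internal engine maximizes a configurable pairing score (base-pair-count or
pair-type scores with a stacking bonus) over all nested structures, in the
spirit of classic base-pair-maximization DP.  It reports its optimum in
arbitrary score units.  Thermodynamically meaningful free energies (kcal/mol)
are only produced by the external backend (ViennaRNA), which evaluates the full
nearest-neighbor model.

ITS2 folding conventionally augments the spacer with short stretches of the
flanking 5.8S and 28S genes so the proximal stem can form; :func:`add_flanks`
implements that and returns the offset needed to map structure indices back to
spacer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Region, SeqStructRecord, StructSource

__all__ = ["FoldParams", "add_flanks", "fold_mfe", "project_pairs"]

_CANONICAL = {("G", "C"): "GC", ("C", "G"): "GC",
              ("A", "U"): "AU", ("U", "A"): "AU",
              ("G", "U"): "GU", ("U", "G"): "GU"}


@dataclass
class FoldParams:
    """Scoring parameters for the internal folding engine.

    ``scoring="pair_count"`` scores every allowed pair 1; ``"stacking"`` scores
    pairs by type (GC > AU > GU by default) and adds ``stack_bonus`` for each
    directly stacked pair, rewarding contiguous helices.
    """

    scoring: str = "stacking"  # "pair_count" | "stacking"
    pair_scores: dict = field(default_factory=lambda: {"GC": 3.0, "AU": 2.0, "GU": 1.0})
    stack_bonus: float = 1.0
    min_hairpin: int = 3
    flank_len: int = 25
    backend: str = "internal"  # "internal" | "external"

    def __post_init__(self):
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if any(v <= 0 for v in self.pair_scores.values()):
            raise ValueError("pair scores must be positive")
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")

    def pair_score(self, a: str, b: str) -> float | None:
        t = _CANONICAL.get((a, b))
        if t is None:
            return None
        return 1.0 if self.scoring == "pair_count" else self.pair_scores[t]


def add_flanks(its2_seq: str, upstream_5_8s: str, downstream_28s: str, flank_len: int = 25) -> tuple[str, int]:
    """Prepend the last ``flank_len`` nt of 5.8S and append the first
    ``flank_len`` nt of 28S to an ITS2 sequence.

    Returns ``(extended_sequence, offset)`` where ``offset == flank_len`` is
    the shift from extended-sequence indices to ITS2 indices.
    """
    if flank_len > 0:
        if len(upstream_5_8s) < flank_len:
            raise ValueError(f"5.8S flank shorter than flank_len={flank_len}")
        if len(downstream_28s) < flank_len:
            raise ValueError(f"28S flank shorter than flank_len={flank_len}")
    up = upstream_5_8s[len(upstream_5_8s) - flank_len :] if flank_len else ""
    down = downstream_28s[:flank_len]
    return up + its2_seq + down, flank_len


def project_pairs(pairs, offset: int, length: int) -> frozenset:
    """Map pairs from flank-extended coordinates back onto the core region
    ``[offset, offset+length)``, dropping pairs with a partner in a flank."""
    out = set()
    for i, j in pairs:
        if offset <= i and j < offset + length:
            out.add((i - offset, j - offset))
    return frozenset(out)


def _fold_internal(seq: str, params: FoldParams) -> tuple[frozenset, float]:
    n = len(seq)
    h = params.min_hairpin
    NEG = float("-inf")

    # V[i][j]: best score on [i,j] given (i,j) paired; W[i][j]: best on [i,j]
    V = [[NEG] * n for _ in range(n)]
    W = [[0.0] * n for _ in range(n)]

    for span in range(h + 1, n):
        for i in range(0, n - span):
            j = i + span
            ps = params.pair_score(seq[i], seq[j])
            if ps is not None:
                best = ps + (W[i + 1][j - 1] if i + 1 <= j - 1 else 0.0)
                if params.scoring == "stacking" and V[i + 1][j - 1] > NEG:
                    cand = ps + params.stack_bonus + V[i + 1][j - 1]
                    if cand > best:
                        best = cand
                V[i][j] = best
            # W recursion: i unpaired, or i pairs with some k
            best = W[i + 1][j]
            for k in range(i + h + 1, j + 1):
                if V[i][k] > NEG:
                    cand = V[i][k] + (W[k + 1][j] if k + 1 <= j else 0.0)
                    if cand > best:
                        best = cand
            W[i][j] = best

    pairs: set[tuple[int, int]] = set()

    def trace_W(i: int, j: int) -> None:
        while i < j:
            target = W[i][j]
            if target == 0.0 and W[i + 1][j] == 0.0:
                # nothing pairable; fall through positionwise
                i += 1
                continue
            # prefer pairing i (smallest closing k) over leaving it unpaired
            chosen = None
            for k in range(i + h + 1, j + 1):
                if V[i][k] > NEG:
                    rest = W[k + 1][j] if k + 1 <= j else 0.0
                    if V[i][k] + rest == target:
                        chosen = k
                        break
            if chosen is None:
                i += 1
                continue
            trace_V(i, chosen)
            i = chosen + 1

    def trace_V(i: int, j: int) -> None:
        while True:
            pairs.add((i, j))
            ps = params.pair_score(seq[i], seq[j])
            inner_w = W[i + 1][j - 1] if i + 1 <= j - 1 else 0.0
            if (params.scoring == "stacking" and V[i + 1][j - 1] > NEG
                    and ps + params.stack_bonus + V[i + 1][j - 1] == V[i][j]
                    and ps + params.stack_bonus + V[i + 1][j - 1] >= ps + inner_w):
                i, j = i + 1, j - 1
                continue
            trace_W(i + 1, j - 1)
            return

    if n > 0:
        trace_W(0, n - 1)
    score = W[0][n - 1] if n else 0.0
    return frozenset(pairs), score


def _fold_external(seq: str) -> tuple[frozenset, float]:
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise RuntimeError(
            "external folding backend requested but the ViennaRNA python "
            "bindings are not importable"
        ) from exc
    fc = RNA.fold_compound(seq)
    db, mfe = fc.mfe()
    from .io_formats import dotbracket_to_pairs

    return dotbracket_to_pairs(db), float(mfe)


def fold_mfe(seq: str, params: FoldParams | None = None, record_id: str = "folded",
             region: Region = Region.OTHER) -> SeqStructRecord:
    """Fold an unambiguous RNA sequence into its optimal nested structure.

    With ``params.backend == "internal"`` the configurable DP engine is used
    and the optimum is reported in ``score`` (arbitrary units).  With
    ``"external"`` ViennaRNA's MFE structure and free energy (kcal/mol) are
    returned unchanged.  Ties in the internal DP are broken deterministically:
    at each position the traceback prefers pairing over leaving the base
    unpaired, choosing the smallest closing index.
    """
    params = params or FoldParams()
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"cannot fold sequence with ambiguity codes: {sorted(bad)}")
    if len(seq) < params.min_hairpin + 2:
        raise ValueError(f"sequence too short to fold (need >= {params.min_hairpin + 2} nt)")
    if params.backend == "external":
        pairs, energy = _fold_external(seq)
        return SeqStructRecord(id=record_id, seq=seq, pairs=pairs, region=region,
                               energy=energy, source=StructSource.FOLDED_EXTERNAL)
    pairs, score = _fold_internal(seq, params)
    return SeqStructRecord(id=record_id, seq=seq, pairs=pairs, region=region,
                           score=score, source=StructSource.FOLDED_INTERNAL)
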