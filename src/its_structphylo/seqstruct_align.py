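"""Synchronized sequence-structure encoding and alignment.

Every position of a folded record is encoded into a 12-state joint alphabet:
4 bases x 3 structural roles (unpaired ``.``, pair-opening ``(``, pair-closing
``)``).  Records are aligned in that alphabet so that both sequence and
structure inform column homology, in the manner of 4SALE-style synchronized
alignment: pairwise alignment is affine-gap dynamic programming over joint
states, and multiple alignment is progressive along an NJ guide tree built
from pairwise joint-state p-distances.  Manually curated alignments can be
loaded with :func:`read_paired_fasta`, bypassing the aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import SeqStructRecord, dotbracket_to_pairs, FormatError
from .trees import nj_tree

__all__ = [
    "JointScore",
    "encode12",
    "decode12",
    "SeqStructAlignment",
    "align_seqstruct",
    "paired_columns",
    "read_paired_fasta",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "U"), ("U", "C")}


@dataclass
class JointScore:
    """Substitution and gap parameters for the joint 12-state alphabet.

    The score of two states is the sum of a sequence component (match /
    transition / transversion) and a structure component (same role, unpaired
    vs paired, open vs close).  Gap penalties are positive magnitudes.
    """

    match: float = 2.0
    transition: float = -1.0
    transversion: float = -2.0
    role_same: float = 1.0
    role_pair_unpair: float = -2.0
    role_open_close: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 1.0

    def score(self, s: str, t: str) -> float:
        b1, r1 = s[0], s[1]
        b2, r2 = t[0], t[1]
        if b1 == b2:
            seq = self.match
        elif (b1, b2) in _TRANSITIONS:
            seq = self.transition
        else:
            seq = self.transversion
        if r1 == r2:
            struct = self.role_same
        elif {r1, r2} == {"(", ")"}:
            struct = self.role_open_close
        else:
            struct = self.role_pair_unpair
        return seq + struct


def encode12(record: SeqStructRecord) -> list[str]:
    """Encode a record position-wise into joint states ``"<base><role>"``."""
    roles = ["."] * len(record.seq)
    for i, j in record.pairs:
        roles[i] = "("
        roles[j] = ")"
    return [b + r for b, r in zip(record.seq, roles)]


def decode12(states: Sequence[str], record_id: str = "decoded") -> SeqStructRecord:
    """Exact inverse of :func:`encode12`."""
    seq = "".join(s[0] for s in states)
    db = "".join(s[1] for s in states)
    return SeqStructRecord(id=record_id, seq=seq, pairs=dotbracket_to_pairs(db))


# ---------------------------------------------------------------------------
# Alignment container


@dataclass
class SeqStructAlignment:
    """Joint sequence-structure alignment.

    ``rows[taxon]`` is a list over alignment columns of joint states (or
    ``None`` for a gap); ungapping any row reproduces ``encode12`` of the
    taxon's record exactly.
    """

    taxa: list
    rows: dict
    records: dict

    def __post_init__(self):
        widths = {len(r) for r in self.rows.values()}
        if len(widths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        for t in self.taxa:
            states = [s for s in self.rows[t] if s is not None]
            if states != encode12(self.records[t]):
                raise ValueError(f"row for {t!r} does not ungap to its record")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    def col_map(self, taxon: str) -> list:
        """Per column: original sequence index of this taxon, or None (gap)."""
        out, k = [], 0
        for s in self.rows[taxon]:
            if s is None:
                out.append(None)
            else:
                out.append(k)
                k += 1
        return out

    def inverse_col_map(self, taxon: str) -> dict:
        return {orig: col for col, orig in enumerate(self.col_map(taxon)) if orig is not None}

    def base_matrix(self) -> dict:
        """taxon -> aligned base string with '-' gaps (structure dropped)."""
        return {t: "".join(s[0] if s else "-" for s in self.rows[t]) for t in self.taxa}

    def write_paired_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                seq = "".join(s[0] if s else "-" for s in self.rows[t])
                db = "".join(s[1] if s else "-" for s in self.rows[t])
                fh.write(f">{t}\n{seq}\n{db}\n")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(str(c + 1) for c in range(self.width)) + "\n")
            for t in self.taxa:
                fh.write(t + "\t" + "\t".join(s if s else "--" for s in self.rows[t]) + "\n")


def read_paired_fasta(path) -> SeqStructAlignment:
    """Load a user-supplied joint alignment (sequence row + structure row per
    taxon, gaps as '-')."""
    lines = [ln.rstrip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) % 3 != 0:
        raise FormatError("paired FASTA must have 3 lines per record (>id, seq, struct)")
    taxa, rows, records = [], {}, {}
    for k in range(0, len(lines), 3):
        if not lines[k].startswith(">"):
            raise FormatError(f"expected header at line {k + 1}")
        t = lines[k][1:].strip()
        seq, db = lines[k + 1], lines[k + 2]
        if len(seq) != len(db):
            raise FormatError(f"record {t!r}: sequence/structure length mismatch")
        row = [None if b == "-" else b + r for b, r in zip(seq.upper().replace("T", "U"), db)]
        ungapped_seq = "".join(s[0] for s in row if s)
        ungapped_db = "".join(s[1] for s in row if s)
        records[t] = SeqStructRecord(id=t, seq=ungapped_seq, pairs=dotbracket_to_pairs(ungapped_db))
        rows[t] = row
        taxa.append(t)
    return SeqStructAlignment(taxa=taxa, rows=rows, records=records)


# ---------------------------------------------------------------------------
# Pairwise and profile DP (Gotoh affine gaps)

_NEG = float("-inf")


def _gotoh(colsA: list, colsB: list, colscore, gap_open: float, gap_extend: float) -> list:
    """Affine-gap global alignment of two column sequences.

    Returns the aligned path as a list of (i | None, j | None).  Ties prefer
    match over gap-in-B over gap-in-A, which makes the traceback
    deterministic.
    """
    n, m = len(colsA), len(colsB)
    # row-list DP (python lists are much faster than numpy scalar indexing here)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in B (consume A)
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in A (consume B)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        ca = colsA[i - 1]
        for j in range(1, m + 1):
            s = colscore(ca, colsB[j - 1])
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] - gap_open, Xp[j] - gap_extend, Yp[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend,
                        Xi[j - 1] - gap_open)
    # traceback (tolerance-based equality guards against float drift)
    def _eq(a: float, b: float) -> bool:
        return a != _NEG and b != _NEG and abs(a - b) <= 1e-9

    mats = {"M": M, "X": X, "Y": Y}
    path = []
    i, j = n, m
    best = max(M[i][j], X[i][j], Y[i][j])
    state = next(k for k in ("M", "X", "Y") if _eq(mats[k][i][j], best))
    while i > 0 or j > 0:
        if state == "M":
            s = colscore(colsA[i - 1], colsB[j - 1])
            prev = M[i][j] - s
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = next(k for k in ("M", "X", "Y") if _eq(mats[k][i][j], prev))
        elif state == "X":
            v = X[i][j]
            path.append((i - 1, None))
            i -= 1
            if i == 0 and j == 0:
                break
            if _eq(M[i][j] - gap_open, v):
                state = "M"
            elif _eq(X[i][j] - gap_extend, v):
                state = "X"
            else:
                state = "Y"
        else:
            v = Y[i][j]
            path.append((None, j - 1))
            j -= 1
            if i == 0 and j == 0:
                break
            if _eq(M[i][j] - gap_open, v):
                state = "M"
            elif _eq(Y[i][j] - gap_extend, v):
                state = "Y"
            else:
                state = "X"
    path.reverse()
    return path


def _profile_colscore(score: JointScore):
    cache: dict = {}
    pair_cache: dict = {}

    def pscore(a: str, b: str) -> float:
        v = pair_cache.get((a, b))
        if v is None:
            v = score.score(a, b)
            pair_cache[(a, b)] = v
        return v

    def colscore(colA: tuple, colB: tuple) -> float:
        key = (colA, colB)
        v = cache.get(key)
        if v is not None:
            return v
        tot, cnt = 0.0, 0
        for a in colA:
            if a is None:
                continue
            for b in colB:
                if b is None:
                    continue
                tot += pscore(a, b)
                cnt += 1
        v = tot / cnt if cnt else 0.0
        cache[key] = v
        return v

    return colscore


def _merge(profA, profB, path):
    taxaA, colsA = profA
    taxaB, colsB = profB
    nA, nB = len(taxaA), len(taxaB)
    merged = []
    for ia, ib in path:
        left = colsA[ia] if ia is not None else (None,) * nA
        right = colsB[ib] if ib is not None else (None,) * nB
        merged.append(tuple(left) + tuple(right))
    return taxaA + taxaB, merged


def _pairwise_pdistance(statesA: list, statesB: list, score: JointScore) -> float:
    path = _gotoh([(s,) for s in statesA], [(s,) for s in statesB],
                  _profile_colscore(score), score.gap_open, score.gap_extend)
    diff = same = 0
    for ia, ib in path:
        if ia is None or ib is None:
            continue
        if statesA[ia] == statesB[ib]:
            same += 1
        else:
            diff += 1
    total = diff + same
    return diff / total if total else 0.0


def align_seqstruct(records: Sequence[SeqStructRecord], score: JointScore | None = None) -> SeqStructAlignment:
    """Progressively align encoded records along an NJ guide tree.

    Deterministic: guide-tree ties resolve by taxon order and profile merges
    follow a fixed postorder traversal.
    """
    score = score or JointScore()
    if len(records) < 2:
        raise ValueError("need at least 2 records to align")
    for r in records:
        if not r.seq:
            raise ValueError(f"record {r.id!r} is empty")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    enc = {r.id: encode12(r) for r in records}
    by_id = {r.id: r for r in records}

    # merge order
    if len(records) == 2:
        order = [(ids[0], ids[1])]
        merge_plan = None
    else:
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _pairwise_pdistance(enc[ids[i]], enc[ids[j]], score)
        guide = nj_tree(d, ids)
        try:
            guide.reroot_at_midpoint(update_bipartitions=False)
        except Exception:
            pass
        merge_plan = guide

    colscore = _profile_colscore(score)

    def align_pair(pA, pB):
        path = _gotoh(pA[1], pB[1], colscore, score.gap_open, score.gap_extend)
        return _merge(pA, pB, path)

    if merge_plan is None:
        a, b = ids[0], ids[1]
        taxa, cols = align_pair(([a], [(s,) for s in enc[a]]), ([b], [(s,) for s in enc[b]]))
    else:
        def build(node):
            if node.is_leaf():
                t = node.taxon.label
                return [t], [(s,) for s in enc[t]]
            profs = [build(c) for c in node.child_nodes()]
            cur = profs[0]
            for nxt in profs[1:]:
                cur = align_pair(cur, nxt)
            return cur
        taxa, cols = build(merge_plan.seed_node)

    rows = {}
    for k, t in enumerate(taxa):
        rows[t] = [col[k] for col in cols]
    # restore input taxon order
    ordered = [t for t in ids if t in rows]
    return SeqStructAlignment(taxa=ordered, rows=rows, records={t: by_id[t] for t in ordered})


def paired_columns(aln: SeqStructAlignment, threshold: float = 0.5) -> list:
    """Column pairs (p, q) that are structurally complementary in at least
    ``threshold`` of the rows ungapped at p (gapped rows abstain)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    width = aln.width
    votes: dict[tuple[int, int], int] = {}
    ungapped = [0] * width
    partner_col: dict[str, dict[int, int]] = {}
    for t in aln.taxa:
        inv = aln.inverse_col_map(t)
        partner_col[t] = {inv[i]: inv[j] for i, j in aln.records[t].pairs
                          if i in inv and j in inv}
    for p in range(width):
        for t in aln.taxa:
            if aln.rows[t][p] is None:
                continue
            ungapped[p] += 1
            q = partner_col[t].get(p)
            if q is not None:
                votes[(p, q)] = votes.get((p, q), 0) + 1
    out = []
    for (p, q), v in votes.items():
        if ungapped[p] and v / ungapped[p] >= threshold:
            out.append((p, q))
    return sorted(out)
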