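"""Classification of aligned changes into CBC / hemi-CBC / Nst / silent.

A compensatory base change (CBC) replaces both partners of a structural base
pair while keeping the pairing allowed (e.g. U:G <-> A:U); a hemi-CBC (hCBC)
replaces exactly one partner while keeping it allowed (e.g. U:A <-> U:G); a
non-structural substitution (Nst) either breaks the pairing or occurs at an
unpaired position.  Indels never count as substitution events; they are logged
as a separate class.

The default classifier is strict: a change whose result is not an allowed
pair is an Nst even if only one partner moved.  ``lenient=True`` additionally
admits C:A/A:C as "weak pairs", reproducing the more permissive labeling some
studies use for such cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ALLOWED_PAIRS, GroupMap
from .seqstruct_align import SeqStructAlignment, paired_columns

__all__ = [
    "ChangeEvent",
    "classify_pair_change",
    "classify_unpaired_change",
    "tabulate_events",
    "cbc_matrix",
    "events_to_dataframe",
]

_WEAK_PAIRS = frozenset([("C", "A"), ("A", "C")])
_BASES = "ACGU"


@dataclass(frozen=True)
class ChangeEvent:
    """One classified change between two taxa or groups at one column (and
    its partner column when the site is paired)."""

    a: str
    b: str
    aligned_col: int
    partner_col: int | None
    pos_a: int | None  # 0-based original coordinate in a (None if gapped)
    pos_b: int | None
    helix: str
    state_a: tuple
    state_b: tuple
    klass: str  # CBC | hCBC | Nst | indel


def classify_pair_change(state_a: tuple, state_b: tuple,
                         allowed: frozenset = ALLOWED_PAIRS,
                         lenient: bool = False) -> str:
    """Classify a change between two base-pair states.

    Returns one of ``"CBC"``, ``"hCBC"``, ``"Nst"``, ``"silent"``.  Symmetric
    in its arguments and deterministic.
    """
    (a1, a2), (b1, b2) = state_a, state_b
    for base in (a1, a2, b1, b2):
        if base not in _BASES:
            raise ValueError(f"ambiguous or invalid base {base!r}; resolve or skip")
    if state_a == state_b:
        return "silent"
    ok = allowed | _WEAK_PAIRS if lenient else allowed
    if (a1, a2) in ok and (b1, b2) in ok:
        if a1 != b1 and a2 != b2:
            return "CBC"
        return "hCBC"
    return "Nst"


def classify_unpaired_change(base_a: str, base_b: str) -> str:
    """Classify a change at an unpaired column: silent if identical, Nst
    otherwise.  Gaps must be handled by the caller (indel class)."""
    if base_a == base_b:
        return "silent"
    return "Nst"


def _row_base(aln: SeqStructAlignment, taxon: str, col: int) -> str | None:
    s = aln.rows[taxon][col]
    return s[0] if s else None


def _group_state(bases: dict, threshold: float):
    """Shared state of a group at one site: (state, exceptions).  ``state`` is
    None when no state reaches the threshold (polymorphic)."""
    counts: dict = {}
    for t, b in bases.items():
        counts[b] = counts.get(b, 0) + 1
    total = len(bases)
    if not total:
        return None, []
    state, cnt = max(counts.items(), key=lambda kv: (kv[1], str(kv[0])))
    if cnt / total >= threshold:
        exceptions = [t for t, b in bases.items() if b != state]
        return state, sorted(exceptions)
    return None, sorted(bases)


def tabulate_events(aln: SeqStructAlignment,
                    groups: GroupMap | None = None,
                    helixmap=None,
                    mode: str = "taxon_pairwise",
                    paired_cols: Sequence[tuple] | None = None,
                    pair_threshold: float = 0.5,
                    group_threshold: float = 1.0,
                    lenient: bool = False):
    """Classify every difference between taxa (or group consensus states).

    In ``taxon_pairwise`` mode every unordered pair of taxa is compared at
    every paired and unpaired column.  In ``group_level`` mode a per-group
    state is derived per site (shared by at least ``group_threshold`` of the
    ungapped members, else the site is polymorphic for that group and the
    deviating members are listed as exceptions, mirroring per-taxon exception
    reporting) and groups are compared pairwise.

    Returns ``(events, tables)`` where ``events`` is a list of
    :class:`ChangeEvent` (silent identities are not materialized) and
    ``tables`` is a dict with ``"by_pair"`` and ``"by_helix"`` count
    DataFrames plus the ``"exceptions"`` list in group mode.
    """
    if mode not in ("taxon_pairwise", "group_level"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "group_level" and groups is None:
        raise ValueError("group_level mode requires a GroupMap")
    if groups is not None:
        missing = [t for t in aln.taxa if t not in groups.assignments]
        if missing:
            raise ValueError(f"taxa without group assignment: {missing}")

    if paired_cols is None:
        paired_cols = paired_columns(aln, pair_threshold)
    paired_set = {p for pq in paired_cols for p in pq}
    unpaired_cols = [c for c in range(aln.width) if c not in paired_set]

    col_maps = {t: aln.col_map(t) for t in aln.taxa}

    def helix_label(col: int) -> str:
        if helixmap is None:
            return ""
        lab = helixmap.helix_of(col)
        return lab if lab is not None else "loop"

    events: list[ChangeEvent] = []
    exceptions: list[tuple] = []

    if mode == "group_level":
        units = sorted(groups.groups())

    def emit(a, b, cols, sa, sb, pos_a, pos_b, klass):
        events.append(ChangeEvent(
            a=a, b=b, aligned_col=cols[0],
            partner_col=cols[1] if len(cols) > 1 else None,
            pos_a=pos_a, pos_b=pos_b, helix=helix_label(cols[0]),
            state_a=sa, state_b=sb, klass=klass))

    if mode == "taxon_pairwise":
        taxa = aln.taxa
        for ia in range(len(taxa)):
            for ib in range(ia + 1, len(taxa)):
                a, b = taxa[ia], taxa[ib]
                for p, q in paired_cols:
                    sa = (_row_base(aln, a, p), _row_base(aln, a, q))
                    sb = (_row_base(aln, b, p), _row_base(aln, b, q))
                    gap_a = None in sa
                    gap_b = None in sb
                    if gap_a and gap_b:
                        continue
                    if gap_a != gap_b:
                        emit(a, b, (p, q), sa, sb, col_maps[a][p], col_maps[b][p], "indel")
                        continue
                    klass = classify_pair_change(sa, sb, lenient=lenient)
                    if klass != "silent":
                        emit(a, b, (p, q), sa, sb, col_maps[a][p], col_maps[b][p], klass)
                for c in unpaired_cols:
                    ba = _row_base(aln, a, c)
                    bb = _row_base(aln, b, c)
                    if ba is None and bb is None:
                        continue
                    if (ba is None) != (bb is None):
                        emit(a, b, (c,), (ba,), (bb,), col_maps[a][c], col_maps[b][c], "indel")
                        continue
                    if classify_unpaired_change(ba, bb) == "Nst":
                        emit(a, b, (c,), (ba,), (bb,), col_maps[a][c], col_maps[b][c], "Nst")
    else:
        grp = groups.groups()
        # per-unit states at each site
        def unit_states(cols):
            states = {}
            for g in units:
                bases = {}
                for t in grp[g]:
                    vals = tuple(_row_base(aln, t, c) for c in cols)
                    if None in vals:
                        continue  # gapped member abstains
                    bases[t] = vals
                state, exc = _group_state(bases, group_threshold)
                if state is None and bases:
                    exceptions.append((g, tuple(c for c in cols), "polymorphic", exc))
                elif exc:
                    exceptions.append((g, tuple(c for c in cols), "deviating", exc))
                states[g] = state
            return states

        def rep_pos(g, col):
            for t in sorted(grp[g]):
                if col_maps[t][col] is not None:
                    return col_maps[t][col]
            return None

        for p, q in paired_cols:
            states = unit_states((p, q))
            for ia in range(len(units)):
                for ib in range(ia + 1, len(units)):
                    ga, gb = units[ia], units[ib]
                    sa, sb = states[ga], states[gb]
                    if sa is None or sb is None:
                        continue
                    klass = classify_pair_change(sa, sb, lenient=lenient)
                    if klass != "silent":
                        emit(ga, gb, (p, q), sa, sb, rep_pos(ga, p), rep_pos(gb, p), klass)
        for c in unpaired_cols:
            states = unit_states((c,))
            for ia in range(len(units)):
                for ib in range(ia + 1, len(units)):
                    ga, gb = units[ia], units[ib]
                    sa, sb = states[ga], states[gb]
                    if sa is None or sb is None:
                        continue
                    if classify_unpaired_change(sa[0], sb[0]) == "Nst":
                        emit(ga, gb, (c,), sa, sb, rep_pos(ga, c), rep_pos(gb, c), "Nst")

    klasses = ["CBC", "hCBC", "Nst", "indel"]
    by_pair: dict[tuple, dict] = {}
    by_helix: dict[str, dict] = {}
    for ev in events:
        key = (ev.a, ev.b)
        by_pair.setdefault(key, {k: 0 for k in klasses})[ev.klass] += 1
        hkey = ev.helix or "loop"
        by_helix.setdefault(hkey, {k: 0 for k in klasses})[ev.klass] += 1
    pair_df = pd.DataFrame.from_dict(by_pair, orient="index", columns=klasses).fillna(0).astype(int)
    helix_df = pd.DataFrame.from_dict(by_helix, orient="index", columns=klasses).fillna(0).astype(int)
    tables = {"by_pair": pair_df, "by_helix": helix_df}
    if mode == "group_level":
        tables["exceptions"] = exceptions
    return events, tables


def cbc_matrix(events: Iterable[ChangeEvent], taxa: Sequence[str]) -> pd.DataFrame:
    """Symmetric taxon x taxon matrix of CBC event counts (zero diagonal)."""
    m = pd.DataFrame(np.zeros((len(taxa), len(taxa)), dtype=int), index=taxa, columns=taxa)
    for ev in events:
        if ev.klass != "CBC":
            continue
        m.loc[ev.a, ev.b] += 1
        m.loc[ev.b, ev.a] += 1
    return m


def events_to_dataframe(events: Iterable[ChangeEvent]) -> pd.DataFrame:
    """Event catalog with 1-based positions, ready for CSV export."""
    rows = []
    for ev in events:
        rows.append({
            "a": ev.a,
            "b": ev.b,
            "aligned_col": ev.aligned_col + 1,
            "partner_col": (ev.partner_col + 1) if ev.partner_col is not None else "",
            "pos_a": (ev.pos_a + 1) if ev.pos_a is not None else "",
            "pos_b": (ev.pos_b + 1) if ev.pos_b is not None else "",
            "helix": ev.helix,
            "state_a": ":".join(x if x else "-" for x in ev.state_a),
            "state_b": ":".join(x if x else "-" for x in ev.state_b),
            "class": ev.klass,
        })
    return pd.DataFrame(rows, columns=["a", "b", "aligned_col", "partner_col", "pos_a",
                                       "pos_b", "helix", "state_a", "state_b", "class"])
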