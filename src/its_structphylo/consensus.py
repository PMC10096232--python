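"""Per-group consensus sequence-structures and per-helix statistics.

The consensus base of a column is the minimal IUPAC code covering the bases
observed in the group (gapped rows abstain per column); per-column
conservation is the plurality fraction.  Consensus pairs are column pairs
structurally complementary in a majority of members; the subset present with
an allowed pairing in every ungapped member is reported separately as the
100%-conserved pair set, matching the convention of reporting both a
consensus structure and its fully conserved core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import ALLOWED_PAIRS, IUPAC_CODES
from .seqstruct_align import SeqStructAlignment

__all__ = ["ConsensusModel", "build_consensus", "helix_stats", "iupac_code"]

_CODE_OF = {frozenset(v): k for k, v in IUPAC_CODES.items()}
_TRANSITIONS = {frozenset("AG"), frozenset("CU")}


def iupac_code(bases) -> str:
    """Minimal IUPAC code covering a non-empty set of unambiguous bases."""
    key = frozenset(bases)
    if not key:
        raise ValueError("empty base set")
    return _CODE_OF[key]


@dataclass
class ConsensusModel:
    group: str
    members: list
    consensus_seq: str  # IUPAC; '-' where every member is gapped
    consensus_pairs: list  # column pairs complementary in >= pair_threshold of members
    conserved_pairs_100: list  # subset with an allowed pair in every ungapped member
    conservation: list  # per column, plurality fraction among ungapped members

    def __post_init__(self):
        if not set(self.conserved_pairs_100) <= set(self.consensus_pairs):
            raise ValueError("conserved_pairs_100 must be a subset of consensus_pairs")


def build_consensus(aln: SeqStructAlignment, group_members, group: str = "all",
                    pair_threshold: float = 0.5) -> ConsensusModel:
    """Consensus model for ``group_members`` of a joint alignment."""
    members = [t for t in aln.taxa if t in set(group_members)]
    if len(members) < 2:
        raise ValueError("consensus needs at least 2 group members")
    width = aln.width
    seq_chars: list[str] = []
    conservation: list[float] = []
    for c in range(width):
        bases = [aln.rows[t][c][0] for t in members if aln.rows[t][c] is not None]
        if not bases:
            seq_chars.append("-")
            conservation.append(0.0)
            continue
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        unambiguous = [b for b in bases if b in "ACGU"]
        seq_chars.append(iupac_code(unambiguous) if unambiguous else "N")
        conservation.append(max(counts.values()) / len(bases))

    # member pairing in column coordinates
    member_pairs: dict[str, dict[int, int]] = {}
    for t in members:
        inv = aln.inverse_col_map(t)
        mp = {}
        for i, j in aln.records[t].pairs:
            if i in inv and j in inv:
                mp[inv[i]] = inv[j]
        member_pairs[t] = mp

    votes: dict[tuple[int, int], int] = {}
    ungapped: dict[int, int] = {}
    for t in members:
        for p, q in member_pairs[t].items():
            votes[(p, q)] = votes.get((p, q), 0) + 1
    for c in range(width):
        ungapped[c] = sum(1 for t in members if aln.rows[t][c] is not None)

    consensus_pairs = sorted(
        pq for pq, v in votes.items()
        if ungapped[pq[0]] and v / ungapped[pq[0]] >= pair_threshold)

    conserved_100 = []
    for p, q in consensus_pairs:
        ok = True
        for t in members:
            sp, sq = aln.rows[t][p], aln.rows[t][q]
            if sp is None or sq is None:
                continue  # gapped member abstains
            if member_pairs[t].get(p) != q or (sp[0], sq[0]) not in ALLOWED_PAIRS:
                ok = False
                break
        if ok:
            conserved_100.append((p, q))

    return ConsensusModel(group=group, members=members, consensus_seq="".join(seq_chars),
                          consensus_pairs=consensus_pairs,
                          conserved_pairs_100=conserved_100, conservation=conservation)


def helix_stats(model: ConsensusModel, decomposition, aln: SeqStructAlignment) -> pd.DataFrame:
    """Per-helix statistics of a group consensus.

    length: pairs in the helix; gc_fraction / gu_fraction: fraction of helix
    pairs whose consensus bases form G:C / G:U; variability: columns of the
    helix span with two or more observed states over span columns; ti / tv:
    per column, each unordered pair of distinct observed bases counts one
    transition (A<->G, C<->U) or transversion.
    """
    members = model.members
    rows = []
    units = list(decomposition.helices)
    if decomposition.proximal_stem:
        units.append(("skeleton", decomposition.proximal_stem))
    for unit in units:
        if isinstance(unit, tuple):
            label, pairs = unit
            span = range(min(i for i, _ in pairs), max(j for _, j in pairs) + 1)
        else:
            label, pairs = unit.label, unit.pairs
            span = range(unit.fiveprime_arm[0], unit.threeprime_arm[1])
        gc = gu = 0
        for p, q in pairs:
            bp = frozenset((model.consensus_seq[p], model.consensus_seq[q]))
            if bp == frozenset("GC"):
                gc += 1
            elif bp == frozenset("GU"):
                gu += 1
        variant = 0
        ti = tv = 0
        ncols = 0
        for c in span:
            if c >= len(model.consensus_seq):
                continue
            ncols += 1
            obs = {aln.rows[t][c][0] for t in members if aln.rows[t][c] is not None}
            obs &= set("ACGU")
            if len(obs) >= 2:
                variant += 1
                obs_sorted = sorted(obs)
                for a_i in range(len(obs_sorted)):
                    for b_i in range(a_i + 1, len(obs_sorted)):
                        if frozenset((obs_sorted[a_i], obs_sorted[b_i])) in _TRANSITIONS:
                            ti += 1
                        else:
                            tv += 1
        npairs = len(pairs)
        rows.append({
            "helix": label,
            "length": npairs,
            "gc_fraction": gc / npairs if npairs else 0.0,
            "gu_fraction": gu / npairs if npairs else 0.0,
            "variability": variant / ncols if ncols else 0.0,
            "ti": ti,
            "tv": tv,
        })
    return pd.DataFrame(rows).set_index("helix")
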