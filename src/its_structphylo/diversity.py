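"""GC content, DnaSP-style diversity indices, and group mean distances.

Distances default to the p-distance with pairwise deletion of gaps (the
convention of standard distance tables); a Kimura two-parameter option is
provided for sensitivity.  Standard errors of group means come from a seeded
bootstrap over alignment columns.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GroupMap

__all__ = [
    "gc_content",
    "DiversityReport",
    "diversity_indices",
    "pairwise_distance_matrix",
    "DistanceTable",
    "group_distances",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CU")}
_BASES = set("ACGU")


def gc_content(seq_or_seqs, per: str = "record"):
    """GC fraction: (G+C)/(A+C+G+U); ambiguity codes and gaps are excluded
    from numerator and denominator.

    ``per="record"`` on a string returns a float; on a list, a dict id-less
    list of floats; ``per="group"`` with ``(seqs, groups)`` handled by the
    caller via means of member values.
    """
    def one(s: str) -> float:
        if not s:
            raise ValueError("empty sequence")
        counted = [b for b in s.upper().replace("T", "U") if b in _BASES]
        if not counted:
            raise ValueError("sequence has no unambiguous bases")
        return sum(1 for b in counted if b in "GC") / len(counted)

    if isinstance(seq_or_seqs, str):
        return one(seq_or_seqs)
    vals = [one(s) for s in seq_or_seqs]
    if per == "group":
        return float(np.mean(vals))
    return vals


@dataclass
class DiversityReport:
    label: str
    n: int
    S: int  # segregating (polymorphic) sites
    Pi: float  # nucleotide diversity per site
    parsimony_informative: int
    singletons: int
    Eta: int  # total number of mutations
    haplotypes: int
    hap_diversity: float  # Nei's h
    indel_sites: int
    indel_haplotypes: int

    def __post_init__(self):
        if self.S < self.parsimony_informative or self.Eta < self.S:
            raise ValueError("inconsistent diversity indices")
        if not (0.0 <= self.hap_diversity <= 1.0 and self.Pi >= 0.0):
            raise ValueError("indices out of range")


def diversity_indices(seqs: Sequence[str], label: str = "") -> DiversityReport:
    """DnaSP-style indices on aligned sequences ('-' gaps).

    Pi averages, over all sequence pairs, the per-pair proportion of
    differing sites among sites where both are ungapped (pairwise deletion).
    Eta counts, per segregating site, every base beyond the first (number of
    distinct bases minus one).  Haplotypes are distinct aligned sequences;
    Nei's h = n(1 - sum p_i^2)/(n - 1).  Indel sites are columns where gap
    presence varies; indel haplotypes are the distinct gap presence/absence
    patterns over those columns.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    seqs = [s.upper().replace("T", "U") for s in seqs]

    S = eta = informative = singletons = 0
    for c in range(L):
        col = [s[c] for s in seqs if s[c] in _BASES]
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        if len(counts) >= 2:
            S += 1
            eta += len(counts) - 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative += 1
            if len(counts) == 2 and min(counts.values()) == 1:
                singletons += 1

    diffs = []
    for a, b in combinations(seqs, 2):
        comp = diff = 0
        for x, y in zip(a, b):
            if x in _BASES and y in _BASES:
                comp += 1
                if x != y:
                    diff += 1
        diffs.append(diff / comp if comp else 0.0)
    pi = float(np.mean(diffs))

    hap_counts: dict[str, int] = {}
    for s in seqs:
        hap_counts[s] = hap_counts.get(s, 0) + 1
    k = len(hap_counts)
    h = (n * (1.0 - sum((v / n) ** 2 for v in hap_counts.values())) / (n - 1)) if k > 1 else 0.0

    indel_cols = [c for c in range(L)
                  if 0 < sum(1 for s in seqs if s[c] == "-") < n]
    indel_patterns = {tuple(s[c] == "-" for c in indel_cols) for s in seqs}
    indel_haps = len(indel_patterns) if indel_cols else 1

    return DiversityReport(label=label, n=n, S=S, Pi=pi,
                           parsimony_informative=informative, singletons=singletons,
                           Eta=eta, haplotypes=k, hap_diversity=h,
                           indel_sites=len(indel_cols), indel_haplotypes=indel_haps)


def _pair_distance(a: str, b: str, cols: Sequence[int], model: str) -> float:
    comp = diff = ts = 0
    for c in cols:
        x, y = a[c], b[c]
        if x in _BASES and y in _BASES:
            comp += 1
            if x != y:
                diff += 1
                if frozenset((x, y)) in _TRANSITIONS:
                    ts += 1
    if comp == 0:
        return float("nan")
    if model == "p_distance":
        return diff / comp
    if model == "k2p":
        P = ts / comp
        Q = (diff - ts) / comp
        try:
            return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        except ValueError:
            return float("nan")
    raise ValueError(f"unknown distance model {model!r}")


def pairwise_distance_matrix(rows: Mapping[str, str], model: str = "p_distance",
                             cols: Sequence[int] | None = None):
    """Taxon-by-taxon distance matrix from aligned base strings."""
    taxa = list(rows)
    L = len(next(iter(rows.values())))
    cols = list(range(L)) if cols is None else list(cols)
    d = np.zeros((len(taxa), len(taxa)))
    for i, j in combinations(range(len(taxa)), 2):
        d[i, j] = d[j, i] = _pair_distance(rows[taxa[i]], rows[taxa[j]], cols, model)
    return d, taxa


@dataclass
class DistanceTable:
    between: pd.DataFrame  # symmetric group x group mean distances
    between_se: pd.DataFrame | None
    within: pd.Series  # per-group mean (NaN for groups of size < 2)
    within_se: pd.Series | None


def group_distances(rows: Mapping[str, str], groups: GroupMap,
                    model: str = "p_distance", se_reps: int = 1000,
                    seed: int = 0) -> DistanceTable:
    """Within- and between-group mean distances with bootstrap SEs.

    ``rows`` maps taxon to aligned base string.  The between-group mean
    averages the pairwise distances over all cross-group taxon pairs; the
    within-group mean over intra-group pairs (not applicable, NaN, for
    singleton groups).  With ``se_reps > 0``, standard errors are the
    standard deviations of the group means over ``se_reps`` bootstrap
    resamplings of alignment columns, seeded for reproducibility.
    """
    for t in rows:
        groups.group_of(t)
    if se_reps < 0:
        raise ValueError("se_reps must be >= 0")
    glabels = sorted(set(groups.assignments[t] for t in rows))
    members = {g: sorted(t for t in rows if groups.assignments[t] == g) for g in glabels}
    L = len(next(iter(rows.values())))

    def means(cols):
        between = pd.DataFrame(np.nan, index=glabels, columns=glabels)
        within = pd.Series(np.nan, index=glabels)
        for gi, gj in combinations(glabels, 2):
            vals = [_pair_distance(rows[a], rows[b], cols, model)
                    for a in members[gi] for b in members[gj]]
            vals = [v for v in vals if not math.isnan(v)]
            m = float(np.mean(vals)) if vals else float("nan")
            between.loc[gi, gj] = between.loc[gj, gi] = m
        for g in glabels:
            if len(members[g]) < 2:
                continue
            vals = [_pair_distance(rows[a], rows[b], cols, model)
                    for a, b in combinations(members[g], 2)]
            vals = [v for v in vals if not math.isnan(v)]
            within[g] = float(np.mean(vals)) if vals else float("nan")
        np.fill_diagonal(between.values, 0.0)
        return between, within

    base_cols = list(range(L))
    between, within = means(base_cols)
    between_se = within_se = None
    if se_reps > 0:
        rng = random.Random(seed)
        bs_between, bs_within = [], []
        for _ in range(se_reps):
            cols = [rng.randrange(L) for _ in range(L)]
            b, w = means(cols)
            bs_between.append(b.values)
            bs_within.append(w.values)
        between_se = pd.DataFrame(np.nanstd(np.array(bs_between), axis=0, ddof=1),
                                  index=glabels, columns=glabels)
        within_se = pd.Series(np.nanstd(np.array(bs_within), axis=0, ddof=1),
                              index=glabels)
    return DistanceTable(between=between, between_se=between_se,
                         within=within, within_se=within_se)
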