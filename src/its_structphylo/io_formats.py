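"""Canonical data model and readers/writers for the formats the pipeline touches.

Sequences are held as RNA (``U`` canonical); DNA input is transcribed on read.
Secondary structures are nested sets of 0-based base-pair index tuples,
interconvertible with single-level dot-bracket (Vienna) notation.  Trees are
:class:`dendropy.Tree` objects; Newick round-trips preserve branch lengths and
internal-node support labels.

Coordinates are 0-based half-open internally; human-readable reports are
1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "Region",
    "StructSource",
    "SeqStructRecord",
    "RegionAnnotation",
    "MotifHit",
    "GroupMap",
    "IUPAC_CODES",
    "ALLOWED_PAIRS",
    "parse_fasta",
    "write_fasta",
    "dotbracket_to_pairs",
    "pairs_to_dotbracket",
    "read_vienna",
    "write_vienna",
    "read_newick",
    "write_newick",
    "read_group_map",
    "write_group_map",
]

# IUPAC nucleotide one-letter codes (RNA form) -> set of unambiguous bases
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

#: Watson-Crick plus wobble pairs, as unordered base tuples.
ALLOWED_PAIRS: frozenset[tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


class Region(str, Enum):
    ITS1 = "ITS1"
    FIVE_EIGHT_S = "5.8S"
    ITS2 = "ITS2"
    FULL_ITS = "FULL_ITS"
    OTHER = "OTHER"


class StructSource(str, Enum):
    FOLDED_INTERNAL = "folded_internal"
    FOLDED_EXTERNAL = "folded_external"
    TEMPLATE_MODELED = "template_modeled"
    USER_SUPPLIED = "user_supplied"


class FormatError(ValueError):
    """Raised on malformed input files or structure strings."""


def _check_pairs(pairs: Iterable[tuple[int, int]], length: int) -> frozenset[tuple[int, int]]:
    pairs = frozenset((int(i), int(j)) for i, j in pairs)
    seen: set[int] = set()
    for i, j in pairs:
        if not 0 <= i < j < length:
            raise ValueError(f"pair ({i},{j}) out of range for length {length}")
        if j - i < 4:
            raise ValueError(f"pair ({i},{j}) violates minimum hairpin size (j-i >= 4)")
        if i in seen or j in seen:
            raise ValueError(f"index in pair ({i},{j}) participates in more than one pair")
        seen.update((i, j))
    ordered = sorted(pairs)
    for a in range(len(ordered)):
        i, j = ordered[a]
        for k, l in ordered[a + 1 :]:
            if k > j:
                break
            if i < k < j < l:
                raise ValueError(f"pairs ({i},{j}) and ({k},{l}) cross (pseudoknot)")
    return pairs


@dataclass(frozen=True)
class SeqStructRecord:
    """One sequence with an optional nested secondary structure.

    Parameters
    ----------
    id : str
        Record identifier, preserved verbatim from input.
    seq : str
        RNA sequence (uppercase, ``U`` canonical; IUPAC ambiguity codes allowed).
    pairs : frozenset of (int, int)
        Nested base pairs, 0-based, ``i < j``, hairpin loops of at least three
        unpaired bases.
    region : Region
        Which part of the rDNA cistron the record covers.
    energy : float or None
        Free energy in kcal/mol when produced by a thermodynamic backend;
        ``None`` otherwise.
    score : float or None
        Arbitrary-unit score from the internal folding engine.
    source : StructSource
        Provenance of the structure.
    """

    id: str
    seq: str
    pairs: frozenset = frozenset()
    region: Region = Region.OTHER
    energy: float | None = None
    score: float | None = None
    source: StructSource = StructSource.USER_SUPPLIED

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "pairs", _check_pairs(self.pairs, len(self.seq)))

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def partner(self) -> dict[int, int]:
        """Map every paired index to its partner."""
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def dotbracket(self) -> str:
        return pairs_to_dotbracket(self.pairs, len(self.seq))

    def with_(self, **kw) -> "SeqStructRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    pattern: str
    start: int
    end: int  # half-open
    mismatches: int = 0
    spacer_len: int | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("motif hit must have end > start")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")


@dataclass
class RegionAnnotation:
    """ITS1/5.8S/ITS2 intervals for one record, with anchor evidence.

    ``intervals`` maps :class:`Region` to 0-based half-open ``(start, end)``;
    ``unresolved`` lists boundary names whose anchor was not found within its
    mismatch budget; ``trims`` records signed nt offsets between an external
    annotation convention and the anchor-based one (positive = external
    boundary lies upstream of the anchor-based one).
    """

    record_id: str
    intervals: dict[Region, tuple[int, int]]
    anchors: list[MotifHit] = field(default_factory=list)
    trims: dict[Region, int] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        ivs = self.intervals
        for r, (s, e) in ivs.items():
            if e <= s:
                raise ValueError(f"empty interval for {r}")
        order = [Region.ITS1, Region.FIVE_EIGHT_S, Region.ITS2]
        present = [r for r in order if r in ivs]
        for a, b in zip(present, present[1:]):
            if ivs[a][1] > ivs[b][0]:
                raise ValueError(f"intervals for {a.value} and {b.value} overlap or are out of order")

    def subsequence(self, seq: str, region: Region) -> str:
        s, e = self.intervals[region]
        return seq[s:e]


@dataclass
class GroupMap:
    """Taxon id -> group label assignment."""

    assignments: dict[str, str]

    def __post_init__(self):
        for t, g in self.assignments.items():
            if not g:
                raise ValueError(f"empty group label for taxon {t!r}")

    def group_of(self, taxon: str) -> str:
        try:
            return self.assignments[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no group assignment") from None

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for t, g in self.assignments.items():
            out.setdefault(g, []).append(t)
        return out


# ---------------------------------------------------------------------------
# FASTA


def _clean_seq(raw: str, record_id: str, alphabet_policy: str) -> str:
    allowed = set("ACGU") if alphabet_policy == "strict" else set(IUPAC_CODES)
    out = []
    for pos, ch in enumerate(raw):
        c = ch.upper()
        if c == "T":
            c = "U"
        if c not in allowed:
            raise FormatError(
                f"record {record_id!r}: non-{'ACGU' if alphabet_policy == 'strict' else 'IUPAC'} "
                f"character {ch!r} at position {pos}"
            )
        out.append(c)
    return "".join(out)


def parse_fasta(path, alphabet_policy: str = "iupac", region: Region = Region.OTHER) -> list[SeqStructRecord]:
    """Read a multi-FASTA file into :class:`SeqStructRecord` objects.

    DNA is transcribed (T -> U) and lowercase is uppercased; records carry an
    empty pair set.  Duplicate ids and non-IUPAC characters raise
    :class:`FormatError` (with ``alphabet_policy="strict"`` only unambiguous
    A/C/G/U/T are accepted).
    """
    text = Path(path).read_text()
    records: list[SeqStructRecord] = []
    seen: set[str] = set()
    rid: str | None = None
    chunks: list[str] = []

    def flush():
        if rid is None:
            return
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r}")
        seen.add(rid)
        seq = _clean_seq("".join(chunks), rid, alphabet_policy)
        records.append(SeqStructRecord(id=rid, seq=seq, region=region))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            rid = line[1:].strip()
            if not rid:
                raise FormatError("FASTA header with empty id")
            chunks = []
        else:
            if rid is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line)
    flush()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SeqStructRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


# ---------------------------------------------------------------------------
# Dot-bracket


def dotbracket_to_pairs(db: str) -> frozenset:
    """Parse single-level dot-bracket notation into a set of index pairs.

    Raises :class:`FormatError` at the index of the first unbalanced bracket;
    pseudoknot bracket levels ([], {}) are rejected.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at index {idx}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise FormatError(f"invalid dot-bracket character {ch!r} at index {idx}")
    if stack:
        raise FormatError(f"unbalanced '(' at index {stack[0]}")
    return frozenset(pairs)


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# Vienna structure files: 3 lines per record (">id", sequence, structure [(energy)])


def read_vienna(path, region: Region = Region.OTHER,
                source: StructSource = StructSource.USER_SUPPLIED) -> list[SeqStructRecord]:
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) % 3 != 0:
        raise FormatError(f"Vienna file {path} is not made of 3-line records")
    out: list[SeqStructRecord] = []
    seen: set[str] = set()
    for k in range(0, len(lines), 3):
        header, seq, struct = lines[k], lines[k + 1], lines[k + 2]
        if not header.startswith(">"):
            raise FormatError(f"expected '>' header at line {k + 1} of {path}")
        rid = header[1:].strip()
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r}")
        seen.add(rid)
        energy = None
        db = struct.strip()
        m = re.search(r"\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)$", db)
        if m:
            energy = float(m.group(1))
            db = db[: m.start()].strip()
        seq = _clean_seq(seq.strip(), rid, "iupac")
        if len(db) != len(seq):
            raise FormatError(f"record {rid!r}: structure length {len(db)} != sequence length {len(seq)}")
        out.append(SeqStructRecord(id=rid, seq=seq, pairs=dotbracket_to_pairs(db),
                                   region=region, energy=energy, source=source))
    return out


def write_vienna(records: Sequence[SeqStructRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            line = r.dotbracket()
            if r.energy is not None:
                line += f" ({r.energy:.2f})"
            fh.write(f">{r.id}\n{r.seq}\n{line}\n")


# ---------------------------------------------------------------------------
# Newick / trees


def read_newick(path_or_string) -> dendropy.Tree:
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        src = {"data": s}
    else:
        src = {"path": s}
    tree = dendropy.Tree.get(schema="newick", suppress_internal_node_taxa=True, **src)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree as Newick with branch lengths and internal support labels.

    Branch lengths are written to 6 decimals; internal-node support values
    (``node.label`` or dendropy bipartition support) become internal labels.
    """
    if tree is None or tree.seed_node is None or not any(
            lf.taxon is not None for lf in tree.leaf_node_iter()):
        raise ValueError("cannot write an empty tree")
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    Path(path).write_text(s.strip() + "\n")


# ---------------------------------------------------------------------------
# Group map TSV


def read_group_map(path) -> GroupMap:
    assignments: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"group map line {lineno}: expected 'taxon<TAB>group'")
        taxon, grp = parts
        if taxon in assignments:
            raise FormatError(f"group map line {lineno}: duplicate taxon {taxon!r}")
        assignments[taxon] = grp
    if not assignments:
        raise FormatError(f"no assignments in group map {path}")
    return GroupMap(assignments)


def write_group_map(gm: GroupMap, path) -> None:
    with open(path, "w") as fh:
        for t, g in gm.assignments.items():
            fh.write(f"{t}\t{g}\n")
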