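"""Template-based structure transfer and helix decomposition.

ITS2 secondary structures across related taxa are strongly homologous, so
instead of folding every sequence de novo a curated template structure is
transferred onto each target: the target is globally aligned to the template
sequence and a template pair carries over whenever both of its columns align
to target bases that can still form an allowed pair (AU, GC, or GU/wobble).
This mirrors the "custom modeling" approach of ITS2 structure databases.

Structures are decomposed into helices around the central loop: a helix is a
maximal stack of directly nested pairs interrupted only by small bulges or
internal loops, helices hanging off the outermost multiloop are numbered
I, II, ... in 5'->3' order, and the stem that closes that multiloop (formed by
the 5.8S/28S flanks in full-length ITS2 models) is the proximal stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .io_formats import ALLOWED_PAIRS, SeqStructRecord, StructSource

__all__ = ["HelixDecomposition", "Helix", "model_from_template", "enumerate_helices"]


class TemplateTooDistantError(ValueError):
    pass


@dataclass
class Helix:
    label: str
    pairs: list  # all pairs of the subtree rooted at this helix's outermost pair
    fiveprime_arm: tuple[int, int]  # half-open interval of 5' arm of the stem run
    threeprime_arm: tuple[int, int]


@dataclass
class HelixDecomposition:
    proximal_stem: list = field(default_factory=list)
    helices: list = field(default_factory=list)  # list[Helix], 5'->3'
    central_loop: set = field(default_factory=set)

    def all_pairs(self) -> frozenset:
        out = set(self.proximal_stem)
        for h in self.helices:
            out.update(h.pairs)
        return frozenset(out)

    def helix_of(self, index: int) -> str | None:
        """Label of the helix whose span contains ``index`` (paired or not);
        ``"skeleton"`` for the proximal stem span outside all helices; ``None``
        if the index lies in no helix span (central loop / exterior)."""
        if index in self.central_loop:
            return None
        for h in self.helices:
            if h.fiveprime_arm[0] <= index < h.threeprime_arm[1]:
                return h.label
        if self.proximal_stem:
            i0 = min(i for i, _ in self.proximal_stem)
            j1 = max(j for _, j in self.proximal_stem)
            if i0 <= index <= j1:
                return "skeleton"
        return None


def _make_aligner(match: float = 2.0, mismatch: float = -1.0,
                  gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def model_from_template(target: str, template: SeqStructRecord, min_identity: float = 0.75,
                        aligner: Align.PairwiseAligner | None = None,
                        record_id: str | None = None) -> SeqStructRecord:
    """Transfer the template's base pairs onto a target sequence.

    The target is globally aligned to the template; a template pair (i, j)
    transfers iff both columns align to target bases (no gap) and those bases
    form an allowed pair.  Alignment identity (matches / aligned ungapped
    columns) below ``min_identity`` raises :class:`TemplateTooDistantError`.
    """
    if not target or not template.seq:
        raise ValueError("empty target or template sequence")
    if not 0.0 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0, 1]")
    aligner = aligner or _make_aligner()
    aln = max(aligner.align(template.seq, target),
              key=lambda a: (a.score,))  # biopython returns best-first; max for safety
    # column-wise template index -> target index map
    tpl_to_tgt: dict[int, int] = {}
    matches = 0
    compared = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for off in range(te - ts):
            ti, qi = ts + off, qs + off
            tpl_to_tgt[ti] = qi
            compared += 1
            if template.seq[ti] == target[qi]:
                matches += 1
    identity = matches / compared if compared else 0.0
    if identity < min_identity:
        raise TemplateTooDistantError(
            f"template too distant: identity {identity:.3f} < min_identity {min_identity}")
    pairs = set()
    for i, j in template.pairs:
        qi, qj = tpl_to_tgt.get(i), tpl_to_tgt.get(j)
        if qi is None or qj is None:
            continue
        if (target[qi], target[qj]) in ALLOWED_PAIRS and qj - qi >= 4:
            pairs.add((qi, qj))
    return SeqStructRecord(
        id=record_id or f"{template.id}-modeled",
        seq=target,
        pairs=frozenset(pairs),
        region=template.region,
        source=StructSource.TEMPLATE_MODELED,
    )


def _pair_tree(pairs: list):
    """Nesting forest over sorted pairs: returns (children, roots)."""
    children: dict[tuple[int, int], list] = {p: [] for p in pairs}
    roots: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        (children[stack[-1]] if stack else roots).append(p)
        stack.append(p)
    return children, roots


def _stem_run(root: tuple[int, int], children, bulge_bound: int) -> list:
    """Maximal run of directly nested pairs from ``root``, merging across
    bulges/internal loops of at most ``bulge_bound`` unpaired nt per strand."""
    run = [root]
    cur = root
    while len(children[cur]) == 1:
        (c,) = children[cur]
        if (c[0] - cur[0] - 1) > bulge_bound or (cur[1] - c[1] - 1) > bulge_bound:
            break
        run.append(c)
        cur = c
    return run


def enumerate_helices(record: SeqStructRecord, bulge_bound: int = 6) -> HelixDecomposition:
    """Decompose a structure into the proximal stem, numbered helices, and the
    central loop.

    The nesting forest of pairs is computed first.  If there is a single
    outermost stem whose unbranched trunk ends at a multiloop with two or
    more branches, that trunk is the proximal stem and each branch becomes a
    numbered helix (I, II, ... in 5'->3' order); otherwise the top-level
    branches themselves are the numbered helices.  A numbered helix owns every
    pair of its subtree (so the decomposition partitions the pair set); its
    arm intervals come from the maximal stem run at its root, merging across
    bulges/internal loops of at most ``bulge_bound`` unpaired nt per strand.
    The central loop is the set of unpaired positions of the multiloop (or the
    exterior, when there is no proximal stem) not covered by any helix span.
    """
    if not record.pairs:
        raise ValueError("unstructured record: empty pair set")
    pairs = sorted(record.pairs)
    children, roots = _pair_tree(pairs)
    partner = record.partner

    proximal: list = []
    branch_roots: list[tuple[int, int]]
    if len(roots) == 1:
        # follow the unbranched trunk from the single root
        trunk = [roots[0]]
        while len(children[trunk[-1]]) == 1:
            trunk.append(children[trunk[-1]][0])
        if len(children[trunk[-1]]) >= 2:
            proximal = trunk
            branch_roots = children[trunk[-1]]
        else:
            branch_roots = roots
    else:
        branch_roots = roots

    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    prox_set = set(proximal)
    helices: list[Helix] = []
    for n, broot in enumerate(sorted(branch_roots)):
        oi, oj = broot
        subtree = [(i, j) for i, j in pairs
                   if oi <= i and j <= oj and (i, j) not in prox_set]
        run = _stem_run(broot, children, bulge_bound)
        ci, cj = run[-1]
        label = roman[n] if n < len(roman) else str(n + 1)
        helices.append(Helix(label=label, pairs=subtree,
                             fiveprime_arm=(oi, ci + 1), threeprime_arm=(cj, oj + 1)))
    if proximal:
        lo, hi = proximal[-1][0] + 1, proximal[-1][1]
    else:
        lo, hi = 0, len(record.seq)
    spans = [(h.fiveprime_arm[0], h.threeprime_arm[1]) for h in helices]
    central = {k for k in range(lo, hi)
               if k not in partner and not any(a <= k < b for a, b in spans)}
    return HelixDecomposition(proximal_stem=proximal, helices=helices, central_loop=central)
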