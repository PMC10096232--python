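# Methods

## Data model

Sequences are RNA internally (`T` is transcribed to `U` on read). A
`SeqStructRecord` couples a sequence with a nested set of base pairs
(0-based, `i < j`, no pseudoknots, hairpin loops of at least three unpaired
nucleotides) and, optionally, a free energy. Human-readable reports use
1-based inclusive coordinates; everything internal is 0-based half-open.
Allowed pairs throughout are the Watson-Crick pairs plus the G-U wobble.

## Region annotation

ITS1, 5.8S, and ITS2 are located inside a full amplicon by conserved motif
anchors rather than profile HMMs: 5.8S Motif I (`CGAUGAAGAACGUAGC`) marks the
5.8S start, the conserved `CAUAU` pentamer marks the 5.8S–ITS2 boundary, and
a configurable 28S proximal-stem anchor marks the ITS2 end. Each anchor has
a mismatch budget (1 for the 16-mer Motif I, 0 for the short boundary
pentamer, whose degeneracy would otherwise produce spurious hits) and a ±30 nt
search window centred on the position expected from nominal region lengths
(ITS1 240, 5.8S 161, ITS2 222 nt). Multiple in-window hits resolve to the
leftmost with a warning; a missing anchor leaves its boundary **unresolved**
rather than guessed, and a record with no anchors at all is an error.

`harmonize_boundaries` reconciles an external annotation convention with the
anchor-based one: the anchor-based intervals are kept and the signed per-region
offset is recorded (positive = the external boundary lies upstream, i.e.
nucleotides are pruned when adopting the anchor convention). Because a
disagreement can in principle affect both edges of a region, the second edge's
offset is reported through the warnings channel instead of being folded into
one number.

## Folding

The internal engine maximizes a configurable pairing score over all nested
structures: V(i,j) (best score with (i,j) paired) and W(i,j) (best score on
[i,j]) recursions with pair scores GC=3, AU=2, GU=1 and a stacking bonus of 1
for directly stacked pairs (a `pair_count` mode scores every pair 1). The
minimum hairpin is 3 unpaired nt. Traceback is deterministic: at each
position pairing is preferred over leaving the base unpaired, taking the
smallest closing index among ties. The optimum is reported in **arbitrary
score units**: free energies in kcal/mol are only meaningful under the full
nearest-neighbor model, so they are emitted solely by the external backend
(ViennaRNA's MFE fold), which is an explicit error — never a silent
fallback — when unavailable. ITS2 folding first appends 25 nt of 5.8S and
28S flank so the proximal stem can form; structure indices map back to
spacer coordinates through the returned offset.

## Template-based homology modeling

ITS2 structures across a tribe-level dataset are transferred from one
template rather than folded independently. The target is globally aligned to
the template sequence (match 2, mismatch −1, gap open −5, extend −1); a
template pair (i,j) carries over iff both columns align gap-free to target
bases that form an allowed pair. Alignment identity (matches over aligned
ungapped columns) below `min_identity = 0.75` aborts with "template too
distant". Transfer is idempotent on the template itself, and a family evolved
with only CBC/hCBC events — which by definition keep pairing allowed —
retains the template's pairs in full.

The packaged ITS2 template is a **synthetic** flank-extended structure built
to the canonical architectural constraints: a 12-bp proximal stem, four
helices (14, 15, 28, and 10 pairs) radiating from the central loop, a UGGU
block on the 5' side of Helix III near its apex, a U-U mismatch on both
strands of Helix II, and the conserved AAA spacer between helices II and
III. The packaged 5.8S template carries motifs I–III and four hairpins around
one central loop. Both are constructed programmatically so complementarity
and nesting hold by construction; real templates (e.g. a database-modeled
accession) can be supplied as Vienna files everywhere a template is accepted.

Helix decomposition builds the nesting forest of pairs. When a single
outermost trunk ends in a multiloop with ≥ 2 branches, the trunk is the
proximal stem and the branches are numbered I, II, … in 5'→3' order;
otherwise the top-level branches themselves are the numbered helices. A
numbered helix owns every pair of its subtree (the decomposition partitions
the pair set); its arm intervals come from the maximal directly-nested run at
its root, merged across bulges/internal loops of at most B = 6 unpaired nt
per strand — chosen so that small asymmetries (such as the Helix II U-U
mismatch) do not split a helix. Position-to-helix attribution uses helix
spans, so bulge and hairpin-loop positions count toward their enclosing
helix; only central-loop/exterior positions are "loop", and proximal-stem
positions are "skeleton".

## Joint sequence-structure alignment

Each position is encoded into one of 12 states (base × {unpaired, opening,
closing}). The pairwise substitution score is a sum of a sequence part
(match +2, transition −1, transversion −2) and a structure part (same role
+1, paired↔unpaired −2, opening↔closing −3), with affine gaps (open 5,
extend 1); these are declared parameters, not claims about any published
matrix. Multiple alignment is progressive: pairwise joint-state p-distances
feed an NJ guide tree (midpoint-rooted), and profiles are merged by
affine-gap profile DP with sum-of-pairs column scores. Manually curated
alignments can be loaded from paired FASTA (sequence row + structure row),
bypassing the aligner. Gapped rows abstain from a column's pairing votes:
`paired_columns` reports (p,q) when at least the threshold fraction (default
0.5 in the pipeline, 1.0 available) of rows ungapped at p open a pair whose
partner maps to q.

## Event classification

For two base-pair states the classifier returns **silent** (identical),
**CBC** (both partners differ, both states allowed pairs), **hCBC** (exactly
one partner differs, both states allowed), else **Nst**. It is symmetric and
total over the 256 ordered state pairs; an independently coded truth table
pins this down in the tests. Two deliberate choices:

- A single-partner change to a non-pair (e.g. U:A → C:A) is an **Nst**, not
  an hCBC — the defining property of an hCBC is that pairing survives. A
  `lenient` flag admits C:A/A:C as "weak pairs" for compatibility with more
  permissive published labelings.
- A double change to a non-pair (G:C → A:G) is one Nst event, not two.

Indels never count as substitutions; a gap/base contrast is logged as a
separate indel event. Group-level tabulation derives a per-group state per
site — shared by at least `group_threshold` (default 1.0, i.e. unanimity,
matching the per-taxon exception style of clade-level reporting) of the
ungapped members — and lists deviating members as exceptions instead of
majority-voting them away; polymorphic group-sites are excluded from the
contrast. Counts are reported per pair of taxa/groups and per helix.

## Consensus and statistics

The consensus base of a column is the minimal IUPAC code covering the
observed bases; gapped rows abstain per column (they are not mismatches).
Consensus pairs need a 0.5 majority of structurally pairing members; the
100%-conserved subset additionally requires an allowed pairing in *every*
ungapped member — both entities are reported because consensus structure and
fully-conserved core answer different questions. Helix statistics: length in
pairs, GC- and G-U-pair fractions of the consensus pairs, variability
(variant columns / span columns), and transition/transversion counts (each
unordered pair of distinct observed bases per column counts once).

Diversity indices follow the DnaSP conventions: segregating sites S,
parsimony-informative sites, singletons, total mutations Eta (distinct bases
minus one per segregating site), haplotype count and Nei's h =
n(1−Σp²)/(n−1), and indel sites/haplotypes from the gap presence/absence
matrix. Pi is the mean over sequence pairs of the per-pair difference
proportion with pairwise deletion of gaps. Group distances default to the
p-distance (the convention of standard distance tables; K2P is available for
sensitivity), with standard errors from a seeded bootstrap over alignment
columns (1000 replicates by default; the pipeline scales this down, see
below).

## Trees

Neighbor joining uses the standard Q criterion with two determinism rules:
ties resolve to the lowest (row, column) index pair, and a negative branch
length is clamped to zero with the deficit moved to its sibling so the
joined pair's path length is preserved. UPGMA is average linkage with the
same tie rule. Bootstrap support resamples alignment columns with
replacement, rebuilds the distance matrix and tree per replicate, and maps
bipartition frequencies (percent) onto the full tree; it is reproducible per
seed. Robinson-Foulds distance is the symmetric difference of non-trivial
bipartition sets. Likelihood tree search is out of scope; alignments export
in formats external ML tools accept, and their Newick results can be read
back for comparison.

## Synthetic families

The generator is the package's study-conditions instrument, not a tuning
knob. A root amplicon (ITS1 240 nt carrying the core motif, 5.8S 161 nt
carrying motifs I–III, ITS2 222 nt folding to the packaged template, 25 nt of
28S head) evolves along a known tree — either user-supplied Newick or a
random birth process rescaled to total length 3.0 by default, which yields on
the order of 20–40 events on an 8-taxon family, comparable to the variation a
tribe-level spacer alignment shows. Per branch, event counts are Poisson
(rate × branch length) per class with defaults CBC 1.0, hCBC 2.0,
pairing-breaking Nst 2.0, loop Nst 3.0, loop indel 0.8 per unit branch
length: compensatory changes rarer than neutral ones, indels rarest, loops
freer than stems. Events are placed uniformly over eligible sites, at most
one event per site per branch (a guard errors out when rates demand more than
`max_events_per_branch = 40`, advising lower rates). CBC/hCBC sites must
currently form an allowed pair; pairing-breaking substitutions always produce
a non-pair, so branch-wise classification of parent against child recovers
the planted class by construction. Indels are single-nucleotide and confined
to loops. Motif blocks, the whole 5.8S, and the 28S head are immutable unless
`pseudogene_rate` fires, in which case 5.8S Motif III is ablated (leaving the
annotation anchors intact so only the functional screen fails) and the
record is flagged. A global column registry tracks insertions, so the true
alignment, true paired columns, true region intervals, and a replayable
per-branch event log are all exact.

What the generator does **not** emulate: rate heterogeneity among sites or
lineages, multi-nucleotide indels, alignment ambiguity in repeat regions,
intra-genomic rDNA copy variation, and base-composition drift. Passing tests
therefore demonstrate correctness of the machinery under the stated model,
not robustness to every artifact of real GenBank data; real datasets are
supported through the replication path (FASTA + group map + optional
user template and user alignment).

The printed-exemplar set (`make_toy_cbc_set`) encodes published pair states
at five paired positions (39/70, 47/64, 85/113, 97/101, 148/186 in 1-based
unaligned coordinates) on otherwise identical records, giving a deterministic
micro-fixture for the classifier and the group-level exception logic.

## Pseudogene screen

A record passes iff 5.8S motifs I–III are present within a 1-mismatch
budget, the ITS1 core motif (`GGCGC`-(3–6 nt)-`GYGCCAAGGAA`) is present, and
each region's GC content lies in 45–60% and its length within bounds (5.8S
160–162 nt, ITS1 200–280, ITS2 200–240 by default; all configurable).
Reasons enumerate every failure, and the screen is monotone: relaxing a
bound can never turn a pass into a fail. The ambiguous literature convention
for the Motif II offset ("25 bases downstream of AAGAA") is reported from
both the start and the end of AAGAA.

## Numerical and scale choices

- All randomness funnels through explicit integer seeds; reruns are
  bit-identical for deterministic stages.
- DP tracebacks use tolerance 1e-9 equality to guard against float drift in
  averaged profile scores.
- The pipeline defaults to 200 bootstrap/SE replicates and the test suite
  and acceptance script use 6–8-taxon families and 10–50 seeds per property;
  these sizes already saturate the exact properties being checked (boundary
  recovery, planted-count equality, DP optimality), so larger runs add cost
  without information. The library-level defaults (1000 replicates) match
  the field's reporting convention.
- For simulated input the pipeline uses the generator's true alignment by
  default (`use_true_alignment`), isolating downstream stages from aligner
  error; re-alignment mode exercises the full path.

## Known limitations

- The internal folding engine is a maximization model; its scores are not
  free energies and are not comparable across sequences of different length.
- Progressive alignment is heuristic; no simultaneous alignment-and-folding
  is attempted, and very divergent families should use an external curated
  alignment.
- Group-level unanimity (threshold 1.0) goes silent at sites where any
  member deviates; this is intentional (exceptions are listed instead) but
  means group event counts are conservative.
- ITS1 has no packaged structural template; its decompositions are
  descriptive only.
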