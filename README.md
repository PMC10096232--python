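# its-structphylo

Sequence-structure analysis of the nuclear ribosomal internal transcribed
spacers (ITS1, 5.8S, ITS2) for phylogenetics and species delimitation.

The nrDNA ITS region evolves quickly in sequence but under strong secondary
structure constraint: the ITS2 of most eukaryotes folds into four helices
radiating from a central loop, closed by a proximal stem formed between the
3' end of 5.8S and the 5' end of 28S. Substitutions at paired sites therefore
fall into informative classes: a **compensatory base change (CBC)** replaces
both partners of a base pair while pairing stays allowed (e.g. U:G ↔ A:U), a
**hemi-CBC (hCBC)** replaces exactly one partner while pairing stays allowed
(U:A ↔ U:G), and a **non-structural substitution (Nst)** breaks pairing or
hits an unpaired site. These classes carry different phylogenetic signal —
CBCs at deep splits, hCBCs for species groups, Nsts between close species —
and conserved sequence motifs (the angiosperm ITS1 core motif, 5.8S motifs
I–III, the ITS2 UGGU block and U-U mismatch) let functional rDNA copies be
told apart from pseudogenes.

This package implements the full analysis as a tested pipeline:

- **io_formats** — FASTA / Vienna dot-bracket / Newick / group-map TSV I/O
  around a validated `SeqStructRecord` (nested pairs, hairpin ≥ 3 nt).
- **annotation** — ITS1/5.8S/ITS2 boundaries from conserved motif anchors
  (5.8S Motif I, the CAUAU 5.8S–ITS2 boundary, a 28S proximal-stem anchor),
  with trim bookkeeping against external annotation conventions.
- **folding** — internal base-pair-maximization DP (pair-count or stacking
  scores, arbitrary units) plus an optional ViennaRNA backend for real
  free energies; 25-nt 5.8S/28S flank augmentation for the proximal stem.
- **homology_model** — template-based structure transfer (a pair carries
  over iff its columns align gap-free onto bases that still form an allowed
  pair) and helix decomposition around the central loop.
- **seqstruct_align** — joint 12-state (4 bases × 3 structural roles)
  encoding, affine-gap pairwise DP, and NJ-guided progressive alignment.
- **cbc** — the CBC/hCBC/Nst/silent classifier, per-taxon-pair and per-group
  event tabulation with per-helix tallies, and CBC count matrices.
- **consensus** — per-group IUPAC consensus sequence-structures, the
  100%-conserved pair subset, and per-helix GC/G-U/variability/ti:tv stats.
- **motifs** — IUPAC motif scanning with mismatch budgets and the pseudogene
  screen (motifs + GC + length bounds).
- **diversity** — GC content, DnaSP-style indices (S, Pi, Eta, haplotype
  diversity, indel sites), p-distance / K2P group distances with bootstrap SE.
- **trees** — neighbor joining, UPGMA, column-bootstrap support,
  Robinson-Foulds distances.
- **synthdata** — synthetic ITS families evolved on a known tree with a
  fully logged, replayable record of planted CBC/hCBC/Nst/indel events.

## Worked example

```python
from its_structphylo import (SynthConfig, generate_family, annotate_regions,
                             default_anchors, tabulate_events, cbc_matrix)
from its_structphylo.synthdata import recover_planted_counts

records, truth = generate_family(SynthConfig(n_taxa=6, seed=42))
ann = annotate_regions(records[0], default_anchors())
print({r.value: iv for r, iv in ann.intervals.items()})
print("planted  :", truth.planted_counts())
print("recovered:", recover_planted_counts(truth))
events, tables = tabulate_events(truth.alignment, paired_cols=truth.paired_cols)
print(cbc_matrix(events, truth.alignment.taxa))
```

prints

```
{'ITS1': (0, 240), '5.8S': (240, 401), 'ITS2': (401, 623)}
planted  : {'CBC': 2, 'hCBC': 4, 'Nst': 16, 'indel': 0}
recovered: {'CBC': 2, 'hCBC': 4, 'Nst': 16, 'indel': 0}
    t1  t2  t3  t4  t5  t6
t1   0   2   1   1   1   1
t2   2   0   1   1   1   1
t3   1   1   0   0   0   0
...
```

The anchor-based annotation recovers the generator's true region boundaries
exactly; branch-wise classification on the true alignment recovers every
planted event class count; and the CBC matrix shows the two taxa (`t1`, `t2`)
whose lineage accumulated the compensatory changes — the input CBCAnalyzer-style
tree building works from.

The same analysis runs from the shell:

```sh
its-structphylo simulate --seed 42 --out family/
its-structphylo run --config run.json --out results/
```

where `run.json` holds either a `simulate` block or a `fasta` + `groups`
pair; the output directory then contains `regions.tsv`, `structs.db`,
`aln.ssfasta`, `events.csv`, per-group consensus files, motif and pseudogene
reports, diversity and distance tables, and Newick trees with bootstrap
support.

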