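"""End-to-end orchestration: annotate -> model -> align -> classify ->
consensus -> motifs -> diversity -> trees, from a single JSON-style config.

Every stage writes its output under one directory in a re-loadable plain-text
format, and a run-metadata JSON records every parameter and seed, so that a
rerun with an identical config is bit-identical for the deterministic stages
and any stage can be re-run from its predecessor's files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import templates
from .annotation import annotate_regions, default_anchors
from .cbc import cbc_matrix, events_to_dataframe, tabulate_events
from .consensus import build_consensus, helix_stats
from .diversity import diversity_indices, gc_content, group_distances, pairwise_distance_matrix
from .folding import add_flanks
from .homology_model import enumerate_helices, model_from_template
from .io_formats import (GroupMap, Region, SeqStructRecord, parse_fasta, read_group_map,
                         write_newick, write_vienna)
from .motifs import PACKAGED_MOTIFS, scan_motif, screen_pseudogene
from .seqstruct_align import align_seqstruct, paired_columns
from .synthdata import SynthConfig, generate_family
from .trees import bootstrap_support, nj_tree, upgma_tree

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


DEFAULTS = {
    "flank_len": 25,
    "min_identity": 0.75,
    "pair_threshold": 0.5,
    "group_threshold": 1.0,
    "bootstrap_reps": 200,
    "distance_model": "p_distance",
    "se_reps": 200,
    "seed": 0,
    "use_true_alignment": True,
}


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full analysis; returns a dict of result objects and writes the
    report bundle under ``outdir``."""
    cfg = {**DEFAULTS, **config}
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    results: dict = {}

    # ------------------------------------------------------------ input
    truth = None
    if "simulate" in cfg:
        sim = SynthConfig(**{**cfg["simulate"], "seed": cfg["simulate"].get("seed", seed)})
        records, truth = generate_family(sim)
        groups = GroupMap({r.id: f"G{k % 2 + 1}" for k, r in enumerate(records)}) \
            if "groups" not in cfg else GroupMap(cfg["groups"])
        results["truth"] = truth
    else:
        try:
            records = parse_fasta(cfg["fasta"], region=Region.FULL_ITS)
        except Exception as exc:
            raise PipelineError("annotate", str(exc)) from exc
        groups = read_group_map(cfg["groups"]) if isinstance(cfg.get("groups"), (str, Path)) \
            else GroupMap(cfg.get("groups", {r.id: "all" for r in records}))
    results["records"] = records
    results["groups"] = groups

    # ------------------------------------------------------------ annotate
    anchors = default_anchors()
    annotations = {}
    rows = []
    for rec in records:
        try:
            ann = annotate_regions(rec.with_(pairs=frozenset(), region=Region.FULL_ITS),
                                   anchors)
        except Exception as exc:
            raise PipelineError("annotate", f"record {rec.id!r}: {exc}") from exc
        annotations[rec.id] = ann
        for reg, (s, e) in ann.intervals.items():
            rows.append({"record_id": rec.id, "region": reg.value,
                         "start": s + 1, "end": e,
                         "unresolved": ";".join(ann.unresolved)})
    pd.DataFrame(rows).to_csv(out / "regions.tsv", sep="\t", index=False)
    results["annotations"] = annotations

    # ------------------------------------------------------------ model (ITS2)
    template = templates.its2_template(cfg["flank_len"])
    modeled = []
    for rec in records:
        ann = annotations[rec.id]
        try:
            its2 = ann.subsequence(rec.seq, Region.ITS2)
            up = ann.subsequence(rec.seq, Region.FIVE_EIGHT_S)
            down = rec.seq[ann.intervals[Region.ITS2][1]:]
            ext, _off = add_flanks(its2, up, down, cfg["flank_len"])
            m = model_from_template(ext, template, cfg["min_identity"], record_id=rec.id)
        except Exception as exc:
            raise PipelineError("model", f"record {rec.id!r}: {exc}") from exc
        modeled.append(m)
    write_vienna(modeled, out / "structs.db")
    results["modeled"] = modeled

    # ------------------------------------------------------------ align
    try:
        if truth is not None and cfg["use_true_alignment"]:
            aln = truth.alignment
        else:
            aln = align_seqstruct(modeled)
    except Exception as exc:
        raise PipelineError("align", str(exc)) from exc
    aln.write_paired_fasta(out / "aln.ssfasta")
    results["alignment"] = aln

    pcols = paired_columns(aln, cfg["pair_threshold"])

    # consensus over everything defines the helix frame for event tallies
    cons_all = build_consensus(aln, aln.taxa, group="all", pair_threshold=cfg["pair_threshold"])
    frame = SeqStructRecord(id="consensus-frame",
                            seq="".join("N" if ch == "-" else ch for ch in cons_all.consensus_seq)
                            .replace("N", "A"),
                            pairs=frozenset(cons_all.consensus_pairs))
    helixmap = enumerate_helices(frame) if cons_all.consensus_pairs else None

    # ------------------------------------------------------------ events
    try:
        events, tables = tabulate_events(aln, groups=groups, helixmap=helixmap,
                                         mode="taxon_pairwise", paired_cols=pcols)
        gevents, gtables = tabulate_events(aln, groups=groups, helixmap=helixmap,
                                           mode="group_level", paired_cols=pcols,
                                           group_threshold=cfg["group_threshold"])
    except Exception as exc:
        raise PipelineError("events", str(exc)) from exc
    events_to_dataframe(events).to_csv(out / "events.csv", index=False)
    events_to_dataframe(gevents).to_csv(out / "events_groups.csv", index=False)
    m = cbc_matrix(events, aln.taxa)
    m.to_csv(out / "cbc_matrix.tsv", sep="\t")
    results["events"] = events
    results["group_events"] = gevents
    results["event_tables"] = tables
    results["cbc_matrix"] = m

    # ------------------------------------------------------------ consensus per group
    stats_frames = []
    for g, members in sorted(groups.groups().items()):
        members = [t for t in members if t in aln.rows]
        if len(members) < 2:
            continue
        cm = build_consensus(aln, members, group=g, pair_threshold=cfg["pair_threshold"])
        with open(out / f"consensus_{g}.db", "w") as fh:
            db = ["."] * aln.width
            for p, q in cm.consensus_pairs:
                db[p], db[q] = "(", ")"
            fh.write(f">consensus_{g}\n{cm.consensus_seq}\n{''.join(db)}\n")
        pd.DataFrame({"column": range(1, aln.width + 1),
                      "conservation": cm.conservation}).to_csv(
            out / f"conservation_{g}.tsv", sep="\t", index=False)
        if helixmap is not None:
            hs = helix_stats(cm, helixmap, aln)
            hs.insert(0, "group", g)
            stats_frames.append(hs)
    if stats_frames:
        pd.concat(stats_frames).to_csv(out / "helix_stats.tsv", sep="\t")

    # ------------------------------------------------------------ motifs + screen
    mrows, vrows = [], []
    for rec in records:
        for name, pattern in PACKAGED_MOTIFS.items():
            if isinstance(pattern, tuple):
                hits = []
                for p in pattern:
                    hits = scan_motif(rec.seq, p, 0, name)
                    if hits:
                        break
            else:
                hits = scan_motif(rec.seq, pattern, 1, name)
            for h in hits[:3]:
                mrows.append({"record_id": rec.id, "motif": name, "start": h.start + 1,
                              "end": h.end, "mismatches": h.mismatches,
                              "spacer_len": h.spacer_len if h.spacer_len is not None else ""})
        try:
            verdict = screen_pseudogene(rec, annotations[rec.id])
        except Exception as exc:
            raise PipelineError("screen", f"record {rec.id!r}: {exc}") from exc
        vrows.append({"record_id": rec.id, "pass": verdict.passed,
                      "reasons": ";".join(verdict.reasons)})
    pd.DataFrame(mrows).to_csv(out / "motifs.tsv", sep="\t", index=False)
    pd.DataFrame(vrows).to_csv(out / "pseudogene_screen.tsv", sep="\t", index=False)
    results["verdicts"] = vrows

    # ------------------------------------------------------------ diversity + distances
    base_rows = aln.base_matrix()
    div = diversity_indices(list(base_rows.values()), label="full")
    pd.DataFrame([asdict(div)]).to_csv(out / "diversity.tsv", sep="\t", index=False)
    gcs = {rec.id: gc_content(rec.seq) for rec in records}
    pd.DataFrame([{"record_id": k, "gc": v} for k, v in gcs.items()]).to_csv(
        out / "gc_content.tsv", sep="\t", index=False)
    dt = group_distances(base_rows, groups, model=cfg["distance_model"],
                         se_reps=cfg["se_reps"], seed=seed + 1)
    dt.between.to_csv(out / "between_group_distances.tsv", sep="\t")
    dt.within.to_csv(out / "within_group_distances.tsv", sep="\t")
    results["diversity"] = div
    results["distances"] = dt

    # ------------------------------------------------------------ trees
    def builder(cols):
        return pairwise_distance_matrix(base_rows, model=cfg["distance_model"], cols=cols)

    try:
        tree = bootstrap_support(builder, n_columns=aln.width, tree_builder=nj_tree,
                                 reps=cfg["bootstrap_reps"], seed=seed + 2)
        write_newick(tree, out / "nj_tree.nwk")
        results["nj_tree"] = tree
        if m.values.sum() > 0:
            cbc_tree = upgma_tree(m.values.astype(float), list(m.index))
            write_newick(cbc_tree, out / "cbc_tree.nwk")
            results["cbc_tree"] = cbc_tree
    except Exception as exc:
        raise PipelineError("trees", str(exc)) from exc

    meta = {"config": {k: v for k, v in cfg.items() if k != "simulate"},
            "simulate": cfg.get("simulate"),
            "n_records": len(records),
            "alignment_width": aln.width,
            "seed": seed}
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    return results
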