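"""End-to-end orchestration: ORF curation -> protein classification ->
precursor identification -> target/degradome confirmation -> expression
analytics, with a single reproducible run report.

Stage outputs are TSV files; the report is JSON with per-stage record
counts (input = retained + rejected at every filter), the module-network
table, and provenance (config echo, config hash, seed).  Reports carry
no timestamps, so identical (inputs, config, seed) produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classifier import classify_arf, classify_tir_afb, select_candidate_orf
from .config import PipelineConfig
from .degradome import (CleavageEvidence, build_module_table, categorise,
                        export_tplot, read_degradome_tsv, scan_targets)
from .expression import ddct, group_tests, read_qpcr_tsv, zscore_rows
from .precursor import assess_stem_membership, correlate_expression, locate_mature
from .references import load_references
from .sequence_core import find_complete_orfs, principal_orf, read_fasta

log = logging.getLogger("auxinmir")


@dataclass
class RunPaths:
    transcripts: str
    mirnas: str
    degradome: str | None = None
    mirna_rpm: str | None = None
    transcript_fpkm: str | None = None
    qpcr: str | None = None
    qpcr_reference_gene: str = "LlActin"
    qpcr_calibrator: str = "control"


@dataclass
class StageCount:
    stage: str
    n_input: int
    n_retained: int
    rejected: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_input != self.n_retained + sum(self.rejected.values()):
            raise AssertionError(
                f"count conservation violated at {self.stage}: "
                f"{self.n_input} != {self.n_retained} + {self.rejected}")


def _read_expression_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def run_all(paths: RunPaths, cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write stage TSVs plus report.json."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": [],
        "notes": [
            "cleavage convention: degradome tag 5' end opposite miRNA position 10",
            "fold engine: nussinov-max-pairing",
        ],
    }
    counts: list[StageCount] = []

    # ---- stage 1: transcripts and complete ORFs ----------------------
    transcripts = read_fasta(paths.transcripts)
    log.info("stage=orf event=read n=%d", len(transcripts))
    orfs_by_tid = {}
    for t in transcripts:
        orfs = find_complete_orfs(t, min_aa=cfg.min_aa)
        if orfs:
            orfs_by_tid[t.id] = orfs
    sc = StageCount("complete_orfs", len(transcripts), len(orfs_by_tid),
                    {"no_complete_orf": len(transcripts) - len(orfs_by_tid)})
    sc.check()
    counts.append(sc)
    with open(out / "orfs.tsv", "w") as fh:
        fh.write("transcript_id\tstrand\tframe\tcds_start\tcds_end\tn_aa\tn_orfs_on_transcript\n")
        for tid in sorted(orfs_by_tid):
            for o in orfs_by_tid[tid]:
                fh.write(f"{tid}\t{o.strand}\t{o.frame}\t{o.cds_start}\t"
                         f"{o.cds_end}\t{o.n_aa}\t{len(orfs_by_tid[tid])}\n")

    # ---- stage 2: protein classification -----------------------------
    tir1_ref, arf_ref, pb1_ref = load_references()
    annotations: dict[str, str] = {}
    tir_rows, arf_rows = [], []
    detail: dict[str, dict] = {}
    by_annotation = {"tir": [], "arf": [], "auxiaa": [], "other": []}
    for t in transcripts:
        label = t.annotation.upper()
        if "TIR" in label or "AFB" in label:
            key = "tir"
        elif "ARF" in label:
            key = "arf"
        elif "IAA" in label:
            key = "auxiaa"     # annotation passthrough only, not classified
        else:
            key = "other"
        by_annotation[key].append(t)

    for t in by_annotation["tir"]:
        orfs = orfs_by_tid.get(t.id)
        if not orfs:
            continue
        rep = classify_tir_afb(select_candidate_orf(orfs, [tir1_ref.seq]), tir1_ref, cfg)
        annotations[t.id] = f"TIR1/AFB:{rep.verdict}"
        tir_rows.append({
            "protein_id": rep.protein_id, "has_fbox": rep.has_fbox,
            "fbox_quality": round(rep.fbox_quality, 4),
            "lrr_coverage": round(rep.lrr_coverage, 4),
            "pocket_conserved": rep.n_pocket_conserved,
            "ac_conserved": sum(c.conserved for c in rep.ac_checks),
            "verdict": rep.verdict, "reason": rep.reason,
            "n_orfs_on_transcript": len(orfs)})
        detail[t.id] = {
            "pocket_checks": [dataclasses.asdict(c) for c in rep.pocket_checks],
            "ac_checks": [dataclasses.asdict(c) for c in rep.ac_checks]}
    n_tir = len(tir_rows)
    n_fbox = sum(1 for r in tir_rows if r["has_fbox"])
    n_receptor = sum(1 for r in tir_rows if r["verdict"] == "receptor")
    sc = StageCount("tir_afb_curation", n_tir, n_receptor,
                    {"incomplete_lrr": sum(1 for r in tir_rows if r["verdict"] == "incomplete"),
                     "rejected": sum(1 for r in tir_rows if r["verdict"] == "rejected")})
    sc.check()
    counts.append(sc)
    report["tir_funnel"] = {"candidates": n_tir, "with_fbox": n_fbox,
                            "receptors": n_receptor}

    for t in by_annotation["arf"]:
        orfs = orfs_by_tid.get(t.id)
        if not orfs:
            continue
        rep = classify_arf(select_candidate_orf(orfs, [arf_ref.seq]), arf_ref, pb1_ref, cfg)
        annotations[t.id] = f"ARF:{rep.architecture}"
        arf_rows.append({
            "protein_id": rep.protein_id, "has_dbd": rep.has_dbd,
            "dbd_identity": round(rep.dbd_identity, 4),
            "dbd_motif_start": rep.dbd_motif.start if rep.dbd_motif else "",
            "dbd_motif_mismatches": rep.dbd_motif.n_mismatch if rep.dbd_motif else "",
            "dbd_motif_subs": ";".join(f"{e}{o}>{b}" for e, o, b in
                                       rep.dbd_motif.substitutions) if rep.dbd_motif else "",
            "has_dd": rep.has_dd, "dd_coverage": round(rep.dd_coverage, 4),
            "md_call": rep.md_call, "pb1_type": rep.pb1.pb1_type,
            "architecture": rep.architecture, "role_note": rep.role_note})
    sc = StageCount("arf_curation", len(arf_rows),
                    sum(1 for r in arf_rows if r["architecture"] != ""), {})
    sc.check()
    counts.append(sc)
    pd.DataFrame(tir_rows).to_csv(out / "tir_afb_reports.tsv", sep="\t", index=False)
    pd.DataFrame(arf_rows).to_csv(out / "arf_reports.tsv", sep="\t", index=False)
    (out / "residue_checks.json").write_text(json.dumps(detail, indent=2, sort_keys=True))

    # ---- stage 3: precursors ------------------------------------------
    mirna_records = read_fasta(paths.mirnas)
    mirnas = {m.id: m.seq for m in mirna_records}
    mirna_rpm = (_read_expression_tsv(paths.mirna_rpm) if paths.mirna_rpm else None)
    transcript_fpkm = (_read_expression_tsv(paths.transcript_fpkm)
                       if paths.transcript_fpkm else None)
    prec_rows = []
    n_hits = n_in_stem = n_pass = 0
    for mid in sorted(mirnas):
        for t in transcripts:
            for span in locate_mature(t, mirnas[mid], cfg.max_mismatch):
                n_hits += 1
                cand = assess_stem_membership(t, mid, span, cfg)
                rho_rec = None
                if (cand.in_stem and mirna_rpm is not None
                        and transcript_fpkm is not None
                        and mid in mirna_rpm.index and t.id in transcript_fpkm.index):
                    rho_rec = correlate_expression(
                        mirna_rpm.loc[mid].values, transcript_fpkm.loc[t.id].values,
                        mirna_id=mid, transcript_id=t.id,
                        rho_threshold=cfg.rho_threshold)
                n_in_stem += cand.in_stem
                n_pass += bool(rho_rec and rho_rec.passes)
                prec_rows.append({
                    "mirna_id": mid, "transcript_id": t.id,
                    "mirna_start": span[0], "mirna_end": span[1],
                    "in_stem": cand.in_stem,
                    "paired_fraction": round(cand.paired_fraction, 4),
                    "arm": cand.arm,
                    "structure": cand.fold.structure,
                    "fold_engine": cand.fold.engine,
                    "rho": (round(rho_rec.rho, 4) if rho_rec and rho_rec.rho == rho_rec.rho
                            else ""),
                    "rho_passes": rho_rec.passes if rho_rec else "",
                })
    sc = StageCount("precursor_stem_filter", n_hits, n_in_stem,
                    {"outside_stem": n_hits - n_in_stem})
    sc.check()
    counts.append(sc)
    sc = StageCount("precursor_rho_filter", n_in_stem, n_pass,
                    {"rho_below_threshold_or_missing": n_in_stem - n_pass})
    sc.check()
    counts.append(sc)
    pd.DataFrame(prec_rows).to_csv(out / "precursors.tsv", sep="\t", index=False)

    # ---- stage 4: targets + degradome ---------------------------------
    profiles = read_degradome_tsv(paths.degradome) if paths.degradome else {}
    sites = []
    for mid in sorted(mirnas):
        sites.extend(scan_targets(mid, mirnas[mid], transcripts, cfg))
    evidence: list[CleavageEvidence] = []
    tplot_dir = out / "tplots"
    tplot_dir.mkdir(exist_ok=True)
    n_confirmed = 0
    site_rows = []
    for s in sites:
        prof = profiles.get(s.transcript_id)
        ev = None
        if prof is not None:
            ev = categorise(prof, s.cleavage_pos, site=s)
            if ev.category is not None:
                tp = tplot_dir / f"{s.mirna_id}__{s.transcript_id}.tsv"
                export_tplot(prof, s.cleavage_pos, tp)
                ev.tplot_path = str(tp.relative_to(out))
                evidence.append(ev)
                n_confirmed += 1
        site_rows.append({
            "mirna_id": s.mirna_id, "transcript_id": s.transcript_id,
            "site_start": s.site_start, "site_end": s.site_end,
            "penalty": s.penalty, "cleavage_pos": s.cleavage_pos,
            "reads_at_site": ev.reads_at_site if ev else 0,
            "category": ev.category if ev and ev.category is not None else "",
            "convention": s.convention})
    sc = StageCount("degradome_confirmation", len(sites), n_confirmed,
                    {"no_tag_at_cleavage_site": len(sites) - n_confirmed})
    sc.check()
    counts.append(sc)
    pd.DataFrame(site_rows).to_csv(out / "target_sites.tsv", sep="\t", index=False)

    modules = build_module_table(evidence, annotations, max_category=cfg.max_category)
    module_rows = [dataclasses.asdict(m) for m in modules]
    pd.DataFrame(module_rows).to_csv(out / "module_network.tsv", sep="\t", index=False)
    report["module_network"] = module_rows

    # ---- stage 5: expression analytics --------------------------------
    if transcript_fpkm is not None:
        z, flagged = zscore_rows(transcript_fpkm)
        z.round(6).to_csv(out / "transcript_fpkm_zscores.tsv", sep="\t")
        report["zscore_flagged_rows"] = flagged
    if paths.qpcr:
        qpcr = read_qpcr_tsv(paths.qpcr)
        rels = ddct(qpcr, paths.qpcr_reference_gene, paths.qpcr_calibrator)
        rel_rows = [{"gene": r.gene, "group": r.group,
                     "fold_change": round(r.fold_change, 6),
                     "sd": round(r.sd, 6), "n_bio": r.n_bio} for r in rels]
        pd.DataFrame(rel_rows).to_csv(out / "qpcr_relative_expression.tsv",
                                      sep="\t", index=False)
        tests = {}
        genes = sorted({r.gene for r in rels})
        for gene in genes:
            groups = {r.group: r.rep_folds for r in rels if r.gene == gene}
            if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
                res = group_tests(groups, alpha=cfg.alpha)
                tests[gene] = {"method": res.method, "p_value": res.p_value,
                               "letters": res.letters, "flagged": res.flagged}
        report["qpcr_group_tests"] = tests

    report["stages"] = [dataclasses.asdict(c) for c in counts]
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    log.info("stage=done event=report path=%s", out / "report.json")
    return report
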