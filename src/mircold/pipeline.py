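"""End-to-end pipeline orchestration and report generation.

Chains preprocess -> annotate -> hairpin -> diffexpr -> targets -> qpcr
from a single config, writing intermediate tables and a JSON report whose
summary counts reconcile with the emitted tables. ``demo`` generates a
small synthetic study and runs everything against its planted truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, annotate, diffexpr, hairpin, preprocess, qpcr, synthdata, targets

logger = logging.getLogger("mircold")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "demo"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    outdir: str
    libraries: dict[str, str] = field(default_factory=dict)   # lib_id -> fastq path
    library_meta: dict[str, list[str]] = field(default_factory=dict)  # lib -> [tissue, condition]
    catalog: str | None = None
    contaminants: str | None = None
    contigs: str | None = None
    ct_table: str | None = None
    adapter: str = synthdata.DEFAULT_ADAPTER
    min_overlap: int = 6
    min_mean_q: float = 20.0
    min_tag_len: int = 18
    max_tag_len: int = 24
    contaminant_max_mm: int = 0
    catalog_max_mm: int = 2
    flank: int = hairpin.DEFAULT_FLANK
    max_hits: int = hairpin.DEFAULT_MAX_HITS
    min_abs_mfei: float = 0.85
    de_lfc_threshold: float = diffexpr.LOG2FC_THRESHOLD
    de_p_threshold: float = diffexpr.P_THRESHOLD
    target_cutoff: float = targets.DEFAULT_CUTOFF
    qpcr_threshold_log2: float = qpcr.DIRECTION_THRESHOLD_LOG2
    qpcr_reference_mirna: str = "18S"
    qpcr_reference_target: str = "PduAct1"
    qpcr_pairing: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Summary of one pipeline run; every count reconciles with the tables."""

    provenance: dict[str, Any]
    library_stats: dict[str, dict[str, int]] = field(default_factory=dict)
    n_tags: int = 0
    n_contaminant_tags: int = 0
    n_conserved_entries: int = 0
    n_conserved_tags: int = 0
    n_novel: int = 0
    novel_arm_tally: dict[str, int] = field(default_factory=dict)
    family_sizes: dict[str, int] = field(default_factory=dict)
    specificity: dict[str, list[str]] = field(default_factory=dict)
    de_summary: dict[str, dict[str, int]] = field(default_factory=dict)
    n_target_hits: int = 0
    qpcr_n_genes: int = 0
    skipped_stages: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all configured stages; stage failure aborts with its name."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(provenance={
        "config_digest": config.digest(), "version": __version__, "seed": config.seed,
    })

    stage = "preprocess"
    try:
        table = preprocess.TagTable()
        for lib_id, path in config.libraries.items():
            counts, stats = preprocess.process_library(
                path, lib_id, config.adapter, min_overlap=config.min_overlap,
                min_mean_q=config.min_mean_q, min_len=config.min_tag_len,
                max_len=config.max_tag_len)
            table.add_library(lib_id, counts, stats)
            logger.info("%s: %d raw, %d clean, %d unique tags",
                        lib_id, stats.raw_reads, stats.clean_reads, stats.unique_tags)
        table.write_tsv(outdir / "tags.tsv")
        table.write_stats_json(outdir / "library_stats.json")
        report.library_stats = {
            lib: {"raw_reads": st.raw_reads, "clean_reads": st.clean_reads,
                  "unique_tags": st.unique_tags}
            for lib, st in table.stats.items()}
        report.n_tags = len(table.counts)
        tag_seqs = sorted(table.counts)

        stage = "annotate"
        retained = tag_seqs
        assignments: list[annotate.ConservedAssignment] = []
        unassigned: list[str] = []
        if config.contaminants:
            contaminant_set = annotate.load_fasta(config.contaminants)
            removed, retained = annotate.filter_contaminants(
                tag_seqs, contaminant_set, config.contaminant_max_mm)
            report.n_contaminant_tags = len(removed)
        if config.catalog:
            catalog = annotate.load_catalog(config.catalog)
            assignments, unassigned = annotate.match_conserved(
                retained, catalog, config.catalog_max_mm)
            report.n_conserved_tags = len(assignments)
            report.n_conserved_entries = len({a.entry.name for a in assignments})
            fam = annotate.family_distribution(assignments, table.counts)
            fam.to_csv(outdir / "family_distribution.tsv", sep="\t")
            report.family_sizes = fam["pooled"].to_dict()
            meta = {lib: (t, c) for lib, (t, c) in
                    ((k, tuple(v)) for k, v in config.library_meta.items())}
            if meta:
                presence = annotate.presence_matrix(
                    assignments, table.counts, list(config.libraries))
                sets = annotate.specificity_sets(presence, meta)
                report.specificity = sets.to_dict()
                (outdir / "specificity_sets.json").write_text(
                    json.dumps(report.specificity, indent=2))
            pd.DataFrame([{
                "tag": a.tag_seq, "entry": a.entry.name, "family": a.entry.family,
                "mismatches": a.mismatches} for a in assignments]).to_csv(
                outdir / "conserved_assignments.tsv", sep="\t", index=False)
        else:
            unassigned = list(retained)
            report.skipped_stages.append("annotate")

        stage = "hairpin"
        novel = pd.DataFrame()
        if config.contigs:
            contigs = annotate.load_fasta(config.contigs)
            cfg = hairpin.HairpinConfig(flank=config.flank, max_hits=config.max_hits,
                                        min_abs_mfei=config.min_abs_mfei)
            hits = hairpin.map_tags(unassigned, contigs, cfg.max_hits)
            evaluations = []
            for hit in hits:
                cand = hairpin.extract_precursor(hit, contigs, cfg.flank)
                fr = hairpin.fold(cand.seq)
                evaluations.append(hairpin.evaluate_hairpin(cand, fr, cfg))
            novel = hairpin.select_novel(evaluations)
            novel.to_csv(outdir / "novel_mirnas.tsv", sep="\t", index=False)
            with open(outdir / "precursors.txt", "w") as fh:
                for ev in evaluations:
                    if ev.passed:
                        fh.write(f"{ev.precursor_seq}\n{ev.structure}\n{ev.mfe:.2f}\n")
            report.n_novel = len(novel)
            report.novel_arm_tally = hairpin.arm_tally(novel)
        else:
            report.skipped_stages.append("hairpin")

        stage = "diffexpr"
        contrasts = _tissue_contrasts(config.library_meta)
        if assignments and contrasts:
            entity_counts = _entity_counts(assignments, novel, table)
            de = diffexpr.contrast_table(entity_counts, table.totals(), contrasts)
            de.to_csv(outdir / "differential_expression.tsv", sep="\t", index=False)
            report.de_summary = diffexpr.summarize_calls(de)
        else:
            report.skipped_stages.append("diffexpr")

        stage = "targets"
        if config.contigs and (assignments or len(novel)):
            contigs = annotate.load_fasta(config.contigs)
            hit_rows = []
            mirnas = {a.entry.name: a.entry.mature_seq for a in assignments}
            for _, row in novel.iterrows():
                mirnas[f"novel_{row.mature_seq}"] = row.mature_seq
            for name, mseq in mirnas.items():
                for tid, tseq in contigs.items():
                    for hit in targets.scan_transcript(
                            mseq, tseq, config.target_cutoff, name, tid):
                        hit_rows.append({
                            "mirna": hit.mirna_name, "transcript": hit.transcript_id,
                            "window_start": hit.window_start,
                            "expectation": hit.expectation,
                            "pairing": ",".join(hit.pairing),
                            "cleavage_pos": hit.cleavage_pos})
            pd.DataFrame(hit_rows).to_csv(outdir / "target_hits.tsv", sep="\t",
                                          index=False)
            report.n_target_hits = len(hit_rows)
        else:
            report.skipped_stages.append("targets")

        stage = "qpcr"
        if config.ct_table:
            ct = qpcr.read_ct_table(config.ct_table)
            genes = sorted(set(ct["gene"]) - {config.qpcr_reference_mirna,
                                              config.qpcr_reference_target})
            samples = sorted(set(ct["sample"]))
            calibrators = {s: _calibrator_for(s, samples) for s in samples}
            mirna_genes = [g for g in genes if not g.startswith("target_")]
            target_genes = [g for g in genes if g.startswith("target_")]
            rel_mi = qpcr.relative_expression_table(
                ct, mirna_genes, config.qpcr_reference_mirna, calibrators,
                config.qpcr_threshold_log2)
            rel_mi.to_csv(outdir / "qpcr_mirna.tsv", sep="\t", index=False)
            report.qpcr_n_genes = len(genes)
            if target_genes:
                rel_tg = qpcr.relative_expression_table(
                    ct, target_genes, config.qpcr_reference_target, calibrators,
                    config.qpcr_threshold_log2)
                rel_tg.to_csv(outdir / "qpcr_targets.tsv", sep="\t", index=False)
                pairing = config.qpcr_pairing or {
                    g: [f"target_{g}"] for g in mirna_genes if f"target_{g}" in target_genes}
                corr = qpcr.correlation_table(rel_mi, rel_tg, pairing)
                corr.to_csv(outdir / "qpcr_correlation.tsv", sep="\t", index=False)
        else:
            report.skipped_stages.append("qpcr")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.to_json(outdir / "report.json")
    return report


def _tissue_contrasts(library_meta: dict[str, list[str]]
                      ) -> list[tuple[str, str, str]]:
    """stress-vs-control contrast per tissue, when both libraries exist."""
    by_tissue: dict[str, dict[str, str]] = {}
    for lib, (tissue, condition) in ((k, tuple(v)) for k, v in library_meta.items()):
        by_tissue.setdefault(tissue, {})[condition] = lib
    return [(tissue, libs["stress"], libs["control"])
            for tissue, libs in sorted(by_tissue.items())
            if "stress" in libs and "control" in libs]


def _entity_counts(assignments, novel: pd.DataFrame,
                   table: preprocess.TagTable) -> pd.DataFrame:
    """Aggregate tag counts per catalog entry (plus novel matures)."""
    libs = table.library_ids
    rows: dict[str, dict[str, int]] = {}
    for a in assignments:
        row = rows.setdefault(a.entry.name, {lib: 0 for lib in libs})
        per = table.counts.get(a.tag_seq, {})
        for lib in libs:
            row[lib] += per.get(lib, 0)
    for _, r in novel.iterrows():
        per = table.counts.get(r.mature_seq, {})
        rows[f"novel_{r.mature_seq}"] = {lib: per.get(lib, 0) for lib in libs}
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=libs).fillna(0)
    return df.astype(int)


def _calibrator_for(sample: str, samples: list[str]) -> str:
    """Default calibrator: the 10C sample of the same genotype and tissue."""
    parts = sample.rsplit("_", 1)
    candidate = f"{parts[0]}_10C"
    return candidate if candidate in samples else sample


def demo(seed: int = 1, outdir: str | Path = "demo_out",
         params: synthdata.SynthParams | None = None
         ) -> tuple[RunReport, synthdata.GroundTruth, PipelineConfig]:
    """Generate a synthetic study and run the full pipeline against it.

    Returns the run report, the generator's ground truth, and the config
    used, so planted expectations can be checked directly.
    """
    outdir = Path(outdir)
    p = params or synthdata.SynthParams(seed=seed)
    refs, truth = synthdata.build_references(p)
    ref_paths = synthdata.write_references(refs, outdir / "refs")
    manifest = synthdata.simulate_libraries(truth, refs, p, outdir / "reads")
    ct_path = outdir / "ct_table.tsv"
    synthdata.simulate_ct_table(truth, p, noise_sd=0.05, path=ct_path)
    truth.to_json(outdir / "ground_truth.json")

    config = PipelineConfig(
        outdir=str(outdir / "run"),
        libraries={lib: manifest["libraries"][lib]["path"]
                   for lib, _, _ in p.libraries},
        library_meta={lib: [tissue, condition]
                      for lib, tissue, condition in p.libraries},
        catalog=str(ref_paths["catalog"]),
        contaminants=str(ref_paths["contaminants"]),
        contigs=str(ref_paths["contigs"]),
        ct_table=str(ct_path),
        adapter=p.adapter,
        seed=seed,
    )
    report = run_pipeline(config)
    return report, truth, config
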