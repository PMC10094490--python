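"""End-to-end orchestration: simulate -> classify peaks -> differential
expression -> integration -> qPCR, with a summary report.

A single :class:`RunConfig` (constructible from YAML) drives everything.
Every stage's tabular output is written to the output directory, the
effective configuration is echoed for provenance, and the summary report is
cross-checked against the stage tables (count fields must equal table
lengths) before being written as JSON and readable text. Given a fixed seed
the whole run is deterministic, byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, integrate, peaks as peaks_mod, qpcr as qpcr_mod, synth
from .genome_io import write_bed, write_table

log = logging.getLogger("castechip")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    sim: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    fc_threshold: float = 2.0
    alpha: float = 0.05
    padj_threshold: float = 0.05
    metaprofile_flank: int = 2000
    metaprofile_bin: int = 50
    n_qpcr_genes: int = 5
    comparison: str = "Q_vs_W"

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "alpha", "padj_threshold"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = synth.SimulationConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(name: str):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages on a simulated dataset; returns the summary report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    except Exception as exc:  # annotate the failing stage for the user
        raise PipelineError(f"pipeline failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    sim = config.sim
    caste_a, caste_b = sim.castes
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )

    t0 = _stage("simulate")
    sim_dir = outdir / "simulated"
    sim_dir.mkdir(exist_ok=True)
    genome = synth.simulate_genome(sim)
    peaksets, truth = synth.simulate_peaks(sim, genome)
    counts, samples, truth = synth.simulate_expression(sim, genome, truth)
    from .genome_io import write_counts, write_gff3

    write_gff3(genome, sim_dir / "genome.gff3")
    for ps in peaksets:
        write_bed(ps.peaks, sim_dir / f"{ps.label}.bed")
    write_counts(counts, sim_dir / "counts.tsv")
    write_table(samples, sim_dir / "samples.tsv")
    truth.to_json(sim_dir / "truth.json")
    log.info("simulate done in %.1fs", time.time() - t0)

    t0 = _stage("classify-peaks")
    consensus = peaks_mod.build_consensus(peaksets)
    classified = peaks_mod.classify_consensus(
        consensus, fc_threshold=config.fc_threshold, alpha=config.alpha
    )
    classified = peaks_mod.annotate_peaks(
        classified, genome, sim.promoter_upstream, sim.promoter_downstream
    )
    write_table(classified, outdir / "classified_peaks.tsv")
    bed = classified.copy()
    bed["name"] = bed["peak_id"] + "|" + bed["peak_class"] + "|" + bed["feature"]
    bed["score"] = 0.0
    write_bed(bed, outdir / "classified_peaks.bed")

    unique_a = classified[classified["peak_class"] == f"unique_{caste_a}"]
    unique_b = classified[classified["peak_class"] == f"unique_{caste_b}"]
    diff_a = classified[classified["peak_class"] == f"differential_up_{caste_a}"]
    diff_b = classified[classified["peak_class"] == f"differential_up_{caste_b}"]
    try:
        dist = peaks_mod.distribution_test(
            unique_a["feature"], unique_b["feature"], labels=(caste_a, caste_b)
        )
        dist_payload = dist.to_dict()
    except ValueError as exc:
        dist_payload = {"error": str(exc)}
    (outdir / "distribution_test.json").write_text(
        json.dumps(dist_payload, indent=1, sort_keys=True)
    )
    log.info("classify-peaks done in %.1fs", time.time() - t0)

    t0 = _stage("diffexpr")
    lengths = truth.genes.set_index("gene_id")["length"]
    de = diffexpr.run_differential(
        counts, samples, deg_threshold=config.padj_threshold, gene_lengths=lengths
    )
    write_table(de.reset_index(), outdir / "diffexpr.tsv")
    degs = set(de.index[de["is_deg"]])
    deg_up = int((de["is_deg"] & (de["log2_fold_change"] > 0)).sum())
    deg_down = int((de["is_deg"] & (de["log2_fold_change"] < 0)).sum())
    log.info("diffexpr done in %.1fs", time.time() - t0)

    t0 = _stage("integrate")
    links = integrate.link_peaks_to_genes(
        classified, genome, sim.promoter_upstream, sim.promoter_downstream
    )
    write_table(links, outdir / "links.tsv")
    dpgs = integrate.differential_peak_genes(classified, links)
    overlap = integrate.overlap_sets(degs, dpgs)
    correlations = {}
    try:
        correlations["all_linked"] = integrate.signal_expression_correlation(
            classified, links, de, deg_only=False
        ).to_dict()
        correlations["deg_only"] = integrate.signal_expression_correlation(
            classified, links, de, deg_only=True
        ).to_dict()
    except ValueError as exc:
        correlations["error"] = str(exc)
    (outdir / "overlap.json").write_text(
        json.dumps(overlap.to_dict(), indent=1, sort_keys=True)
    )
    (outdir / "correlation.json").write_text(
        json.dumps(correlations, indent=1, sort_keys=True)
    )
    coverage = synth.peak_coverage(peaksets, sim.chrom_length)
    profile = integrate.tss_metaprofile(
        {sim.chrom_name: coverage[caste_b]}, genome,
        flank=config.metaprofile_flank, bin_size=config.metaprofile_bin,
    )
    write_table(profile.to_frame(), outdir / "metaprofile.tsv")
    log.info("integrate done in %.1fs", time.time() - t0)

    t0 = _stage("qpcr")
    de_truth = truth.genes[truth.genes["is_de"]]
    qpcr_genes = list(
        de_truth.reindex(
            de_truth["expr_log2fc"].abs().sort_values(ascending=False).index
        )["gene_id"].head(config.n_qpcr_genes)
    )
    qpcr_table = pd.DataFrame()
    if qpcr_genes:
        ct = synth.simulate_qpcr(truth, qpcr_genes, sim)
        write_table(ct, outdir / "qpcr_ct.tsv")
        qpcr_table = qpcr_mod.analyze_targets(
            ct, qpcr_genes, reference="GAPDH", control_group=caste_b
        )
        write_table(qpcr_table, outdir / "qpcr_results.tsv")
    log.info("qpcr done in %.1fs", time.time() - t0)

    def pct(sub: pd.DataFrame) -> dict:
        cats = ("promoter", "intron", "exon")
        in_cats = sub[sub["feature"].isin(cats)]
        n = len(in_cats)
        return {
            c: round(100.0 * float((in_cats["feature"] == c).sum()) / n, 2)
            if n else 0.0
            for c in cats
        }

    report = {
        "comparison": config.comparison,
        "seed": sim.seed,
        "n_consensus_peaks": int(len(classified)),
        "unique_peaks": {caste_a: int(len(unique_a)), caste_b: int(len(unique_b))},
        "differential_peaks": {
            f"up_{caste_a}": int(len(diff_a)),
            f"up_{caste_b}": int(len(diff_b)),
        },
        "unique_peak_feature_percent": {
            caste_a: pct(unique_a), caste_b: pct(unique_b)
        },
        "unique_peak_distribution_test": dist_payload,
        "n_genes_tested": int(len(de)),
        "degs": {"total": int(len(degs)), "up": deg_up, "down": deg_down},
        "n_dpgs": int(len(dpgs)),
        "deg_dpg_overlap": overlap.to_dict(),
        "signal_expression_correlation": correlations,
        "tss_metaprofile_argmax_offset": profile.argmax_offset,
        "qpcr": qpcr_table.to_dict(orient="list"),
    }
    _check_report(report, classified, de, caste_a, caste_b)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "report.txt").write_text(_render_report(report))
    return report


def _check_report(report, classified, de, caste_a, caste_b) -> None:
    """Internal consistency: report counts must equal table lengths."""
    cls = classified["peak_class"]
    checks = {
        "unique A": (report["unique_peaks"][caste_a],
                     int((cls == f"unique_{caste_a}").sum())),
        "unique B": (report["unique_peaks"][caste_b],
                     int((cls == f"unique_{caste_b}").sum())),
        "deg total": (report["degs"]["total"], int(de["is_deg"].sum())),
        "deg split": (report["degs"]["total"],
                      report["degs"]["up"] + report["degs"]["down"]),
    }
    for name, (got, want) in checks.items():
        if got != want:
            raise PipelineError(f"report inconsistency in {name}: {got} != {want}")
    for caste in (caste_a, caste_b):
        p = report["unique_peak_feature_percent"][caste]
        total = sum(p.values())
        if total and abs(total - 100.0) > 0.1:
            raise PipelineError(f"feature percentages for {caste} sum to {total}")


def _render_report(report: dict) -> str:
    lines = [
        f"castechip summary — comparison {report['comparison']} "
        f"(seed {report['seed']})",
        "",
        f"consensus peaks: {report['n_consensus_peaks']}",
        f"unique peaks: {report['unique_peaks']}",
        f"differential peaks: {report['differential_peaks']}",
        f"unique peak feature %: {report['unique_peak_feature_percent']}",
        f"distribution test: {report['unique_peak_distribution_test']}",
        f"DEGs: {report['degs']} of {report['n_genes_tested']} genes",
        f"DPGs: {report['n_dpgs']}",
        f"DEG ∩ DPG: {report['deg_dpg_overlap']}",
        f"signal–expression correlation: {report['signal_expression_correlation']}",
        f"TSS metaprofile argmax offset: {report['tss_metaprofile_argmax_offset']}",
    ]
    return "\n".join(lines) + "\n"
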