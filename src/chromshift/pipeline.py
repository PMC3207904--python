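"""End-to-end orchestration: density -> status -> transitions -> ranking ->
enrichment -> binding-site calling/assignment/stratification -> MeDIP screen.

Every numeric constant used anywhere in the pipeline is sourced from
:class:`PipelineConfig`, whose defaults are the published analysis constants
(300/500 bp windows, ±2 kb / ±1 kb flanks, 4/3 and 1.5/1 RPM thresholds,
ΔK27 0.4, 5-fold DE cutoff, activity score 25, 5 kb / 10 kb distance rules).
Given the same inputs and config the run report is identical across re-runs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import binding, density, expression, io, stats, transitions
from .simulate import SENESCENCE_SAMPLES, STIMULATION_SAMPLES


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    # inputs
    annotation_path: str = ""
    reads_paths: dict = field(default_factory=dict)  # track -> BED path
    expression_path: str = ""
    out_dir: str = "chromshift_out"
    total_mapped: dict = field(default_factory=dict)  # track -> denominator
    genome: dict = field(default_factory=dict)  # chrom -> length (site caller)

    # sample roles
    baseline_sample: str = SENESCENCE_SAMPLES[0]
    condition_samples: list = field(
        default_factory=lambda: list(SENESCENCE_SAMPLES[1:]))
    stimulation_baseline: str = STIMULATION_SAMPLES[0]
    stimulation_samples: list = field(
        default_factory=lambda: list(STIMULATION_SAMPLES))

    # windows and flanks
    k4_window: int = 300
    k27_window: int = 500
    mark_flank: int = 2000
    medip_window: int = 500
    medip_flank: int = 1000

    # mark thresholds
    k4_hi: float = 4.0
    k4_lo: float = 3.0
    k27_hi: float = 1.5
    k27_lo: float = 1.0
    delta_k27: float = 0.4
    medip_low: float = 2.0
    medip_high: float = 4.0

    # expression
    normalization_target: float = 100.0
    floor: float = 1.0
    de_cutoff: float = 5.0
    active_cutoff: float = 25.0

    # binding-site caller and distance rules
    smad1_window: int = 300
    smad1_p_cutoff: float = 1e-5
    smad1_min_reads: int = 8
    smad1_merge_gap: int = 100
    tss_radius: int = 5000
    gene_halo: int = 10000

    read_mode: str = "5prime"
    seed: int = 0

    def validate(self) -> None:
        for name in ("k4_window", "k27_window", "mark_flank", "medip_window",
                     "medip_flank", "k4_hi", "k4_lo", "k27_hi", "k27_lo",
                     "delta_k27", "floor", "de_cutoff", "active_cutoff",
                     "smad1_window", "smad1_min_reads", "smad1_merge_gap",
                     "tss_radius", "gene_halo", "normalization_target"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: {name} must be positive")
        if not self.condition_samples:
            raise PipelineError("config: condition_samples is empty")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


MARK_TRACKS = ["k4_A", "k4_B", "k27_A", "k27_B"]
MEDIP_TRACKS = ["medip_A", "medip_B"]


def load_inputs(config: PipelineConfig):
    """Read annotation, read tracks and expression named in the config."""
    config.validate()
    missing = [p for p in ([config.annotation_path, config.expression_path]
                           + list(config.reads_paths.values()))
               if p and not os.path.exists(p)]
    if missing:
        raise PipelineError(f"missing input files: {missing}")
    annotation = io.read_gene_annotation(config.annotation_path)
    readsets = {}
    for track, path in config.reads_paths.items():
        readsets[track] = io.read_bed_reads(
            path, sample_id=track,
            total_mapped=config.total_mapped.get(track))
    matrix = io.read_expression_table(config.expression_path)
    return annotation, readsets, matrix


def mark_density_table(readsets: dict, annotation, config: PipelineConfig
                       ) -> pd.DataFrame:
    """Per-gene rpm_max for each histone-mark track (+ MeDIP when present)."""
    specs = {
        "k4": density.WindowSpec(config.k4_window, config.mark_flank),
        "k27": density.WindowSpec(config.k27_window, config.mark_flank),
        "medip": density.WindowSpec(config.medip_window, config.medip_flank),
    }
    out = pd.DataFrame(index=annotation.genes["gene_id"])
    for track in MARK_TRACKS + MEDIP_TRACKS:
        if track not in readsets:
            continue
        mark = track.rsplit("_", 1)[0]
        out[track] = density.gene_status_table(
            readsets[track], annotation, specs[mark], mode=config.read_mode)
    out.index.name = "gene_id"
    return out


def run_all(annotation, readsets: dict, matrix, config: PipelineConfig,
            write: bool = True) -> dict:
    """Execute every stage; returns the run report (a plain dict).

    With ``write=True`` all intermediate tables land in ``config.out_dir``.
    """
    config.validate()
    report: dict = {"provenance": {"config_hash": config.content_hash(),
                                   "seed": config.seed,
                                   "read_mode": config.read_mode}}
    outdir = config.out_dir
    if write:
        os.makedirs(outdir, exist_ok=True)
        config.to_yaml(os.path.join(outdir, "config.yaml"))

    def _stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # expression: normalize, rank, gene sets
    run = _stage("normalize")
    norm = run(expression.normalize_global, matrix, config.normalization_target)
    run = _stage("rank")
    fold = run(expression.fold_change, norm, config.baseline_sample,
               config.condition_samples, config.floor)
    up, down = expression.de_sets(fold, config.de_cutoff)
    stim_fold = None
    active = None
    if all(s in norm.scores.index for s in config.stimulation_samples):
        active = expression.active_genes(norm, config.stimulation_samples,
                                         config.active_cutoff)
        stim_fold = expression.fold_change(
            norm, config.stimulation_baseline,
            [s for s in config.stimulation_samples
             if s != config.stimulation_baseline],
            config.floor)
    report["expression"] = {
        "n_genes": len(fold), "n_up_5x": len(up), "n_down_5x": len(down),
        "n_active": None if active is None else len(active),
    }

    # densities and statuses
    run = _stage("density")
    rpm = run(mark_density_table, readsets, annotation, config)
    th_k4 = transitions.MarkThresholds(config.k4_hi, config.k4_lo)
    th_k27 = transitions.MarkThresholds(config.k27_hi, config.k27_lo)
    run = _stage("status")
    status = run(transitions.build_status_table,
                 rpm[[c for c in MARK_TRACKS if c in rpm.columns]],
                 th_k4, th_k27)
    run = _stage("transitions")
    trans = run(transitions.build_transition_table, rpm, th_k4, th_k27)
    counts = transitions.category_counts(trans)
    report["transitions"] = {k: int(v) for k, v in counts.items()}

    # enrichment of transition categories against the expression ranking
    run = _stage("enrichment")
    enrich = run(stats.transition_expression_report, trans, fold)
    report["enrichment"] = enrich.to_dict("records")

    # binding sites
    sites = None
    assignment = gene_targets = None
    if "smad1" in readsets:
        run = _stage("smad1")
        genome = dict(config.genome) or _infer_genome(annotation, readsets)
        caller = binding.SiteCallerParams(
            window=config.smad1_window, p_cutoff=config.smad1_p_cutoff,
            min_reads=config.smad1_min_reads, merge_gap=config.smad1_merge_gap,
            mode=config.read_mode)
        sites = run(binding.call_sites, readsets["smad1"], genome, caller)
        if len(sites):
            assignment, gene_targets = binding.assign_sites(
                sites, annotation, config.tss_radius, config.gene_halo)
            frac_gene, frac_tss = binding.proximity_fractions(assignment)
            targets = set(gene_targets.loc[gene_targets["is_target"],
                                           "gene_id"])
            report["smad1"] = {
                "n_sites": len(sites), "n_target_genes": len(targets),
                "pct_within_10kb_gene": report_proximity_pct(frac_gene),
                "pct_within_5kb_tss": report_proximity_pct(frac_tss),
                "frac_within_10kb_gene": frac_gene,
                "frac_within_5kb_tss": frac_tss,
            }
            if active is not None and stim_fold is not None:
                ranked_active = stim_fold.loc[stim_fold.index.isin(active)]
                ranked_active = ranked_active.sort_values("rank",
                                                          kind="mergesort")
                ranked_active = ranked_active.assign(
                    rank=range(1, len(ranked_active) + 1))
                universe = set(fold.index)
                fp, ks = binding.target_enrichment(targets, active, universe,
                                                   ranked_active)
                report["smad1"]["fisher_p_active"] = fp
                report["smad1"]["ks_p_upregulated"] = (
                    None if ks is None else ks.p_value)
                report["smad1"]["ks_direction"] = (
                    "" if ks is None else ks.direction)
            delta = transitions.delta_mark_table(
                rpm["k27_A"], rpm["k27_B"], config.delta_k27)
            strata = binding.stratify_targets_by_delta_k27(
                targets, delta, fold)
            report["smad1"]["delta_k27_strata"] = strata.to_dict("records")
        else:
            report["smad1"] = {"n_sites": 0, "untestable": True}

    # MeDIP screen
    medip_candidates = None
    if all(t in rpm.columns for t in MEDIP_TRACKS):
        run = _stage("medip")
        medip_candidates = run(transitions.medip_screen, rpm["medip_A"],
                               rpm["medip_B"], config.medip_low,
                               config.medip_high)
        report["medip"] = {"n_candidates": len(medip_candidates),
                           "candidates": medip_candidates}

    if write:
        io.write_table(fold.reset_index(), os.path.join(outdir, "fold_change.tsv"))
        io.write_table(status, os.path.join(outdir, "mark_status.tsv"),
                       sort_by=["gene_id", "mark", "condition"])
        io.write_table(trans.reset_index(), os.path.join(outdir, "transitions.tsv"))
        io.write_table(enrich, os.path.join(outdir, "enrichment.tsv"),
                       sort_by="category")
        if sites is not None and len(sites):
            io.write_sites_bed(sites, os.path.join(outdir, "smad1_sites.bed"))
            io.write_table(assignment, os.path.join(outdir, "smad1_assignment.tsv"),
                           sort_by="site_id")
            io.write_table(gene_targets, os.path.join(outdir, "smad1_targets.tsv"))
        if medip_candidates is not None:
            pd.DataFrame({"gene_id": medip_candidates}).to_csv(
                os.path.join(outdir, "medip_candidates.tsv"), sep="\t",
                index=False)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def _infer_genome(annotation, readsets: dict) -> dict:
    genome: dict[str, int] = {}
    hi = annotation.genes.groupby("chrom")["end"].max()
    for c, v in hi.items():
        genome[c] = int(v)
    for rs in readsets.values():
        if len(rs.reads) == 0:
            continue
        for c, v in rs.reads.groupby("chrom")["end"].max().items():
            genome[c] = max(genome.get(c, 0), int(v))
    return genome


def report_proximity_pct(fraction: float) -> int:
    """Display percentage: 100 x fraction rounded to the nearest integer."""
    return int(np.rint(100.0 * fraction))


def report_proximity(n_flagged_gene: int, n_flagged_tss: int,
                     n_sites: int) -> tuple[int, int]:
    """(pct within gene halo, pct within TSS radius) from site counts."""
    if n_sites <= 0:
        raise ValueError("no sites: proximity untestable")
    return (report_proximity_pct(n_flagged_gene / n_sites),
            report_proximity_pct(n_flagged_tss / n_sites))
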