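"""End-to-end pipeline: simulate/load -> filter -> annotate -> SV analysis
-> parsimony placement -> NPRS dating -> branch rates.

``run_pipeline`` orchestrates the stages over one dataset, writes the
summary tables (per-species effect categories, SV summaries, branch-rate
table, indel length spectrum, window densities) plus a ``manifest.json``
with per-stage input/kept/removed counts, and returns everything in memory.
Re-running with an identical config and seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import io_formats
from .core import (
    GenomeAnnotation,
    INGROUP_SPECIES,
    SpeciesTree,
    VariantClass,
    VariantRecord,
)
from .effects import classify, mod3_spectrum, summarize_categories, window_density
from .filtering import FilterThresholds, exclude_te, hard_filter
from .phylo import (
    PN_MZ_CALIBRATION_MY,
    assign_branch,
    branch_rates,
    build_presence_matrix,
    nprs_date,
)
from .simulate import SimulatedDataset, SimulationConfig, simulate_dataset
from .sv import (
    SVCallSet,
    esd_test,
    genes_affected,
    go_enrichment,
    per_lg_normalized_counts,
    self_consistency_filter,
)

logger = logging.getLogger("cichlidvar")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (defaults are the study values)."""

    outdir: Optional[str] = None
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # input paths; when None the synthetic generator supplies the data
    vcf_paths: Optional[dict[str, str]] = None
    gff_path: Optional[str] = None
    te_path: Optional[str] = None
    lg_path: Optional[str] = None
    fasta_path: Optional[str] = None
    tree_path: Optional[str] = None
    ref_self_vcf: Optional[str] = None
    gene2go_path: Optional[str] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    reciprocal_overlap: float = 0.5
    esd_alpha: float = 0.05
    esd_r: int = 3
    go_fdr: float = 0.05
    window_bp: int = 50_000
    calibration_clade: frozenset = frozenset({"Pn", "Mz"})
    calibration_age_my: float = PN_MZ_CALIBRATION_MY
    run_dating: bool = True
    nprs_restarts: int = 10


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: Optional[SimulatedDataset]
    annotation: GenomeAnnotation
    tree: SpeciesTree
    kept: dict[str, list[VariantRecord]]
    snp_summary: object
    indel_summary: object
    spectrum: Optional[pd.DataFrame]
    densities: pd.DataFrame
    sv_callsets: dict[str, SVCallSet]
    genes_affected: dict[str, dict[str, set]]
    esd: dict[str, dict[str, int]]
    go: dict[str, pd.DataFrame]
    matrix: object
    assignment: object
    chronogram: Optional[object]
    rates: Optional[pd.DataFrame]
    manifest: dict


def _load_inputs(cfg: PipelineConfig):
    ann = io_formats.parse_annotation(cfg.gff_path, cfg.te_path, cfg.lg_path,
                                      fasta_path=cfg.fasta_path)
    tree = io_formats.parse_tree(cfg.tree_path)
    per_species = {
        sp: io_formats.parse_variants(path, sp)
        for sp, path in cfg.vcf_paths.items()
    }
    ref_self_calls = []
    if cfg.ref_self_vcf:
        ref_self_calls = [
            r for r in io_formats.parse_variants(cfg.ref_self_vcf, "Tilapia")
            if r.is_sv
        ]
    gene2go = io_formats.read_gene2go(cfg.gene2go_path) if cfg.gene2go_path else {}
    return ann, tree, per_species, SVCallSet("Tilapia", ref_self_calls), gene2go


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage; any failure aborts with the stage name attached."""
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    stage = "input"
    try:
        dataset = None
        if cfg.vcf_paths is None:
            dataset = simulate_dataset(cfg.simulation, seed=cfg.seed)
            ann = dataset.annotation
            tree = SpeciesTree.from_newick(dataset.tree_newick)
            per_species = dataset.per_species
            ref_self = dataset.reference_self_calls
            gene2go = dataset.gene2go
        else:
            ann, tree, per_species, ref_self, gene2go = _load_inputs(cfg)
        _log_stage(manifest, "input",
                   {sp: len(v) for sp, v in per_species.items()})

        stage = "hard_filter"
        kept: dict[str, list[VariantRecord]] = {}
        for sp, records in per_species.items():
            small = [r for r in records if not r.is_sv]
            svs = [r for r in records if r.is_sv]
            passed, rejected = hard_filter(small, cfg.thresholds)
            kept[sp] = passed + svs
            _log_stage(manifest, f"hard_filter/{sp}",
                       {"in": len(small), "kept": len(passed),
                        "removed": len(rejected)})

        stage = "te_exclusion"
        for sp in kept:
            passed, excluded = exclude_te(kept[sp], ann)
            _log_stage(manifest, f"te_exclusion/{sp}",
                       {"in": len(kept[sp]), "kept": len(passed),
                        "removed": len(excluded)})
            kept[sp] = passed

        stage = "effect_annotation"
        calls_snp = {sp: [] for sp in kept}
        calls_indel = {sp: [] for sp in kept}
        for sp, records in kept.items():
            for r in records:
                if r.var_class is VariantClass.SNP:
                    calls_snp[sp].append(classify(r, ann))
                elif r.var_class is VariantClass.INDEL:
                    calls_indel[sp].append(classify(r, ann))
        snp_summary = (summarize_categories(calls_snp, VariantClass.SNP)
                       if any(calls_snp.values()) else None)
        indel_summary = (summarize_categories(calls_indel, VariantClass.INDEL)
                         if any(calls_indel.values()) else None)
        all_indel_calls = [c for calls in calls_indel.values() for c in calls]
        spectrum = (mod3_spectrum(all_indel_calls,
                                  max_len=cfg.simulation.indel_max_len)
                    if all_indel_calls else None)
        densities = window_density(
            [r for rs in kept.values() for r in rs
             if r.var_class is VariantClass.SNP],
            ann, window=cfg.window_bp)
        _log_stage(manifest, "effect_annotation",
                   {sp: len(calls_snp[sp]) + len(calls_indel[sp])
                    for sp in kept})

        stage = "sv_consolidation"
        sv_callsets: dict[str, SVCallSet] = {}
        genes_hit: dict[str, dict[str, set]] = {}
        esd_out: dict[str, dict[str, int]] = {}
        go_out: dict[str, pd.DataFrame] = {}
        for sp in kept:
            calls = SVCallSet(sp, [r for r in kept[sp] if r.is_sv])
            filtered, removed = self_consistency_filter(calls, ref_self)
            _log_stage(manifest, f"sv_self_consistency/{sp}",
                       {"in": len(calls.calls), "kept": len(filtered.calls),
                        "removed": len(removed.calls)})
            sv_callsets[sp] = filtered
            genes_hit[sp] = {}
            esd_out[sp] = {}
            for vc in (VariantClass.INVERSION, VariantClass.DELETION):
                one = SVCallSet(sp, filtered.by_class(vc))
                genes_hit[sp][vc.value] = genes_affected(one, ann)
                counts = per_lg_normalized_counts(filtered, ann, vc)
                if len(counts) >= 3 and cfg.esd_r <= len(counts) - 2:
                    res = esd_test(counts.values, alpha=cfg.esd_alpha,
                                   r=cfg.esd_r)
                    esd_out[sp][vc.value] = res.n_outliers
            if gene2go:
                affected_all = set().union(*genes_hit[sp].values())
                universe = {g.gene_id for g in ann.genes}
                go_out[sp] = go_enrichment(affected_all & universe, universe,
                                           gene2go, fdr=cfg.go_fdr)

        stage = "presence_matrix"
        per_sp_for_matrix = {
            sp: [r for r in kept[sp] if not r.is_sv] + list(sv_callsets[sp].calls)
            for sp in kept
        }
        matrix = build_presence_matrix(per_sp_for_matrix,
                                       reciprocal=cfg.reciprocal_overlap)
        _log_stage(manifest, "presence_matrix", {"variants": len(matrix)})

        stage = "parsimony_assignment"
        assignment = assign_branch(matrix, tree)
        n_assigned = len(assignment.assignments) - assignment.n_excluded
        _log_stage(manifest, "parsimony_assignment",
                   {"in": len(matrix), "assigned": n_assigned,
                    "excluded": assignment.n_excluded})

        chronogram = None
        rates = None
        if cfg.run_dating:
            stage = "nprs_dating"
            chronogram = nprs_date(
                tree, (cfg.calibration_clade, cfg.calibration_age_my),
                n_restarts=cfg.nprs_restarts, seed=cfg.seed)
            _log_stage(manifest, "nprs_dating",
                       {"objective": chronogram.objective,
                        "converged": chronogram.converged})
            stage = "branch_rates"
            rates = branch_rates(assignment, chronogram)
            _log_stage(manifest, "branch_rates", {"rows": len(rates)})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result = PipelineResult(
        config=cfg, dataset=dataset, annotation=ann, tree=tree, kept=kept,
        snp_summary=snp_summary, indel_summary=indel_summary,
        spectrum=spectrum, densities=densities, sv_callsets=sv_callsets,
        genes_affected=genes_hit, esd=esd_out, go=go_out, matrix=matrix,
        assignment=assignment, chronogram=chronogram, rates=rates,
        manifest=manifest,
    )
    if cfg.outdir:
        _write_outputs(result, cfg.outdir)
    return result


def _log_stage(manifest: dict, name: str, counts: dict) -> None:
    manifest["stages"][name] = counts
    logger.info("stage=%s %s", name,
                " ".join(f"{k}={v}" for k, v in counts.items()))


def _write_outputs(res: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    if res.snp_summary is not None:
        res.snp_summary.counts.to_csv(os.path.join(outdir, "snp_categories.tsv"),
                                      sep="\t")
        res.snp_summary.percentages.to_csv(
            os.path.join(outdir, "snp_category_percent.tsv"), sep="\t")
    if res.indel_summary is not None:
        res.indel_summary.counts.to_csv(
            os.path.join(outdir, "indel_categories.tsv"), sep="\t")
    if res.spectrum is not None:
        res.spectrum.to_csv(os.path.join(outdir, "indel_spectrum.tsv"),
                            sep="\t", index=False)
    # window densities in bedGraph layout (0-based half-open)
    bg = res.densities.copy()
    bg["start0"] = bg["window_start"] - 1
    bg[["lg", "start0", "window_end", "count"]].to_csv(
        os.path.join(outdir, "snp_density.bedgraph"), sep="\t",
        index=False, header=False)
    sv_rows = []
    for sp, per_class in res.genes_affected.items():
        for vc, genes in per_class.items():
            calls = res.sv_callsets[sp].by_class(VariantClass(vc))
            lengths = [c.span_length for c in calls]
            sv_rows.append({
                "species": sp, "var_class": vc, "number": len(calls),
                "longest_bp": max(lengths) if lengths else 0,
                "shortest_bp": min(lengths) if lengths else 0,
                "average_bp": round(sum(lengths) / len(lengths)) if lengths else 0,
                "genes_affected": len(genes),
                "esd_outlier_lgs": res.esd.get(sp, {}).get(vc, 0),
            })
    pd.DataFrame(sv_rows).to_csv(os.path.join(outdir, "sv_summary.tsv"),
                                 sep="\t", index=False)
    if res.rates is not None:
        res.rates.drop(columns=["clade"]).to_csv(
            os.path.join(outdir, "branch_rates.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True)
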