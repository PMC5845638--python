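"""End-to-end orchestration: simulate -> infer -> phenotype stats -> scan ->
classify -> candidate filter, with a manifest for reproducibility.

The run directory receives every stage's tabular output plus a
``manifest.json`` recording the configuration hash, the seed, per-stage row
counts and a checksum per output file (text files by byte content; the
probability-grid container by the digest of its arrays, so the manifest is
invariant to archive metadata).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import candidates as cand
from . import config as cfgmod
from . import infer as inf
from . import io as mio
from . import pheno as ph
from . import qtl as qt
from . import simulate as sim
from .config import PipelineConfig
from .gmap import GeneticMap

__all__ = ["PipelineError", "simulate_dataset", "run_pipeline"]

log = logging.getLogger("magicqtl")

VERSION = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause

    def record(self) -> dict:
        return {"stage": self.stage, "error": str(self.cause)}


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_dataset(config: PipelineConfig) -> dict:
    """Generate the full synthetic dataset a run analyses.

    Returns a dict with keys: gmap, founders, variants, genes, genotypes
    (observed, error-injected), genotypes_true, mosaic, phenotypes
    (PhenotypeTable), log_traits.
    """
    sc = config.simulate
    seeds = _spawn_seeds(config.seed, 4 + len(sc.experiments))
    gmap = sim.default_map(
        n_markers=sc.map.n_markers,
        n_chromosomes=sc.map.n_chromosomes,
        total_cM=sc.map.total_cM,
        bp_per_cM=sc.map.bp_per_cM,
        seed=seeds[0],
    )
    founders, variants, genes = sim.simulate_founders(
        gmap,
        diversity=sc.founders.diversity,
        n_genes_per_chrom=sc.founders.n_genes_per_chrom,
        n_variants_per_gene_region=sc.founders.n_variants_per_gene_region,
        gene_flank_bp=sc.founders.gene_flank_bp,
        seed=seeds[1],
        founders=tuple(sc.founders.names),
    )
    genotypes_true, mosaic = sim.simulate_magic_lines(
        founders,
        gmap,
        n_lines=sc.lines.n_lines,
        n_selfing_generations=sc.lines.n_selfing_generations,
        fixed_funnel=sc.lines.fixed_funnel,
        seed=seeds[2],
    )
    genotypes = (
        sim.add_genotyping_error(genotypes_true, sc.lines.genotyping_error, seed=seeds[3])
        if sc.lines.genotyping_error > 0
        else genotypes_true
    )
    frames = []
    log_traits = set()
    for ei, exp in enumerate(sc.experiments):
        for tc in exp.traits:
            arch = sim.TraitArchitecture(
                trait=tc.trait,
                qtls=tuple(
                    sim.QtlSpec(
                        chrom=q.chrom,
                        position_cM=q.position_cM,
                        effects=tuple(q.effects),
                        treatment_scale=dict(q.treatment_scale),
                    )
                    for q in tc.qtls
                ),
                mu=tc.mu,
                treatment_offsets=dict(tc.treatment_offsets),
                target_h2=tc.target_h2,
                residual_var=tc.residual_var,
                n_replicates=tc.n_replicates,
                transform=tc.transform,
            )
            if tc.transform == "log":
                log_traits.add(tc.trait)
            frames.append(
                sim.simulate_phenotypes(
                    mosaic,
                    gmap,
                    arch,
                    treatments=list(exp.treatments),
                    experiment=exp.name,
                    seed=(seeds[4 + ei] + zlib.crc32(tc.trait.encode())) % (2**31),
                )
            )
    pheno_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["line", "experiment", "treatment", "replicate", "trait", "value"]
        )
    )
    table = ph.PhenotypeTable(data=pheno_df, log_traits=frozenset(log_traits))
    return {
        "gmap": gmap,
        "founders": founders,
        "variants": variants,
        "genes": genes,
        "genotypes": genotypes,
        "genotypes_true": genotypes_true,
        "mosaic": mosaic,
        "phenotypes": table,
        "log_traits": log_traits,
    }


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _grid_digest(grid: inf.FounderProbabilityGrid) -> str:
    h = hashlib.sha256()
    for chrom in grid.chromosomes:
        h.update(grid.positions[chrom].tobytes())
        h.update(np.ascontiguousarray(grid.probs[chrom]).tobytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis and write all stage outputs.

    Returns the manifest (also written to ``manifest.json``).  Any stage
    failure raises :class:`PipelineError` naming the stage, after writing a
    machine-readable error record to the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfgmod.config_hash(config),
        "seed": config.seed,
        "version": VERSION,
        "stages": {},
        "files": {},
        "warnings": 0,
    }
    (out / "config.yaml").write_text(cfgmod.serialize(config))

    stage = "simulate"
    try:
        data = simulate_dataset(config)
        gmap: GeneticMap = data["gmap"]
        gmap.to_tsv(out / "map.tsv")
        mio.write_genotype_vcf(out / "genotypes.vcf", gmap, data["founders"], data["genotypes"])
        mio.write_genotype_tsv(out / "genotypes.tsv", data["genotypes"])
        mio.write_phenotypes_csv(out / "phenotypes.csv", data["phenotypes"])
        mio.write_variants_vcf(out / "variants.vcf", data["variants"])
        mio.write_variants_tsv(out / "variants.tsv", data["variants"])
        mio.write_genes_bed(out / "genes.bed", data["genes"])
        mio.write_genes_gff3(out / "genes.gff3", data["genes"])
        manifest["stages"][stage] = {
            "n_markers": gmap.n_markers,
            "n_lines": len(data["genotypes"]),
            "n_phenotype_rows": len(data["phenotypes"].data),
            "n_variants": len(data["variants"].table),
            "n_genes": len(data["genes"].table),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail(out, stage, exc)

    stage = "infer-founders"
    try:
        ac = config.analysis
        grid = inf.infer_founder_probabilities(
            data["genotypes"],
            data["founders"],
            gmap,
            error_rate=ac.error_rate,
            grid_step_cM=ac.grid_step_cM,
            n_meioses=ac.n_meioses
            if ac.n_meioses is not None
            else sim.expected_meioses(config.simulate.lines.n_selfing_generations),
        )
        grid.save_npz(out / "founder_probs.npz")
        assignment = inf.assign_founder(grid, threshold=ac.assignment_threshold)
        summary = inf.assignment_summary(grid, assignment, truth=data["mosaic"])
        (out / "assignment_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["stages"][stage] = {
            "n_positions": summary["n_positions"],
            "assigned_fraction": summary["assigned_fraction"],
            "accuracy": summary.get("accuracy"),
        }
    except Exception as exc:  # noqa: BLE001
        _fail(out, stage, exc)

    stage = "pheno-stats"
    try:
        table = data["phenotypes"]
        anova_rows, h2_rows, pp_frames, mv_rows, corr_frames = [], [], [], [], []
        for exp in config.simulate.experiments:
            treatments = list(exp.treatments)
            control, *stresses = treatments
            for tc in exp.traits:
                if len(treatments) >= 2:
                    res = ph.two_way_anova(table, tc.trait, exp.name)
                    for term, row in res.terms.iterrows():
                        anova_rows.append(
                            {"trait": tc.trait, "experiment": exp.name, "term": term, **row}
                        )
                for tr in treatments:
                    h = ph.heritability(table, tc.trait, exp.name, tr, r_mode=config.analysis.r_mode)
                    h2_rows.append(
                        {
                            "trait": tc.trait,
                            "experiment": exp.name,
                            "treatment": tr,
                            "sigma2_g": h.sigma2_g,
                            "sigma2_e": h.sigma2_e,
                            "r": h.r,
                            "h2": h.h2,
                        }
                    )
                for strs in stresses:
                    pp_frames.append(ph.plasticity(table, tc.trait, exp.name, control, strs))
                    mv_rows.append(
                        {
                            "trait": tc.trait,
                            "experiment": exp.name,
                            "reference": control,
                            "target": strs,
                            "mv_pct": ph.mean_relative_variation(
                                table,
                                tc.trait,
                                (exp.name, control),
                                (exp.name, strs),
                                paired=config.analysis.mv_paired,
                            ),
                        }
                    )
            corr_frames.append(ph.correlations(table, exp.name).assign(experiment=exp.name))
        pd.DataFrame(anova_rows).to_csv(out / "anova_terms.csv", index=False)
        pd.DataFrame(h2_rows).to_csv(out / "heritability.csv", index=False)
        pp_all = (
            pd.concat(pp_frames, ignore_index=True)
            if pp_frames
            else pd.DataFrame(columns=["line", "experiment", "trait", "pp", "qtl_value"])
        )
        pp_all.to_csv(out / "plasticity.csv", index=False)
        pd.DataFrame(mv_rows).to_csv(out / "mean_relative_variation.csv", index=False)
        (
            pd.concat(corr_frames, ignore_index=True)
            if corr_frames
            else pd.DataFrame()
        ).to_csv(out / "correlations.csv", index=False)
        manifest["stages"][stage] = {
            "n_anova_rows": len(anova_rows),
            "n_h2_rows": len(h2_rows),
            "n_plasticity_rows": len(pp_all),
        }
    except Exception as exc:  # noqa: BLE001
        _fail(out, stage, exc)

    stage = "scan"
    try:
        records: list[qt.QtlRecord] = []
        profiles = []
        scan_pheno: dict[str, pd.Series] = {}
        for exp in config.simulate.experiments:
            treatments = list(exp.treatments)
            control, *stresses = treatments
            for tc in exp.traits:
                for tr in treatments:
                    context = f"{exp.name}:{tr}"
                    y = table.line_means(tc.trait, exp.name, tr)
                    profile = qt.scan(grid, y, tc.trait, context)
                    profiles.append(profile.table.assign(trait=tc.trait, context=context))
                    scan_pheno[f"{tc.trait}|{context}"] = y
                    records.extend(
                        qt.call_peaks(profile, grid, y, gmap, config.analysis.lod_threshold)
                    )
                if config.analysis.map_plasticity:
                    for strs in stresses:
                        context = f"{qt.PLASTICITY_PREFIX}{exp.name}"
                        pp = ph.plasticity(table, tc.trait, exp.name, control, strs)
                        y = pp.set_index("line")["qtl_value"]
                        profile = qt.scan(grid, y, tc.trait, context)
                        profiles.append(profile.table.assign(trait=tc.trait, context=context))
                        scan_pheno[f"{tc.trait}|{context}"] = y
                        records.extend(
                            qt.call_peaks(profile, grid, y, gmap, config.analysis.lod_threshold)
                        )
        founders_t = tuple(config.simulate.founders.names)
        pd.concat(profiles, ignore_index=True).to_csv(out / "lod_profiles.csv", index=False)
        mio.write_qtl_table(out / "qtl_table.csv", records, founders_t)
        manifest["stages"][stage] = {"n_scans": len(profiles), "n_qtl": len(records)}
    except Exception as exc:  # noqa: BLE001
        _fail(out, stage, exc)

    stage = "classify-qtl"
    try:
        classification = qt.classify_qtl(records)
        classification.to_frame().to_csv(out / "classification.csv", index=False)
        classification.venn_counts().to_csv(out / "venn_counts.csv", index=False)
        manifest["stages"][stage] = {
            "n_merged_qtl": len(classification.groups),
            "labels": {
                str(k): int(v)
                for k, v in pd.Series(classification.labels).value_counts().sort_index().items()
            }
            if classification.labels
            else {},
        }
    except Exception as exc:  # noqa: BLE001
        _fail(out, stage, exc)

    stage = "filter-cg"
    try:
        reports, listings = [], []
        max_bp = config.analysis.max_ci_mb * 1e6
        for rec in records:
            if rec.ci_high_bp - rec.ci_low_bp >= max_bp:
                continue
            pattern = config.analysis.groupings.get(rec.trait)
            if pattern:
                grouping = cand.parse_grouping(pattern, founders_t)
            elif config.analysis.suggest_groupings:
                grouping, _note = cand.suggest_grouping(rec.effects_centered, founders_t)
                if grouping is None:
                    continue
            else:
                continue
            summary, listing = cand.cg_report(rec, grouping, data["variants"], data["genes"])
            reports.append(summary)
            listings.append(listing)
        (
            pd.DataFrame(reports)
            if reports
            else pd.DataFrame(
                columns=[
                    "trait", "context", "chrom", "peak_cM", "ci_low_bp", "ci_high_bp",
                    "ci_size_bp", "filter", "n_genes", "n_polymorphisms",
                    "n_candidate_genes", "n_candidate_polymorphisms",
                ]
            )
        ).to_csv(out / "cg_report.csv", index=False)
        (
            pd.concat(listings, ignore_index=True)
            if listings
            else pd.DataFrame(columns=["chrom", "pos", "gene", "effect", "annotation"])
        ).to_csv(out / "cg_candidates.csv", index=False)
        manifest["stages"][stage] = {"n_qtl_filtered": len(reports)}
    except Exception as exc:  # noqa: BLE001
        _fail(out, stage, exc)

    for path in sorted(out.glob("*")):
        if path.name in ("manifest.json", "founder_probs.npz") or path.is_dir():
            continue
        manifest["files"][path.name] = _file_digest(path)
    manifest["files"]["founder_probs.npz"] = _grid_digest(grid)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _fail(out: Path, stage: str, exc: Exception) -> None:
    err = PipelineError(stage, exc)
    (out / "error.json").write_text(json.dumps(err.record(), indent=2))
    log.error("stage %s failed: %s", stage, exc)
    raise err from exc
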