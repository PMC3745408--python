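"""End-to-end orchestration: simulate/load -> QC -> ROH -> association -> sweep.

A single :class:`PipelineConfig` (constructible from a YAML file) drives
one deterministic run.  Outputs are plain-text artefacts in the output
directory: a QC log, BED files of segments and core regions, TSV
association tables (raw and Bonferroni-corrected), a burden report
(Froh, inbreeding F, length comparison), sweep profiles and a JSON run
manifest.  Rerunning with the same (config, seed) reproduces every file
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .association import (
    AssocResult,
    bonferroni,
    fisher_carrier_test,
    kmeans_dichotomize,
    logistic_trait_regression,
    quantitative_trait_regression,
    stouffer_combine,
)
from .io_formats import (
    read_phenotypes,
    read_vcf,
    write_phenotypes,
    write_regions_bed,
    write_roh_bed,
    write_vcf,
)
from .roh import (
    RohParams,
    carrier_matrix,
    compare_roh_length,
    core_regions,
    detect_roh,
    froh,
    hwe_filter,
    inbreeding_f,
    mappable_length,
    prevalence_filter,
)
from .simulate import (
    SimulationConfig,
    SweepConfig,
    plant_sweep,
    simulate_cohort,
    simulate_haplotype_pool,
    simulate_phenotypes,
)
from .sweep import enumerate_cores, rehh, sweep_flag

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "replicate_combine"]


@dataclass
class PipelineConfig:
    """One run's inputs, thresholds and output location."""

    out_dir: str = "rohscan_out"
    seed: int = 0
    # exactly one input source: files or a simulation
    vcf_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    # analysis settings
    hwe_alpha: float = 5e-5
    roh: RohParams = field(default_factory=RohParams)
    min_share: int = 10
    min_control_prev: float = 0.01
    covariates: Sequence[str] = ("sex", "maternal_edu", "paternal_edu", "scq")
    alpha: float = 0.05
    sweep_core_span: Optional[tuple] = None   # (first, last) SNP index
    rehh_min: float = 2.0
    sweep_dist_bp: int = 200_000
    pool_haplotypes: int = 400

    def validate(self) -> None:
        has_files = self.vcf_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError("configure exactly one input source "
                             "(vcf_path xor simulation)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            if "sweep" in sim and sim["sweep"] is not None:
                sim["sweep"] = SweepConfig(**sim["sweep"])
            raw["simulation"] = SimulationConfig(**sim)
        if "roh" in raw:
            raw["roh"] = RohParams(**raw["roh"])
        if "sweep_core_span" in raw and raw["sweep_core_span"] is not None:
            raw["sweep_core_span"] = tuple(raw["sweep_core_span"])
        return cls(**raw)


def _assoc_table(results, p_bonf, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlength\ttest\teffect\tse\tp\tp_bonf\t"
                 "n_used\tr_case\tr_ctrl\tflags\n")
        for res, pb in zip(results, p_bonf):
            r = res.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.length}\t{res.test}\t"
                     f"{res.effect:.6g}\t{res.se:.6g}\t{res.p:.6g}\t{pb:.6g}\t"
                     f"{res.n_used}\t{r.rate_case:.6g}\t{r.rate_ctrl:.6g}\t"
                     f"{','.join(res.flags)}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the results.

    The returned dict holds the in-memory objects of each stage
    (variants, genotypes, segments, regions, association results,
    burden report, sweep profiles, truth when simulated).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"counts": {}}
    stage = "input"
    try:
        truth = None
        if config.simulation is not None:
            stage = "simulate"
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            pool = simulate_haplotype_pool(config.pool_haplotypes, sim)
            if sim.sweep is not None:
                swept, sweep_truth = plant_sweep(pool, sim.sweep,
                                                 seed=sim.seed + 3)
                pool = (pool[0], swept)
            genotypes, haplotypes, truth = simulate_cohort(pool, sim)
            variants = pool[0]
            sample = simulate_phenotypes(truth, sim, genotypes.sample_ids)
            if sim.sweep is not None:
                truth.sweep_core_haplotype = sweep_truth.sweep_core_haplotype
                truth.sweep_carrier_rows = sweep_truth.sweep_carrier_rows
            write_vcf(out / "cohort.vcf", variants, haplotypes=haplotypes)
            write_phenotypes(out / "phenotypes.tsv", sample)
            truth.to_json(out / "truth.json")
        else:
            stage = "load"
            variants, genotypes, haplotypes = read_vcf(
                config.vcf_path, require_phased=config.sweep_core_span is not None)
            sample = read_phenotypes(config.phenotype_path)
            sample = sample.aligned_to(genotypes.sample_ids)

        stage = "hwe_filter"
        n_before = variants.n_snps
        variants, genotypes = hwe_filter(genotypes, variants,
                                         alpha=config.hwe_alpha, sample=sample)
        report["counts"]["snps_in"] = n_before
        report["counts"]["snps_after_hwe"] = variants.n_snps

        stage = "roh"
        segments = detect_roh(genotypes, variants, config.roh)
        write_roh_bed(segments, out / "roh_segments.bed")
        regions = core_regions(segments, variants, min_share=config.min_share,
                               mode="plateau")
        report["counts"]["segments"] = len(segments)
        report["counts"]["core_regions"] = len(regions)
        matrix = carrier_matrix(segments, regions, genotypes.sample_ids)
        matrix, regions = prevalence_filter(matrix, sample,
                                            config.min_control_prev)
        report["counts"]["regions_after_prevalence"] = len(regions)
        write_regions_bed(regions, out / "core_regions.bed")

        stage = "burden"
        froh_map = froh(segments, mappable_length(variants),
                        sample_ids=genotypes.sample_ids)
        f_map = inbreeding_f(genotypes, variants)
        with open(out / "burden.tsv", "w") as fh:
            fh.write("individual_id\tfroh\tinbreeding_f\n")
            for iid in genotypes.sample_ids:
                fh.write(f"{iid}\t{froh_map[iid]:.6g}\t{f_map[iid]:.6g}\n")
        length_cmp = None
        try:
            length_cmp = compare_roh_length(segments, sample)
            with open(out / "length_comparison.tsv", "w") as fh:
                fh.write("mean_case\tmean_ctrl\tz\tp_one_sided\tp_two_sided\n")
                fh.write(f"{length_cmp.mean_case:.6g}\t{length_cmp.mean_ctrl:.6g}"
                         f"\t{length_cmp.z:.4f}\t{length_cmp.p_one_sided:.6g}\t"
                         f"{length_cmp.p_two_sided:.6g}\n")
        except ValueError:
            log.info("length comparison skipped (too few segments per group)")

        stage = "association"
        assoc: dict = {}
        if matrix.n_regions:
            fisher = fisher_carrier_test(matrix, sample)
            pb, thr = bonferroni([r.p for r in fisher], config.alpha)
            for r, p in zip(fisher, pb):
                r.p_bonferroni = float(p)
            _assoc_table(fisher, pb, out / "assoc_case_control.tsv")
            assoc["fisher"] = fisher
            linear = quantitative_trait_regression(matrix, sample,
                                                   config.covariates)
            p_lin = [r.p if np.isfinite(r.p) else 1.0 for r in linear]
            pb_lin, thr_lin = bonferroni(p_lin, config.alpha)
            for r, p in zip(linear, pb_lin):
                r.p_bonferroni = float(p)
            _assoc_table(linear, pb_lin, out / "assoc_afp_linear.tsv")
            assoc["linear"] = linear
            assoc["bonferroni_threshold"] = thr_lin
            afp = sample.table["afp_months"].to_numpy(dtype=float)
            if np.isfinite(afp).sum() >= 2 and \
                    len(np.unique(afp[np.isfinite(afp)])) >= 2:
                dich = kmeans_dichotomize(afp)
                with open(out / "dichotomy.tsv", "w") as fh:
                    fh.write("cutoff_months\tmean_early\tmean_late\n")
                    fh.write(f"{dich.cutoff:.6g}\t{dich.cluster_means[0]:.6g}\t"
                             f"{dich.cluster_means[1]:.6g}\n")
                logistic = logistic_trait_regression(matrix, sample, dich,
                                                     config.covariates)
                p_log = [r.p if np.isfinite(r.p) else 1.0 for r in logistic]
                pb_log, _ = bonferroni(p_log, config.alpha)
                for r, p in zip(logistic, pb_log):
                    r.p_bonferroni = float(p)
                _assoc_table(logistic, pb_log, out / "assoc_afp_logistic.tsv")
                assoc["logistic"] = logistic
                assoc["dichotomy"] = dich

        stage = "sweep"
        sweep_out = None
        if config.sweep_core_span is not None and haplotypes is not None:
            cores = enumerate_cores(haplotypes, config.sweep_core_span, variants)
            usable = [c for c in cores if c.n_carriers >= 2]
            profiles = {}
            with open(out / "sweep_profiles.tsv", "w") as fh:
                fh.write("core\tside\tposition\tdistance_bp\tehh_focal\t"
                         "ehh_others\trehh\n")
                for c in usable:
                    others = [o for o in usable if o is not c]
                    if not others:
                        continue
                    sides = []
                    for side in ("left", "right"):
                        prof = rehh(haplotypes, c, others, side, variants)
                        sides.append(prof)
                        for k in range(len(prof.positions)):
                            fh.write(f"{c.label}\t{side}\t{prof.positions[k]}\t"
                                     f"{prof.distance_bp[k]}\t"
                                     f"{prof.ehh_focal[k]:.6g}\t"
                                     f"{prof.ehh_others[k]:.6g}\t"
                                     f"{prof.rehh[k]:.6g}\n")
                    profiles[c.label] = (
                        sides, sweep_flag(sides, config.rehh_min,
                                          config.sweep_dist_bp))
            sweep_out = profiles

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "counts": report["counts"],
            "config": {k: v for k, v in _config_dict(config).items()
                       if k != "out_dir"},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report.update({
        "variants": variants, "genotypes": genotypes, "sample": sample,
        "segments": segments, "regions": regions, "matrix": matrix,
        "froh": froh_map, "inbreeding_f": f_map, "length": length_cmp,
        "association": assoc, "sweep": sweep_out, "truth": truth,
    })
    return report


def _config_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, (tuple, list)):
            return [convert(x) for x in obj]
        return obj
    return {k: convert(v) for k, v in dataclasses.asdict(config).items()}


def replicate_combine(assoc_a: AssocResult, assoc_b: AssocResult,
                      n_a: int = None, n_b: int = None):
    """Stouffer combination of one region's evidence from two cohorts.

    Both results must refer to the same region interval.  Returns a dict
    with the unweighted combined (z, p) and, when sample sizes are
    given, the sqrt(n)-weighted "z trend" variant.
    """
    ra, rb = assoc_a.region, assoc_b.region
    if (ra.chrom, ra.start, ra.end) != (rb.chrom, rb.start, rb.end):
        raise ValueError("results refer to different regions")
    z, p = stouffer_combine([assoc_a.p, assoc_b.p])
    out = {"z": z, "p": p}
    if n_a is not None and n_b is not None:
        w = np.sqrt([n_a, n_b])
        zt, pt = stouffer_combine([assoc_a.p, assoc_b.p], weights=w)
        out["z_trend"] = zt
        out["p_trend"] = pt
    return out
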