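"""Seeded evaluation protocols for pipeline calibration and recovery.

Each function simulates cohorts under fixed study conditions, runs the
relevant pipeline stages from scratch and returns a summary rate.  They
back both the test suite and the reproduction script; all randomness is
controlled by the ``seed`` argument.

Problem sizes are desk-scale stand-ins for the array-scale study being
emulated: one chromosome of 10-15 Mb with 1,200-2,000 SNPs, cohorts of
300-500 individuals, and 50-100 replicates per summary.
"""

from __future__ import annotations

import numpy as np

from .association import quantitative_trait_regression
from .roh import carrier_matrix, core_regions, detect_roh, froh, mappable_length
from .simulate import (
    SimulationConfig,
    SweepConfig,
    plant_sweep,
    simulate_cohort,
    simulate_haplotype_pool,
    simulate_phenotypes,
)
from .sweep import enumerate_cores, rehh, sweep_flag

__all__ = [
    "type_i_error_rate", "effect_recovery_coverage", "froh_recovery",
    "sweep_detection_rates",
]


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def type_i_error_rate(seed: int, min_tests: int = 1000,
                      max_cohorts: int = 200):
    """Fraction of null region tests rejecting at p < 0.05.

    Cohorts of 300 individuals carry background autozygosity but no
    planted trait region and a beta = 0 phenotype; every consensus
    region's carrier indicator is regressed against AFP.  Returns
    ``(rate, n_tests)`` once at least ``min_tests`` regions have been
    tested.
    """
    hits = 0
    n_tests = 0
    for s in _seeds(seed, max_cohorts):
        cfg = SimulationConfig(
            n_snps=1500, chrom_length_bp=15_000_000, n_cases=150,
            n_controls=150, autozygosity_rate=0.6, segment_min_bp=500_000,
            segment_max_bp=900_000, carrier_beta=0.0, seed=int(s))
        pool = simulate_haplotype_pool(300, cfg)
        genotypes, _, truth = simulate_cohort(pool, cfg)
        sample = simulate_phenotypes(truth, cfg, genotypes.sample_ids)
        segments = detect_roh(genotypes, pool[0])
        regions = core_regions(segments, pool[0], min_share=10,
                               mode="plateau")
        if not regions:
            continue
        matrix = carrier_matrix(segments, regions, genotypes.sample_ids)
        for res in quantitative_trait_regression(matrix, sample):
            if np.isfinite(res.p):
                n_tests += 1
                hits += res.p < 0.05
        if n_tests >= min_tests:
            break
    return hits / n_tests, n_tests


def effect_recovery_coverage(seed: int, n_replicates: int = 100,
                             beta: float = 30.0):
    """Share of replicates whose carrier estimate lies within +/-2 SE of beta.

    Each replicate plants a trait region at 10% carrier prevalence in a
    300-individual cohort (AFP noise SD 18.29 months), re-detects ROHs,
    rebuilds the consensus region and regresses AFP on the recovered
    carrier indicator.  Returns ``(coverage, n_informative)``.
    """
    cover = 0
    used = 0
    for s in _seeds(seed + 1, n_replicates):
        cfg = SimulationConfig(
            n_snps=1200, chrom_length_bp=12_000_000, n_cases=150,
            n_controls=150, autozygosity_rate=0.0,
            planted_region=(550, 650), planted_carrier_freq=0.10,
            carrier_beta=beta, afp_sd=18.29, seed=int(s))
        pool = simulate_haplotype_pool(300, cfg)
        genotypes, _, truth = simulate_cohort(pool, cfg)
        sample = simulate_phenotypes(truth, cfg, genotypes.sample_ids)
        segments = detect_roh(genotypes, pool[0])
        regions = core_regions(segments, pool[0], min_share=10,
                               mode="plateau")
        pos = pool[0].pos
        span = (int(pos[550]), int(pos[650]))
        hit = [i for i, r in enumerate(regions)
               if r.start <= span[1] and r.end >= span[0]]
        if not hit:
            continue
        matrix = carrier_matrix(segments, regions, genotypes.sample_ids)
        res = quantitative_trait_regression(matrix, sample)[hit[0]]
        if np.isfinite(res.effect):
            used += 1
            cover += abs(res.effect - beta) < 2 * res.se
    return (cover / used if used else float("nan")), used


def froh_recovery(seed: int, n_individuals: int = 500,
                  target_fraction: float = 0.05):
    """Mean Froh when every individual carries one ~5%-of-chromosome segment.

    Segments are drawn uniformly on 400-600 kb over a 10 Mb chromosome
    (mean 500 kb = 5% of the map), called back with the default ROH
    rules and summarised as the cohort mean Froh.
    """
    half = n_individuals // 2
    cfg = SimulationConfig(
        n_snps=1500, chrom_length_bp=10_000_000, n_cases=half,
        n_controls=n_individuals - half, autozygosity_rate=1.0,
        segment_min_bp=int(target_fraction * 10_000_000 * 0.8),
        segment_max_bp=int(target_fraction * 10_000_000 * 1.2), seed=seed)
    pool = simulate_haplotype_pool(400, cfg)
    genotypes, _, _ = simulate_cohort(pool, cfg)
    segments = detect_roh(genotypes, pool[0])
    values = froh(segments, mappable_length(pool[0]), genotypes.sample_ids)
    return float(np.mean(list(values.values())))


def _scan_core(haplotypes, variants, core_span, focal_alleles=None):
    cores = enumerate_cores(haplotypes, core_span)
    usable = [c for c in cores if c.n_carriers >= 2]
    if focal_alleles is not None:
        focal = next((c for c in usable if c.alleles == focal_alleles), None)
    else:
        focal = usable[0] if usable else None
    if focal is None:
        return None
    others = [c for c in usable if c is not focal]
    if not others:
        return None
    profiles = [rehh(haplotypes, focal, others, side, variants)
                for side in ("left", "right")]
    return sweep_flag(profiles)


def sweep_detection_rates(seed: int, n_replicates: int = 50):
    """Sweep-flag rates on planted-sweep pools and matched neutral pools.

    Each replicate draws a 400-haplotype pool (2,000 SNPs, 10 Mb), plants
    a five-SNP core sweep at carrier frequency 0.4 with a 300 kb shared
    flank, and scans the swept core; the matched neutral replicate scans
    the most frequent core of the same pool without the sweep.  Returns
    ``(detection_rate, neutral_rate)``.
    """
    span = (1000, 1004)
    hits = []
    neutral = []
    for s in _seeds(seed + 2, n_replicates):
        cfg = SimulationConfig(n_snps=2000, chrom_length_bp=10_000_000,
                               seed=int(s))
        pool = simulate_haplotype_pool(400, cfg)
        sw = SweepConfig(core_start=span[0], core_n_snps=5,
                         carrier_frequency=0.4, flank_bp=300_000)
        swept, truth = plant_sweep(pool, sw, seed=int(s) % (2**31 - 7))
        focal = tuple(int(x) for x in truth.sweep_core_haplotype)
        hits.append(_scan_core(swept, pool[0], span, focal) is True)
        neutral.append(_scan_core(pool[1], pool[0], span) is True)
    return float(np.mean(hits)), float(np.mean(neutral))
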