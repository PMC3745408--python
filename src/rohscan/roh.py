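"""Run-of-homozygosity calling, consensus core regions and burden statistics.

An ROH is a maximal stretch of consecutive non-heterozygous genotype
calls.  A run is broken by a heterozygous call, by an inter-SNP gap
larger than ``max_gap_bp``, or by a chromosome boundary; missing calls
neither break a run nor count toward its SNP tally.  A run is emitted
when it spans at least ``min_length_bp`` OR contains at least
``min_snps`` homozygous calls (the rule is configurable to AND, the
convention some array pipelines use).  Defaults: 500 kb, 50 SNPs,
100 kb gap.

Core regions are maximal stretches of consecutive SNPs covered by the
ROHs of at least ``min_share`` (default 10) distinct individuals; an
individual *carries* a core region when one of its ROHs covers the
region entirely.  Common regions are additionally required to reach a
minimum carrier prevalence in controls (default 1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import (
    CarrierMatrix,
    CoreRegion,
    GenotypeMatrix,
    MISSING,
    ROHSegment,
    SampleTable,
    VariantTable,
)

log = logging.getLogger(__name__)

__all__ = [
    "RohParams", "hwe_filter", "hwe_exact_pvalue", "detect_roh",
    "core_regions", "carrier_matrix", "prevalence_filter", "froh",
    "inbreeding_f", "compare_roh_length", "LengthComparison",
]


@dataclass
class RohParams:
    """Calling thresholds; defaults follow the 500 kb / 50 SNP array rule."""

    min_length_bp: int = 500_000
    min_snps: int = 50
    combine_rule: str = "OR"      # "OR" (either criterion) or "AND" (both)
    max_gap_bp: int = 100_000
    max_het: int = 0              # reserved; > 0 not implemented
    max_missing: int | None = None

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0 or self.min_snps <= 0 or self.max_gap_bp <= 0:
            raise ValueError("thresholds must be positive")
        if self.combine_rule not in ("OR", "AND"):
            raise ValueError("combine_rule must be 'OR' or 'AND'")
        if self.max_het != 0:
            raise NotImplementedError("only zero-het runs are supported")


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value for one SNP's genotype counts.

    Full enumeration of heterozygote counts conditional on the observed
    allele counts; p is the total probability of configurations no more
    likely than the observed one.  Monomorphic SNPs return 1.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    if n == 0 or n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # Unnormalised log-probabilities of each possible het count under HWE
    # conditional on allele counts (Levene's exact distribution).
    from scipy.special import gammaln

    def lgfac(x):
        return gammaln(np.asarray(x, dtype=float) + 1.0)

    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (hets * np.log(2) - lgfac(hets) - lgfac(rare_hom) - lgfac(common_hom))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = min(n_het, int(n_rare))
    p_obs = p[hets == n_het][0] if n_het in hets else 0.0
    if p_obs == 0.0:
        return 0.0
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter(genotypes: GenotypeMatrix, variants: VariantTable,
               alpha: float = 5e-5, sample: SampleTable = None,
               controls_only: bool = True):
    """Drop SNPs out of Hardy-Weinberg equilibrium (exact test p < alpha).

    Genotype counts are taken from controls only when a sample table is
    supplied (case ascertainment can distort HWE); otherwise from all
    individuals.  Returns the filtered ``(variants, genotypes)``.
    """
    codes = genotypes.codes
    if sample is not None and controls_only:
        status = sample.aligned_to(genotypes.sample_ids).status_array()
        codes = codes[status == 0]
        if codes.shape[0] == 0:
            raise ValueError("no controls available for the HWE filter")
    keep = np.ones(variants.n_snps, dtype=bool)
    for j in range(variants.n_snps):
        col = codes[:, j]
        p = hwe_exact_pvalue(int((col == 0).sum()), int((col == 1).sum()),
                             int((col == 2).sum()))
        if p < alpha:
            keep[j] = False
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("HWE filter removed %d SNP(s) at alpha=%g", n_removed, alpha)
    return variants.take(keep), genotypes.take_snps(keep)


def detect_roh(genotypes: GenotypeMatrix, variants: VariantTable,
               params: RohParams = None) -> list:
    """Call maximal homozygous runs per individual and chromosome.

    Segment bounds are the first and last SNP positions of the run
    (1-based inclusive); ``n_snps`` counts homozygous calls only.
    """
    params = params or RohParams()
    segments: list[ROHSegment] = []
    for chrom in variants.chromosomes():
        sl = variants.chrom_slice(chrom)
        pos = variants.pos[sl]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"unsorted positions on chromosome {chrom}")
        codes = genotypes.codes[:, sl]
        # gap_break[k] is True when the step pos[k] -> pos[k+1] breaks a run
        gap_break = np.diff(pos) > params.max_gap_bp
        for i, iid in enumerate(genotypes.sample_ids):
            row = codes[i]
            het = row == 1
            # run boundaries: indices right after a breaker
            breaks = np.zeros(len(pos) + 1, dtype=bool)
            breaks[0] = breaks[-1] = True
            breaks[1:-1] = het[:-1] | het[1:] | gap_break
            # a het SNP is its own (excluded) unit: mark it so runs skip it
            bounds = np.nonzero(breaks)[0]
            for a, b in zip(bounds[:-1], bounds[1:]):
                # candidate run covers SNP indices [a, b)
                if b - a == 1 and het[a]:
                    continue
                seg = _emit_run(row, pos, a, b - 1, params, iid, chrom)
                if seg is not None:
                    segments.append(seg)
    return segments


def _emit_run(row, pos, i0, i1, params, iid, chrom):
    n_hom = int(np.count_nonzero((row[i0:i1 + 1] == 0) | (row[i0:i1 + 1] == 2)))
    if n_hom == 0:
        return None  # run of only missing calls
    n_miss = int(np.count_nonzero(row[i0:i1 + 1] == MISSING))
    if params.max_missing is not None and n_miss > params.max_missing:
        return None
    length = int(pos[i1] - pos[i0] + 1)
    long_enough = length >= params.min_length_bp
    many_enough = n_hom >= params.min_snps
    ok = (long_enough or many_enough) if params.combine_rule == "OR" \
        else (long_enough and many_enough)
    if not ok:
        return None
    return ROHSegment(iid, str(chrom), int(pos[i0]), int(pos[i1]), n_hom)


def core_regions(segments, variants: VariantTable, min_share: int = 10,
                 mode: str = "span") -> list:
    """Consensus intervals where >= min_share individuals' ROHs overlap.

    Per-SNP coverage counts distinct individuals whose segment covers the
    SNP.  With ``mode="span"`` each maximal run of consecutive SNPs with
    coverage >= min_share becomes one core region bounded by its
    first/last SNP positions.  Because segment edges are ragged, a span
    can extend past the interval any single individual covers; for
    association, ``mode="plateau"`` instead refines each run to its
    maximal-coverage plateau(s) — the interval genuinely shared by the
    covering individuals, so every one of them carries the region under
    the full-coverage rule.
    """
    if mode not in ("span", "plateau"):
        raise ValueError("mode must be 'span' or 'plateau'")
    out = []
    for chrom in variants.chromosomes():
        sl = variants.chrom_slice(chrom)
        pos = variants.pos[sl]
        cover = np.zeros(len(pos) + 1, dtype=np.int64)
        for s in segments:
            if s.chrom != str(chrom):
                continue
            i0 = int(np.searchsorted(pos, s.start, side="left"))
            i1 = int(np.searchsorted(pos, s.end, side="right"))
            cover[i0] += 1
            cover[i1] -= 1
        cov = np.cumsum(cover[:-1])
        ok = cov >= min_share
        if not ok.any():
            continue
        edges = np.diff(np.concatenate([[0], ok.view(np.int8), [0]]))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0] - 1
        for a, b in zip(starts, ends):
            if mode == "span":
                out.append(CoreRegion(str(chrom), int(pos[a]), int(pos[b])))
                continue
            local = cov[a:b + 1]
            top = local.max()
            hit = local == top
            e2 = np.diff(np.concatenate([[0], hit.view(np.int8), [0]]))
            for pa, pb in zip(np.nonzero(e2 == 1)[0], np.nonzero(e2 == -1)[0] - 1):
                out.append(CoreRegion(str(chrom), int(pos[a + pa]),
                                      int(pos[a + pb])))
    return out


def carrier_matrix(segments, regions, sample_ids) -> CarrierMatrix:
    """Binary incidence: individual i carries region r iff one of i's
    segments covers r entirely (full-coverage rule)."""
    index = {iid: i for i, iid in enumerate(sample_ids)}
    inc = np.zeros((len(sample_ids), len(regions)), dtype=np.int8)
    by_chrom: dict = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for r_idx, r in enumerate(regions):
        for s in by_chrom.get(r.chrom, ()):
            if s.start <= r.start and s.end >= r.end and s.individual_id in index:
                inc[index[s.individual_id], r_idx] = 1
        r.carrier_ids = [iid for iid in sample_ids if inc[index[iid], r_idx]]
    return CarrierMatrix(inc, list(sample_ids), list(regions))


def prevalence_filter(matrix: CarrierMatrix, sample: SampleTable,
                      min_control_prev: float = 0.01):
    """Drop core regions whose control carrier rate is below the minimum."""
    status = sample.aligned_to(matrix.sample_ids).status_array()
    n_ctrl = int((status == 0).sum())
    n_case = int((status == 1).sum())
    if n_ctrl == 0:
        raise ValueError("no controls in the sample table")
    keep = []
    for r_idx, region in enumerate(matrix.regions):
        col = matrix.incidence[:, r_idx]
        rate_ctrl = float(col[status == 0].sum()) / n_ctrl
        rate_case = float(col[status == 1].sum()) / n_case if n_case else float("nan")
        region.rate_ctrl = rate_ctrl
        region.rate_case = rate_case
        if rate_ctrl >= min_control_prev:
            keep.append(r_idx)
    new = CarrierMatrix(matrix.incidence[:, keep], matrix.sample_ids,
                        [matrix.regions[k] for k in keep])
    return new, new.regions


def froh(segments, mappable_length_bp: int, sample_ids=None) -> dict:
    """Per-individual fraction of the mappable genome inside ROHs.

    Froh_i = sum of segment lengths / mappable length, in [0, 1].
    Overlapping segments for one individual violate the segment
    invariant and raise.
    """
    if mappable_length_bp <= 0:
        raise ValueError("mappable length must be positive")
    per: dict = {iid: 0 for iid in (sample_ids or ())}
    by_ind: dict = {}
    for s in segments:
        by_ind.setdefault((s.individual_id, s.chrom), []).append(s)
    for (iid, _), segs in by_ind.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping segments for individual {iid}")
        per[iid] = per.get(iid, 0) + sum(s.length for s in segs)
    return {iid: total / mappable_length_bp for iid, total in per.items()}


def mappable_length(variants: VariantTable) -> int:
    """Default SNP-mappable span: last - first SNP + 1, summed over chromosomes."""
    total = 0
    for chrom in variants.chromosomes():
        p = variants.pos[variants.chrom_slice(chrom)]
        total += int(p[-1] - p[0] + 1)
    return total


def inbreeding_f(genotypes: GenotypeMatrix, variants: VariantTable = None):
    """Method-of-moments inbreeding coefficient per individual.

    F_i = (O_i - E_i) / (L_i - E_i) where O_i is the observed homozygous
    count over the L_i non-missing SNPs and E_i the HWE expectation
    sum(1 - 2 p q) using sample allele frequencies.
    """
    codes = genotypes.codes
    if codes.shape[0] < 2:
        raise ValueError("need at least 2 individuals to estimate frequencies")
    valid = codes != MISSING
    with np.errstate(invalid="ignore"):
        p_alt = np.where(valid, codes, 0).sum(axis=0) / (2.0 * valid.sum(axis=0))
    poly = (p_alt > 0) & (p_alt < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; F undefined")
    exp_hom = 1.0 - 2.0 * p_alt * (1.0 - p_alt)
    use = valid & poly
    obs = (((codes == 0) | (codes == 2)) & use).sum(axis=1).astype(float)
    exp = (exp_hom * use).sum(axis=1)
    n_used = use.sum(axis=1).astype(float)
    denom = n_used - exp
    f = np.where(denom > 0, (obs - exp) / denom, np.nan)
    return dict(zip(genotypes.sample_ids, f))


@dataclass
class LengthComparison:
    mean_case: float
    mean_ctrl: float
    z: float
    p_one_sided: float
    p_two_sided: float
    t: float
    p_t_two_sided: float
    n_case: int
    n_ctrl: int


def compare_roh_length(segments, sample: SampleTable,
                       per_individual: bool = False) -> LengthComparison:
    """Two-sample z (and Welch t) comparison of ROH lengths by status.

    By default the unit of analysis is the segment; with
    ``per_individual`` it is each individual's mean segment length.
    One-sided p tests case lengths > control lengths.
    """
    status = dict(zip(sample.ids, sample.status_array()))
    case_l, ctrl_l = [], []
    if per_individual:
        by_ind: dict = {}
        for s in segments:
            by_ind.setdefault(s.individual_id, []).append(s.length)
        for iid, ls in by_ind.items():
            (case_l if status.get(iid) == 1 else ctrl_l).append(float(np.mean(ls)))
    else:
        for s in segments:
            (case_l if status.get(s.individual_id) == 1 else ctrl_l).append(
                float(s.length))
    if len(case_l) < 2 or len(ctrl_l) < 2:
        raise ValueError("need at least 2 lengths in each group")
    a, b = np.asarray(case_l), np.asarray(ctrl_l)
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    z = (a.mean() - b.mean()) / se
    t_stat, p_t = stats.ttest_ind(a, b, equal_var=False)
    return LengthComparison(
        mean_case=float(a.mean()), mean_ctrl=float(b.mean()), z=float(z),
        p_one_sided=float(stats.norm.sf(z)),
        p_two_sided=float(2 * stats.norm.sf(abs(z))),
        t=float(t_stat), p_t_two_sided=float(p_t),
        n_case=len(a), n_ctrl=len(b),
    )
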