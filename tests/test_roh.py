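"""ROH calling, core regions, carriers, burden and QC-filter tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rohscan.roh import (
    RohParams,
    carrier_matrix,
    compare_roh_length,
    core_regions,
    detect_roh,
    froh,
    hwe_exact_pvalue,
    hwe_filter,
    inbreeding_f,
    mappable_length,
)
from rohscan.types import (
    MISSING,
    CoreRegion,
    GenotypeMatrix,
    ROHSegment,
    SampleTable,
    VariantTable,
)

from conftest import random_genotype_matrix
from oracles import (
    coverage_core_regions_oracle,
    hwe_exact_enumeration,
    roh_oracle,
)
import pandas as pd


def make_variants(pos, chrom="1"):
    pos = np.asarray(pos)
    if np.ndim(chrom) == 0:
        chroms = [chrom] * len(pos)
    else:
        chroms = list(chrom)
    return VariantTable(chroms, pos, [f"rs{c}_{p}" for c, p in zip(chroms, pos)],
                        ["A"] * len(pos), ["G"] * len(pos))


def segs_as_tuples(segments):
    return sorted((s.individual_id, s.chrom, s.start, s.end, s.n_snps)
                  for s in segments)


class TestDetectRoh:
    def test_all_het_individual_yields_nothing(self):
        v = make_variants(np.arange(1, 61) * 10_000)
        g = GenotypeMatrix(np.ones((1, 60), dtype=np.int8), ["i1"])
        assert detect_roh(g, v) == []

    def test_snp_criterion_or_vs_and(self):
        """60 hom SNPs over 300 kb pass under OR, are suppressed under AND."""
        pos = np.arange(60) * 5000 + 1   # span 295,001 bp < 500 kb
        v = make_variants(pos)
        g = GenotypeMatrix(np.zeros((1, 60), dtype=np.int8), ["i1"])
        assert len(detect_roh(g, v, RohParams(combine_rule="OR"))) == 1
        assert detect_roh(g, v, RohParams(combine_rule="AND")) == []

    def test_gap_breaks_run(self):
        pos = np.concatenate([np.arange(30) * 4000 + 1,
                              np.arange(30) * 4000 + 300_000])
        v = make_variants(pos)
        g = GenotypeMatrix(np.zeros((1, 60), dtype=np.int8), ["i1"])
        out = detect_roh(g, v, RohParams(min_snps=25, min_length_bp=10**9))
        assert len(out) == 2    # 183-kb hop between blocks exceeds 100 kb

    def test_missing_does_not_break_or_count(self):
        pos = np.arange(60) * 4000 + 1
        v = make_variants(pos)
        row = np.zeros(60, dtype=np.int8)
        row[20:30] = MISSING
        g = GenotypeMatrix(row[None, :], ["i1"])
        out = detect_roh(g, v, RohParams(min_snps=50, min_length_bp=10**9))
        assert segs_as_tuples(out) == [("i1", "1", 1, int(pos[-1]), 50)]
        # a max_missing cap suppresses the run
        out2 = detect_roh(g, v, RohParams(min_snps=50, min_length_bp=10**9,
                                          max_missing=5))
        assert out2 == []

    def test_matches_streaming_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_chrom = int(rng.integers(1, 3))
            codes, pos, chroms = random_genotype_matrix(
                rng, n_ind=12, n_snps=200, chrom_length=2_000_000,
                p_het=float(rng.uniform(0.05, 0.4)),
                p_missing=float(rng.uniform(0, 0.15)), n_chrom=n_chrom)
            params = RohParams(
                min_length_bp=int(rng.integers(50_000, 400_000)),
                min_snps=int(rng.integers(5, 40)),
                combine_rule=str(rng.choice(["OR", "AND"])),
                max_gap_bp=int(rng.integers(20_000, 150_000)))
            ids = [f"i{k}" for k in range(12)]
            v = make_variants(pos, chroms)
            got = segs_as_tuples(detect_roh(GenotypeMatrix(codes, ids), v,
                                            params))
            want = roh_oracle(codes, pos, chroms, ids,
                              params.min_length_bp, params.min_snps,
                              params.combine_rule, params.max_gap_bp)
            assert got == want

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        codes, pos, chroms = random_genotype_matrix(rng, 20, 300, 3_000_000)
        v = make_variants(pos, chroms)
        g = GenotypeMatrix(codes, [f"i{k}" for k in range(20)])
        base = len(detect_roh(g, v, RohParams(min_length_bp=100_000,
                                              min_snps=10)))
        stricter_len = len(detect_roh(g, v, RohParams(min_length_bp=200_000,
                                                      min_snps=10)))
        stricter_snp = len(detect_roh(g, v, RohParams(min_length_bp=100_000,
                                                      min_snps=20)))
        assert stricter_len <= base
        assert stricter_snp <= base

    def test_planted_segments_recovered_with_exact_bounds(self, small_cohort):
        """Every planted synthetic segment is returned with exact bp bounds."""
        segs = detect_roh(small_cohort["genotypes"], small_cohort["variants"])
        by_ind = {}
        for s in segs:
            by_ind.setdefault(s.individual_id, []).append((s.start, s.end))
        n_checked = 0
        for iid, planted in small_cohort["truth"].segments.items():
            for start, end in planted:
                assert any(s <= start and e >= end
                           for s, e in by_ind.get(iid, [])), (iid, start, end)
                n_checked += 1
        assert n_checked > 20


class TestHwe:
    def test_perfect_hwe_retained(self):
        assert hwe_exact_pvalue(25, 50, 25) > 0.5

    def test_total_het_deficit_excluded(self):
        assert hwe_exact_pvalue(50, 0, 50) < 5e-5

    def test_monomorphic_retained(self):
        assert hwe_exact_pvalue(80, 0, 0) == 1.0

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=60, deadline=None)
    def test_matches_rational_enumeration(self, a, b, c):
        assert hwe_exact_pvalue(a, b, c) == pytest.approx(
            hwe_exact_enumeration(a, b, c), abs=1e-10)

    def test_filter_removes_only_violations(self):
        rng = np.random.default_rng(8)
        good = rng.choice([0, 1, 2], size=(200, 5), p=[0.25, 0.5, 0.25])
        bad = np.where(rng.random((200, 1)) < 0.5, 0, 2)  # zero hets
        codes = np.hstack([good, bad]).astype(np.int8)
        v = make_variants(np.arange(6) * 1000 + 1)
        g = GenotypeMatrix(codes, [f"i{k}" for k in range(200)])
        v2, g2 = hwe_filter(g, v, alpha=5e-5)
        assert v2.n_snps == 5
        v3, _ = hwe_filter(g, v, alpha=0.0)
        assert v3.n_snps == 6     # alpha 0 excludes nothing


class TestCoreRegions:
    def _segments(self, n, start, end):
        return [ROHSegment(f"i{k}", "1", start, end, 10) for k in range(n)]

    def test_min_share_boundary(self):
        v = make_variants(np.arange(10) * 100_000 + 1_000_000)
        segs = self._segments(9, 1_200_000, 1_800_000)
        assert core_regions(segs, v, min_share=10) == []
        regs = core_regions(self._segments(12, 1_200_000, 1_800_000), v, 10)
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (1_200_000, 1_800_000)

    def test_matches_per_snp_coverage_oracle(self):
        rng = np.random.default_rng(17)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 150, replace=False))
        v = make_variants(pos)
        for trial in range(10):
            segs = []
            for k in range(40):
                a = int(rng.integers(1, 1_900_000))
                b = a + int(rng.integers(10_000, 400_000))
                segs.append(ROHSegment(f"i{k}", "1", a, b, 5))
            share = int(rng.integers(2, 8))
            got = [(r.start, r.end) for r in core_regions(segs, v, share)]
            assert got == coverage_core_regions_oracle(segs, pos, "1", share)

    def test_plateau_mode_regions_are_fully_shared(self):
        """Plateau refinement guarantees >= min_share full coverers even when
        ragged segment edges widen the raw coverage span."""
        rng = np.random.default_rng(41)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 300, replace=False))
        v = make_variants(pos)
        segs = []
        for k in range(60):
            centre = int(rng.choice([1_000_000, 2_000_000]))
            a = centre - int(rng.integers(100_000, 400_000))
            b = centre + int(rng.integers(100_000, 400_000))
            segs.append(ROHSegment(f"i{k}", "1", a, b, 5))
        for share in (5, 10, 20):
            for r in core_regions(segs, v, share, mode="plateau"):
                full = sum(1 for s in segs
                           if s.start <= r.start and s.end >= r.end)
                assert full >= share

    def test_min_share_monotonicity(self):
        rng = np.random.default_rng(23)
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), 100, replace=False))
        v = make_variants(pos)
        segs = [ROHSegment(f"i{k}", "1", int(rng.integers(1, 500_000)),
                           int(rng.integers(500_001, 999_999)), 3)
                for k in range(30)]
        counts = [len(core_regions(segs, v, m)) for m in (2, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)


class TestCarriersAndPrevalence:
    def test_full_coverage_rule(self):
        region = CoreRegion("1", 1000, 2000)
        exact = ROHSegment("i1", "1", 1000, 2000, 5)
        partial = ROHSegment("i2", "1", 1500, 3000, 5)
        m = carrier_matrix([exact, partial], [region], ["i1", "i2"])
        assert m.incidence[:, 0].tolist() == [1, 0]

    def test_column_sums_match_recount(self):
        rng = np.random.default_rng(31)
        ids = [f"i{k}" for k in range(25)]
        segs, regions = [], []
        for k, iid in enumerate(ids):
            a = int(rng.integers(1, 100_000))
            segs.append(ROHSegment(iid, "1", a, a + 50_000, 4))
        for _ in range(5):
            a = int(rng.integers(1, 120_000))
            regions.append(CoreRegion("1", a, a + int(rng.integers(1, 40_000))))
        m = carrier_matrix(segs, regions, ids)
        for r_idx, region in enumerate(regions):
            expected = sum(1 for s in segs if s.start <= region.start
                           and s.end >= region.end)
            assert m.incidence[:, r_idx].sum() == expected
            assert region.n_carriers == expected

    def test_prevalence_filter_boundary(self):
        from rohscan.roh import prevalence_filter
        ids = [f"c{k}" for k in range(315)] + [f"u{k}" for k in range(1115)]
        status = [1] * 315 + [0] * 1115
        sample = SampleTable(pd.DataFrame({"individual_id": ids,
                                           "status": status}))
        inc = np.zeros((1430, 2), dtype=np.int8)
        inc[315:326, 0] = 1     # 11 control carriers: rate 0.00987 < 1%
        inc[315:327, 1] = 1     # 12 control carriers: rate 0.01076 >= 1%
        from rohscan.types import CarrierMatrix
        m = CarrierMatrix(inc, ids, [CoreRegion("1", 1, 10),
                                     CoreRegion("1", 20, 30)])
        m2, regions = prevalence_filter(m, sample, 0.01)
        assert m2.n_regions == 1 and regions[0].start == 20
        m3, _ = prevalence_filter(m, sample, 0.0)
        assert m3.n_regions == 2


class TestBurden:
    def test_froh_hand_arithmetic(self):
        segs = [ROHSegment("i1", "1", 1, 500_000, 10),
                ROHSegment("i1", "2", 1, 700_000, 10)]
        out = froh(segs, 30_000_000)
        assert out["i1"] == pytest.approx(0.04, rel=1e-6)
        assert froh([], 1000) == {}

    def test_froh_rejects_overlap(self):
        segs = [ROHSegment("i1", "1", 1, 1000, 5),
                ROHSegment("i1", "1", 500, 2000, 5)]
        with pytest.raises(ValueError, match="overlap"):
            froh(segs, 10_000)

    def test_froh_invariant_to_chromosome_partition(self):
        segs_one = [ROHSegment("i1", "1", 1, 1000, 5),
                    ROHSegment("i1", "1", 5000, 6000, 5)]
        segs_two = [ROHSegment("i1", "2", 5000, 6000, 5),
                    ROHSegment("i1", "1", 1, 1000, 5)]
        assert froh(segs_one, 10_000) == froh(segs_two, 10_000)

    def test_inbreeding_f_extremes(self):
        rng = np.random.default_rng(5)
        codes = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25],
                           size=(100, 400)).astype(np.int8)
        codes[0] = np.where(codes[0] == 1, 0, codes[0])  # fully homozygous
        g = GenotypeMatrix(codes, [f"i{k}" for k in range(100)])
        f = inbreeding_f(g)
        assert f["i0"] == pytest.approx(1.0)
        others = [v for k, v in f.items() if k != "i0"]
        assert abs(np.mean(others)) < 0.05

    def test_inbreeding_f_three_snp_hand_example(self):
        # two individuals, 3 SNPs; allele freqs p_alt = (0.25, 0.5, 0.75)
        codes = np.array([[0, 1, 2], [1, 1, 1]], dtype=np.int8)
        g = GenotypeMatrix(codes, ["a", "b"])
        f = inbreeding_f(g)
        # E = (1-2*.25*.75) + (1-2*.5*.5) + (1-2*.75*.25) = 1.75; L = 3
        assert f["a"] == pytest.approx((2 - 1.75) / (3 - 1.75))
        assert f["b"] == pytest.approx((0 - 1.75) / (3 - 1.75))

    def test_mappable_length_sums_chromosomes(self):
        v = make_variants([10, 1000, 2000, 50, 500],
                          ["1", "1", "1", "2", "2"])
        assert mappable_length(v) == (2000 - 10 + 1) + (500 - 50 + 1)


class TestLengthComparison:
    @staticmethod
    def _sample(n_case, n_ctrl):
        ids = ([f"c{k}" for k in range(n_case)]
               + [f"u{k}" for k in range(n_ctrl)])
        return SampleTable(pd.DataFrame({
            "individual_id": ids, "status": [1] * n_case + [0] * n_ctrl}))

    def test_identical_distributions_give_null_z(self):
        rng = np.random.default_rng(1)
        lengths = rng.integers(500_000, 1_500_000, size=400)
        segs = [ROHSegment(f"c{k % 40}" if k % 2 else f"u{k % 40}", "1",
                           1, int(lengths[k]), 5) for k in range(400)]
        res = compare_roh_length(segs, self._sample(40, 40))
        assert abs(res.z) < 3
        assert 0.001 < res.p_one_sided < 0.999

    def test_planted_shift_detected_and_z_sign(self):
        rng = np.random.default_rng(2)
        segs = []
        for k in range(300):
            base = int(rng.normal(650_000, 100_000))
            segs.append(ROHSegment(f"c{k}", "1", 1, base + 200_000, 5))
            segs.append(ROHSegment(f"u{k}", "1", 1, base, 5))
        res = compare_roh_length(segs, self._sample(300, 300))
        assert res.z > 3
        assert res.p_one_sided < 0.01
        assert res.mean_case > res.mean_ctrl

    def test_permuted_labels_give_null_mean_z(self):
        rng = np.random.default_rng(4)
        lengths = rng.integers(500_000, 2_000_000, size=200)
        zs = []
        for rep in range(60):
            perm = rng.permutation(200)
            segs = [ROHSegment(f"c{k}" if perm[k] < 100 else f"u{k}", "1", 1,
                               int(lengths[k]), 5) for k in range(200)]
            ids = [f"c{k}" for k in range(200)] + [f"u{k}" for k in range(200)]
            sample = SampleTable(pd.DataFrame({
                "individual_id": ids,
                "status": [1] * 200 + [0] * 200}))
            zs.append(compare_roh_length(segs, sample).z)
        assert abs(np.mean(zs)) < 3 / np.sqrt(60)

    def test_small_group_rejected(self):
        segs = [ROHSegment("c0", "1", 1, 1000, 5),
                ROHSegment("u0", "1", 1, 1000, 5),
                ROHSegment("u1", "1", 1, 2000, 5)]
        with pytest.raises(ValueError):
            compare_roh_length(segs, self._sample(1, 2))
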