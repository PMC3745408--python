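"""Independent brute-force oracles used to check the fast implementations.

Everything here favours obviousness over speed: plain Python loops,
exact rational arithmetic where p-values are compared to 12 digits, and
no code shared with the package under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

MISSING = -1


def roh_oracle(codes, pos, chroms, sample_ids, min_length_bp=500_000,
               min_snps=50, combine_rule="OR", max_gap_bp=100_000,
               max_missing=None):
    """Streaming re-derivation of maximal homozygous runs.

    Walks each individual's genotypes SNP by SNP, closing the open run
    at a het call, an oversized gap or a chromosome change, and emits
    (individual, chrom, start, end, n_hom) for runs passing the length /
    SNP-count rule.
    """
    out = []
    n_ind, n_snps = codes.shape
    for i in range(n_ind):
        run = []          # list of (snp_index) in the open run
        prev_chrom = None
        prev_pos = None

        def close(run):
            if not run:
                return
            hom = [j for j in run if codes[i, j] in (0, 2)]
            if not hom:
                return
            n_miss = sum(1 for j in run if codes[i, j] == MISSING)
            if max_missing is not None and n_miss > max_missing:
                return
            start, end = pos[run[0]], pos[run[-1]]
            length = end - start + 1
            ok_len = length >= min_length_bp
            ok_n = len(hom) >= min_snps
            ok = (ok_len or ok_n) if combine_rule == "OR" else (ok_len and ok_n)
            if ok:
                out.append((sample_ids[i], str(chroms[run[0]]), int(start),
                            int(end), len(hom)))

        for j in range(n_snps):
            g = codes[i, j]
            new_chrom = chroms[j] != prev_chrom
            big_gap = (prev_pos is not None and not new_chrom
                       and pos[j] - prev_pos > max_gap_bp)
            if new_chrom or big_gap:
                close(run)
                run = []
            if g == 1:
                close(run)
                run = []
            else:
                run.append(j)
            prev_chrom = chroms[j]
            prev_pos = pos[j]
        close(run)
    return sorted(out)


def coverage_core_regions_oracle(segments, pos, chrom, min_share=10):
    """Core regions by testing every SNP's coverage directly."""
    cov = []
    for p in pos:
        carriers = {s.individual_id for s in segments
                    if s.chrom == chrom and s.start <= p <= s.end}
        cov.append(len(carriers))
    regions = []
    k = 0
    while k < len(pos):
        if cov[k] >= min_share:
            j = k
            while j + 1 < len(pos) and cov[j + 1] >= min_share:
                j += 1
            regions.append((int(pos[k]), int(pos[j])))
            k = j + 1
        else:
            k += 1
    return regions


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher p by full enumeration in rational arithmetic."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0

    def prob(k):
        return Fraction(comb(c1, k) * comb(n - c1, r1 - k), comb(n, r1))

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(min(total, Fraction(1)))


def hwe_exact_enumeration(n_hom_ref, n_het, n_hom_alt):
    """Exact HWE p by enumerating heterozygote counts in rationals."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    if n == 0 or n_rare == 0:
        return 1.0
    from math import factorial
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        weights[h] = Fraction(2 ** h,
                              factorial(h) * factorial(rare_hom)
                              * factorial(common_hom))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return float(min(sum(p for p in probs.values() if p <= p_obs), Fraction(1)))


def ehh_pairwise_oracle(hap_block):
    """EHH at each column by testing identity of every carrier pair.

    ``hap_block`` holds the carriers' alleles ordered outward from the
    core edge; returns EHH per column.  Each row is compared as a byte
    prefix so the all-pairs scan stays affordable at oracle scale.
    """
    hap_block = np.asarray(hap_block, dtype=np.int8)
    rows = [r.tobytes() for r in hap_block]
    n = len(rows)
    n_pairs = comb(n, 2)
    out = []
    for depth in range(hap_block.shape[1]):
        same = sum(1 for a, b in itertools.combinations(rows, 2)
                   if a[:depth + 1] == b[:depth + 1])
        out.append(same / n_pairs)
    return np.array(out)


def combined_others_ehh_oracle(blocks):
    """Combined-others EHH from per-core carrier blocks (pair counting)."""
    num, den = [], 0
    width = blocks[0].shape[1] if blocks else 0
    totals = np.zeros(width)
    for block in blocks:
        n = block.shape[0]
        den += comb(n, 2)
        for depth in range(width):
            same = 0
            for i, j in itertools.combinations(range(n), 2):
                if np.array_equal(block[i, :depth + 1], block[j, :depth + 1]):
                    same += 1
            totals[depth] += same
    return totals / den


def kmeans_split_oracle(values):
    """Best 2-cluster split by brute force over every sorted split point."""
    x = np.sort(np.asarray(values, dtype=float))
    best_wss, best_k = np.inf, None
    for k in range(1, len(x)):
        a, b = x[:k], x[k:]
        wss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if wss < best_wss - 1e-12:
            best_wss, best_k = wss, k
    return x[:best_k], x[best_k:]


def mannwhitney_exact_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = _rank(pooled)
    u_obs = _u_stat(ranks[:n_a], n_a, len(b))
    mu = n_a * len(b) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        u = _u_stat([ranks[i] for i in idx], n_a, len(b))
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def _rank(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _u_stat(group_ranks, n_a, n_b):
    return sum(group_ranks) - n_a * (n_a + 1) / 2.0


def d_prime_oracle(hap_a, hap_b):
    """D' from the four haplotype counts, written out longhand."""
    n = len(hap_a)
    p_ab = sum(1 for x, y in zip(hap_a, hap_b) if x == 1 and y == 1) / n
    p_a = sum(hap_a) / n
    p_b = sum(hap_b) / n
    d = p_ab - p_a * p_b
    if d > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return 0.0
    return d / dmax
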