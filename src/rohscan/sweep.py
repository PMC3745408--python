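"""Core-haplotype enumeration and EHH/REHH selection-sweep scanning.

EHH (extended haplotype homozygosity) at a flanking marker x is the
probability that two randomly chosen chromosomes carrying the focal
core haplotype are identical at every SNP from the core edge through x:

    EHH(x) = sum_g C(n_g, 2) / C(n_c, 2)

where the carriers split into groups g of identical extended
haplotypes.  REHH divides the focal core's EHH by the combined decay of
all other core haplotypes:

    EHH_others(x) = sum_s sum_g C(n_{s,g}, 2) / sum_s C(n_s, 2)

A region is flagged as a candidate selective sweep when REHH >= 2 at a
marker more than 200 kb from the core, the threshold used for
array-scale scans.  Distances are physical bp from the nearer core-edge
SNP; no genetic map is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .types import PhasedHaplotypes, VariantTable

__all__ = [
    "CoreHaplotype", "EHHProfile", "BifurcationNode", "enumerate_cores",
    "ehh", "rehh", "sweep_flag", "bifurcation", "d_prime",
]


@dataclass
class CoreHaplotype:
    """A distinct allele string over the core SNP span and its carriers."""

    core_span: tuple               # (first, last) SNP index, inclusive
    alleles: tuple                 # 0/1 per core SNP
    carrier_rows: np.ndarray       # haplotype row indices
    frequency: float
    ancestral_match: tuple | None = None   # per-allele flag when known

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_rows)

    @property
    def label(self) -> str:
        return "".join(str(int(a)) for a in self.alleles)


@dataclass
class EHHProfile:
    """Per-flanking-SNP EHH of the focal core, combined-others EHH and REHH."""

    core: CoreHaplotype
    side: str                      # "left" or "right"
    positions: np.ndarray          # bp of each flanking SNP
    distance_bp: np.ndarray        # from the nearer core-edge SNP
    ehh_focal: np.ndarray
    ehh_others: np.ndarray | None = None
    rehh: np.ndarray | None = None


def enumerate_cores(haps: PhasedHaplotypes, core_span,
                    variants: VariantTable = None) -> list:
    """Distinct allele strings over a contiguous core span, by frequency.

    Raises if the span is empty or outside the window.  When the variant
    table carries ancestral-allele flags the per-allele ancestral match
    is attached as metadata.
    """
    a, b = int(core_span[0]), int(core_span[1])
    if not (0 <= a <= b < haps.n_snps):
        raise ValueError("core span outside the SNP window")
    block = haps.alleles[:, a:b + 1]
    strings, inverse = np.unique(block, axis=0, return_inverse=True)
    n_hap = haps.n_haplotypes
    cores = []
    for s_idx in range(strings.shape[0]):
        rows = np.nonzero(inverse == s_idx)[0]
        alleles = tuple(int(x) for x in strings[s_idx])
        anc = None
        if variants is not None and variants.ancestral is not None:
            flags = variants.ancestral[a:b + 1]
            anc = tuple(
                (-1 if f == -1 else int(al == f))
                for al, f in zip(alleles, flags)
            )
        cores.append(CoreHaplotype((a, b), alleles, rows,
                                   len(rows) / n_hap, anc))
    cores.sort(key=lambda c: (-c.frequency, c.label))
    return cores


def _flank_indices(core_span, n_snps: int, direction: str) -> np.ndarray:
    a, b = core_span
    if direction == "left":
        return np.arange(a - 1, -1, -1)
    if direction == "right":
        return np.arange(b + 1, n_snps)
    raise ValueError("direction must be 'left' or 'right'")


def _group_pair_counts(block: np.ndarray) -> np.ndarray:
    """For rows of ``block``, cumulative group sizes walking column-by-column.

    Returns an array ``pairs[k]`` = number of row pairs identical over
    the first k+1 columns (columns are already ordered outward from the
    core edge).
    """
    n_rows, n_cols = block.shape
    labels = np.zeros(n_rows, dtype=np.int64)
    pairs = np.empty(n_cols, dtype=np.int64)
    for k in range(n_cols):
        key = labels * 2 + block[:, k]
        _, labels, counts = np.unique(key, return_inverse=True,
                                      return_counts=True)
        pairs[k] = int((counts * (counts - 1) // 2).sum())
    return pairs


def ehh(haps: PhasedHaplotypes, core: CoreHaplotype, direction: str,
        variants: VariantTable) -> EHHProfile:
    """One-sided EHH decay profile for a focal core haplotype."""
    if core.n_carriers < 2:
        raise ValueError("EHH undefined for a core with fewer than 2 carriers")
    idx = _flank_indices(core.core_span, haps.n_snps, direction)
    block = haps.alleles[np.ix_(core.carrier_rows, idx)]
    denom = comb(core.n_carriers, 2)
    pairs = _group_pair_counts(block) if len(idx) else np.empty(0, dtype=np.int64)
    edge = core.core_span[0] if direction == "left" else core.core_span[1]
    edge_pos = int(variants.pos[edge])
    positions = variants.pos[idx]
    return EHHProfile(
        core=core, side=direction, positions=positions,
        distance_bp=np.abs(positions - edge_pos),
        ehh_focal=pairs / denom,
    )


def rehh(haps: PhasedHaplotypes, focal: CoreHaplotype, others,
         direction: str, variants: VariantTable) -> EHHProfile:
    """REHH profile: focal EHH over the combined decay of all other cores.

    Cores with a single carrier contribute no pairs and are excluded.
    Where the combined-others EHH has decayed to zero the ratio
    diverges: REHH is +inf while the focal EHH is still positive and
    NaN (undefined) once both have decayed.
    """
    others = [c for c in others
              if c.n_carriers >= 2 and c.alleles != focal.alleles]
    if not others:
        raise ValueError("REHH needs at least one other core with >= 2 carriers")
    profile = ehh(haps, focal, direction, variants)
    idx = _flank_indices(focal.core_span, haps.n_snps, direction)
    num = np.zeros(len(idx), dtype=np.int64)
    denom = 0
    for c in others:
        block = haps.alleles[np.ix_(c.carrier_rows, idx)]
        if len(idx):
            num += _group_pair_counts(block)
        denom += comb(c.n_carriers, 2)
    ehh_others = num / denom if len(idx) else np.empty(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(ehh_others > 0, profile.ehh_focal / ehh_others,
                     np.where(profile.ehh_focal > 0, np.inf, np.nan))
    profile.ehh_others = ehh_others
    profile.rehh = r
    return profile


def sweep_flag(profiles, rehh_min: float = 2.0, dist_min_bp: int = 200_000,
               ehh_min: float = 0.05):
    """Candidate-sweep decision over one or more one-sided REHH profiles.

    True when any profile reaches REHH >= rehh_min at a marker more than
    dist_min_bp from the core while the focal EHH is still informative
    (>= ehh_min, the conventional decay cutoff below which the ratio is
    pure noise); ``None`` (inconclusive) when no profile extends past
    dist_min_bp.
    """
    if isinstance(profiles, EHHProfile):
        profiles = [profiles]
    reaches = False
    for p in profiles:
        if p.rehh is None:
            raise ValueError("profile lacks REHH values; run rehh() first")
        far = p.distance_bp > dist_min_bp
        if far.any():
            reaches = True
            use = far & (p.ehh_focal >= ehh_min) & ~np.isnan(p.rehh)
            if np.any(p.rehh[use] >= rehh_min):
                return True
    return False if reaches else None


@dataclass
class BifurcationNode:
    """One distinct extended haplotype at a given flank depth."""

    depth: int
    count: int
    allele: int | None = None      # allele taken at this step (None at root)
    children: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "depth": self.depth, "count": self.count, "allele": self.allele,
            "children": [c.to_dict() for c in self.children],
        }


def bifurcation(haps: PhasedHaplotypes, core: CoreHaplotype,
                direction: str) -> BifurcationNode:
    """Haplotype bifurcation tree rooted at the core haplotype.

    Each level splits the carriers by the allele at the next flanking
    SNP; node counts at any depth sum to the carrier count.
    """
    if core.n_carriers < 1:
        raise ValueError("core has no carriers")
    idx = _flank_indices(core.core_span, haps.n_snps, direction)
    block = haps.alleles[np.ix_(core.carrier_rows, idx)]
    root = BifurcationNode(depth=0, count=core.n_carriers)

    def grow(node: BifurcationNode, rows: np.ndarray, depth: int) -> None:
        if depth >= block.shape[1]:
            return
        col = block[rows, depth]
        for allele in (0, 1):
            sub = rows[col == allele]
            if len(sub):
                child = BifurcationNode(depth=depth + 1, count=len(sub),
                                        allele=allele)
                node.children.append(child)
                grow(child, sub, depth + 1)

    grow(root, np.arange(core.n_carriers), 0)
    return root


def d_prime(haps: PhasedHaplotypes, snp_i: int, snp_j: int):
    """Normalised LD coefficient D' and r^2 between two SNPs.

    D = p_AB - p_A p_B from phased haplotype counts; D' = D / D_max with
    D_max = min(p_A p_b, p_a p_B) for D > 0 and min(p_A p_B, p_a p_b)
    for D < 0.  Monomorphic SNPs are undefined and raise.
    """
    a = haps.alleles[:, snp_i].astype(float)
    b = haps.alleles[:, snp_j].astype(float)
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("D' undefined for a monomorphic SNP")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if d == 0 else d / d_max
    r2 = d ** 2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(dprime), float(r2)
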