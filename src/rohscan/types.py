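"""Core in-memory containers for the ROH / sweep pipeline.

Conventions
-----------
* Genotypes are coded ``0`` (hom-ref), ``1`` (het), ``2`` (hom-alt) and
  ``MISSING = -1`` in an ``int8`` matrix of shape (individuals, SNPs).
* Haplotype alleles are ``0`` (ref) / ``1`` (alt) in an ``int8`` matrix of
  shape (2 * individuals, SNPs); rows ``2i`` and ``2i + 1`` belong to
  individual ``i``.
* Physical coordinates are 1-based inclusive throughout (VCF convention);
  BED export converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "VariantTable",
    "GenotypeMatrix",
    "PhasedHaplotypes",
    "SampleTable",
    "ROHSegment",
    "CoreRegion",
    "CarrierMatrix",
]


@dataclass
class VariantTable:
    """Per-SNP metadata: chromosome, 1-based position, id and alleles.

    ``ancestral`` is an optional per-SNP flag (0 = ref allele ancestral,
    1 = alt allele ancestral, -1 = unknown) used only to annotate core
    haplotypes in the sweep module.
    """

    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ancestral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.ancestral is not None:
            self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        self.validate()

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        n = self.n_snps
        for name in ("chrom", "snp_id", "ref", "alt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"VariantTable field {name!r} has wrong length")
        if len(set(self.snp_id)) != n:
            raise ValueError("SNP ids are not unique")
        if np.any(self.ref == self.alt):
            raise ValueError("ref and alt alleles must differ at every SNP")
        for chrom in pd.unique(self.chrom):
            p = self.pos[self.chrom == chrom]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        return list(pd.unique(self.chrom))

    def chrom_slice(self, chrom) -> slice:
        """Contiguous column slice of one chromosome."""
        idx = np.nonzero(self.chrom == chrom)[0]
        if len(idx) == 0:
            raise KeyError(f"chromosome {chrom!r} not in table")
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError(f"chromosome {chrom!r} columns are not contiguous")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def take(self, indices) -> "VariantTable":
        anc = self.ancestral[indices] if self.ancestral is not None else None
        return VariantTable(
            self.chrom[indices], self.pos[indices], self.snp_id[indices],
            self.ref[indices], self.alt[indices], anc,
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "chrom": self.chrom, "pos": self.pos, "snp_id": self.snp_id,
            "ref": self.ref, "alt": self.alt,
        }
        if self.ancestral is not None:
            d["ancestral"] = self.ancestral
        return pd.DataFrame(d)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype codes with row ids."""

    codes: np.ndarray
    sample_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        if self.codes.ndim != 2:
            raise ValueError("genotype codes must be 2-D")
        if self.codes.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix rows")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0, 1, 2, MISSING}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.codes == MISSING).mean(axis=0)

    def take_snps(self, indices) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes[:, indices], self.sample_ids)


@dataclass
class PhasedHaplotypes:
    """2N x SNPs binary allele matrix; rows 2i, 2i+1 belong to individual i."""

    alleles: np.ndarray
    sample_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("need exactly two haplotype rows per individual")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def individual_of(self, hap_row: int) -> str:
        return self.sample_ids[hap_row // 2]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse haplotype pairs into unphased genotype codes."""
        g = self.alleles[0::2] + self.alleles[1::2]
        return GenotypeMatrix(g.astype(np.int8), self.sample_ids)


#: Phenotype-table columns and dtypes expected by the association module.
SAMPLE_COLUMNS = (
    "individual_id", "status", "afp_months", "sex",
    "maternal_edu", "paternal_edu", "viq", "piq", "scq",
)


@dataclass
class SampleTable:
    """Per-individual phenotypes.

    ``status`` is 1 = case, 0 = control.  ``afp_months`` is the age of
    first phrase in months (NaN when unknown).  Parental-education
    columns are ordinal 1-5.  Cognitive scores may be missing.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        for c in missing_cols:
            df[c] = np.nan
        if df["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids")
        afp = pd.to_numeric(df["afp_months"], errors="coerce")
        if (afp <= 0).any():
            raise ValueError("AFP must be positive (months)")
        for c in ("maternal_edu", "paternal_edu"):
            edu = pd.to_numeric(df[c], errors="coerce").dropna()
            if ((edu < 1) | (edu > 5)).any():
                raise ValueError(f"{c} outside ordinal range 1-5")
        df["afp_months"] = afp
        self.table = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list:
        return list(self.table["individual_id"])

    def status_array(self) -> np.ndarray:
        return self.table["status"].to_numpy(dtype=float)

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleTable":
        """Reorder rows to match a genotype matrix's sample order."""
        df = self.table.set_index("individual_id").loc[list(sample_ids)]
        return SampleTable(df.reset_index())


@dataclass(frozen=True)
class ROHSegment:
    """One maximal homozygous run of one individual (1-based inclusive bp)."""

    individual_id: str
    chrom: str
    start: int
    end: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end before start")
        if self.n_snps < 1:
            raise ValueError("segment must contain at least one SNP")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CoreRegion:
    """Consensus interval where >= min_share individuals' ROHs overlap."""

    chrom: str
    start: int
    end: int
    carrier_ids: list = field(default_factory=list)
    rate_case: float = float("nan")
    rate_ctrl: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_ids)


@dataclass
class CarrierMatrix:
    """Binary individuals x core-regions incidence."""

    incidence: np.ndarray
    sample_ids: Sequence[str]
    regions: list

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        if self.incidence.shape != (len(self.sample_ids), len(self.regions)):
            raise ValueError("incidence shape does not match ids x regions")

    @property
    def n_regions(self) -> int:
        return self.incidence.shape[1]

    def column(self, r: int) -> np.ndarray:
        return self.incidence[:, r].astype(float)
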