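"""Readers and writers for the formats the pipeline touches.

VCF reading goes through :mod:`cyvcf2`; VCF writing emits plain VCF 4.2
text (biallelic SNP records only).  PLINK text PED/MAP and the phenotype
TSV are line-oriented whitespace formats read and written directly.  ROH
segments are exported as BED (0-based half-open) with the individual id
in the name column; internal coordinates are 1-based inclusive, so the
conversion is ``start - 1`` / ``end``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    GenotypeMatrix,
    PhasedHaplotypes,
    ROHSegment,
    SampleTable,
    VariantTable,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_vcf", "write_vcf", "read_plink_text", "write_plink_text",
    "read_phenotypes", "write_phenotypes", "write_roh_bed", "read_roh_bed",
    "write_regions_bed",
]


class VcfPhaseError(ValueError):
    """Raised when phased haplotypes are required but GT fields are unphased."""


def read_vcf(path, require_phased: bool = False):
    """Read a biallelic-SNP VCF.

    Non-SNP and multi-allelic records are skipped with a logged count.
    Returns ``(variants, genotypes, haplotypes)``; ``haplotypes`` is
    ``None`` unless ``require_phased`` is set and every GT is phased.

    Raises
    ------
    VcfPhaseError
        if ``require_phased`` is set and any genotype is unphased or
        missing.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ids, refs, alts = [], [], [], [], []
    geno_rows, hap_rows = [], []
    n_skipped = 0
    phased_ok = True
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gts = rec.genotypes  # [allele1, allele2, phased] per sample
        col_g = np.empty(len(samples), dtype=np.int8)
        col_h = np.empty(2 * len(samples), dtype=np.int8)
        for i, (a1, a2, *rest) in enumerate(gts):
            if a1 < 0 or a2 < 0:
                col_g[i] = MISSING
                col_h[2 * i] = col_h[2 * i + 1] = 0
                phased_ok = False
            else:
                col_g[i] = a1 + a2
                col_h[2 * i] = a1
                col_h[2 * i + 1] = a2
                if not (rest and rest[0]):
                    phased_ok = False
        geno_rows.append(col_g)
        hap_rows.append(col_h)
    if n_skipped:
        msg = f"skipped {n_skipped} non-biallelic/non-SNP record(s)"
        log.info(msg)
        warnings.warn(msg, stacklevel=2)
    variants = VariantTable(chroms, poss, ids, refs, alts)
    genotypes = GenotypeMatrix(np.array(geno_rows, dtype=np.int8).T, samples)
    haplotypes = None
    if require_phased:
        if not phased_ok:
            raise VcfPhaseError(
                "require_phased set but VCF contains unphased or missing GT"
            )
        haplotypes = PhasedHaplotypes(np.array(hap_rows, dtype=np.int8).T, samples)
    return variants, genotypes, haplotypes


def write_vcf(path, variants: VariantTable, genotypes: GenotypeMatrix = None,
              haplotypes: PhasedHaplotypes = None) -> None:
    """Write biallelic SNPs as VCF 4.2 text.

    Phased GT fields (``a|b``) are written when ``haplotypes`` is given,
    otherwise unphased genotype codes from ``genotypes``.
    """
    if (genotypes is None) == (haplotypes is None):
        raise ValueError("provide exactly one of genotypes or haplotypes")
    samples = genotypes.sample_ids if genotypes is not None else haplotypes.sample_ids
    lines = ["##fileformat=VCFv4.2"]
    for chrom in pd.unique(variants.chrom):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    unphased_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j in range(variants.n_snps):
        fixed = (f"{variants.chrom[j]}\t{variants.pos[j]}\t{variants.snp_id[j]}\t"
                 f"{variants.ref[j]}\t{variants.alt[j]}\t.\tPASS\t.\tGT")
        if haplotypes is not None:
            col = haplotypes.alleles[:, j]
            gts = [f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(samples))]
        else:
            gts = [unphased_code[int(g)] for g in genotypes.codes[:, j]]
        lines.append(fixed + "\t" + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_plink_text(prefix):
    """Read a PLINK text PED/MAP pair.

    Allele pairs are recoded against ref/alt derived from the MAP-adjacent
    allele inventory: at each SNP the two observed allele characters are
    taken in lexical order as (ref, alt); ``0 0`` is missing.  The PED
    phenotype column (1 = unaffected, 2 = affected) maps to status 0/1.
    """
    prefix = str(prefix)
    map_df = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                         names=["chrom", "snp_id", "cm", "pos"], dtype=str)
    n_snps = len(map_df)
    ids, statuses, rows = [], [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            ids.append(f[1])
            pheno = f[5]
            statuses.append({"2": 1, "1": 0}.get(pheno, np.nan))
            al = f[6:]
            if len(al) != 2 * n_snps:
                raise ValueError(
                    f"individual {f[1]}: expected {2 * n_snps} alleles, got {len(al)}"
                )
            rows.append(al)
    alleles = np.array(rows, dtype=object)  # n_ind x 2*n_snps
    refs, alts = [], []
    codes = np.empty((len(ids), n_snps), dtype=np.int8)
    for j in range(n_snps):
        a = alleles[:, 2 * j]
        b = alleles[:, 2 * j + 1]
        observed = sorted(set(a) | set(b) - {"0"})
        observed = [x for x in observed if x != "0"]
        if len(observed) > 2:
            raise ValueError(f"SNP {map_df.snp_id[j]}: more than two alleles")
        ref = observed[0] if observed else "A"
        alt = observed[1] if len(observed) > 1 else ("G" if ref != "G" else "A")
        refs.append(ref)
        alts.append(alt)
        for i in range(len(ids)):
            if a[i] == "0" or b[i] == "0":
                codes[i, j] = MISSING
            else:
                codes[i, j] = (a[i] != ref) + (b[i] != ref)
    variants = VariantTable(map_df.chrom.to_numpy(), map_df.pos.astype(int).to_numpy(),
                            map_df.snp_id.to_numpy(), refs, alts)
    genotypes = GenotypeMatrix(codes, ids)
    sample = SampleTable(pd.DataFrame({"individual_id": ids, "status": statuses}))
    return variants, genotypes, sample


def write_plink_text(prefix, variants: VariantTable, genotypes: GenotypeMatrix,
                     sample: SampleTable = None) -> None:
    """Write a PLINK text PED/MAP pair (alleles from the variant table)."""
    prefix = str(prefix)
    with open(f"{prefix}.map", "w") as fh:
        for j in range(variants.n_snps):
            fh.write(f"{variants.chrom[j]}\t{variants.snp_id[j]}\t0\t"
                     f"{variants.pos[j]}\n")
    status = {}
    if sample is not None:
        status = dict(zip(sample.ids, sample.table["status"]))
    with open(f"{prefix}.ped", "w") as fh:
        for i, iid in enumerate(genotypes.sample_ids):
            st = status.get(iid, np.nan)
            pheno = "2" if st == 1 else ("1" if st == 0 else "-9")
            pair = {
                0: lambda j: (variants.ref[j], variants.ref[j]),
                1: lambda j: (variants.ref[j], variants.alt[j]),
                2: lambda j: (variants.alt[j], variants.alt[j]),
                MISSING: lambda j: ("0", "0"),
            }
            al = []
            for j in range(variants.n_snps):
                a, b = pair[int(genotypes.codes[i, j])](j)
                al += [a, b]
            fh.write(f"FAM{i} {iid} 0 0 0 {pheno} " + " ".join(al) + "\n")


#: TSV header -> SampleTable column mapping accepted by read_phenotypes.
_PHENO_ALIASES = {
    "individual_id": "individual_id", "iid": "individual_id", "id": "individual_id",
    "status": "status", "afp": "afp_months", "afp_months": "afp_months",
    "sex": "sex", "maternal_edu": "maternal_edu", "paternal_edu": "paternal_edu",
    "viq": "viq", "piq": "piq", "scq": "scq",
}


def read_phenotypes(path) -> SampleTable:
    """Read the phenotype TSV; missing cells stay missing (never imputed)."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={c: _PHENO_ALIASES.get(c.lower(), c) for c in df.columns})
    if "individual_id" not in df.columns:
        raise ValueError("phenotype table must name an individual id column")
    return SampleTable(df)


def write_phenotypes(path, sample: SampleTable) -> None:
    sample.table.to_csv(path, sep="\t", index=False, na_rep="")


def write_roh_bed(segments, path) -> None:
    """Write ROH segments as BED with name = individual id."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.individual_id}\t"
                     f"{s.n_snps}\n")


def read_roh_bed(path):
    """Read segments written by :func:`write_roh_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, iid, n_snps = line.split("\t")
            out.append(ROHSegment(iid, chrom, int(start) + 1, int(end),
                                  int(n_snps)))
    return out


def write_regions_bed(regions, path) -> None:
    """Write core regions as BED; name column holds the carrier count."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.n_carriers}\n")
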