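import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rohscan.simulate import (  # noqa: E402
    SimulationConfig,
    simulate_cohort,
    simulate_haplotype_pool,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-individual cohort with background autozygosity, shared across tests."""
    cfg = SimulationConfig(n_snps=1500, chrom_length_bp=8_000_000,
                           n_cases=50, n_controls=150,
                           autozygosity_rate=0.3, seed=11)
    pool = simulate_haplotype_pool(300, cfg)
    genotypes, haplotypes, truth = simulate_cohort(pool, cfg)
    sample = simulate_phenotypes(truth, cfg, genotypes.sample_ids)
    return {"config": cfg, "variants": pool[0], "pool": pool,
            "genotypes": genotypes, "haplotypes": haplotypes,
            "truth": truth, "sample": sample}


def random_genotype_matrix(rng, n_ind, n_snps, chrom_length, p_het=0.25,
                           p_missing=0.05, n_chrom=1):
    """Random genotype codes with realistic run structure for oracle tests."""
    codes = rng.choice(
        np.array([0, 1, 2, -1], dtype=np.int8), size=(n_ind, n_snps),
        p=[(1 - p_het - p_missing) / 2, p_het,
           (1 - p_het - p_missing) / 2, p_missing])
    per = n_snps // n_chrom
    chroms, pos = [], []
    for c in range(n_chrom):
        k = per if c < n_chrom - 1 else n_snps - per * (n_chrom - 1)
        p = np.sort(rng.choice(np.arange(1, chrom_length), size=k,
                               replace=False))
        chroms += [str(c + 1)] * k
        pos.append(p)
    return codes, np.concatenate(pos), np.array(chroms, dtype=object)
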