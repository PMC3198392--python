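import numpy as np
import pytest

import haplocc as h
from haplocc.cohort import GenotypeMatrix, SnpMeta

RISK_BLOCK = ["rs12483553", "rs2838950", "rs2838951", "rs17004785"]


def make_gm(geno, alleles=None, rsids=None, gene=""):
    """Build a GenotypeMatrix from a plain 0/1/2 (or -1) array."""
    geno = np.asarray(geno, dtype=np.int8)
    m = geno.shape[1]
    rsids = rsids or [f"snp{j}" for j in range(m)]
    alleles = alleles or [("A", "G")] * m
    snps = [SnpMeta(r, gene=gene, position_index=j, alleles=a)
            for j, (r, a) in enumerate(zip(rsids, alleles))]
    return GenotypeMatrix(geno, snps, [f"I{i}" for i in range(geno.shape[0])])


def make_subjects(status, **extra):
    """Minimal valid subject table around a status vector."""
    import pandas as pd
    n = len(status)
    rng = np.random.default_rng(0)
    base = dict(
        id=[f"I{i}" for i in range(n)],
        status=np.asarray(status, dtype=int),
        age=rng.normal(60, 8, n).round(1),
        sex=rng.binomial(1, 0.6, n),
        center=rng.choice(["A", "B"], n),
        bmi_class=rng.choice(["<25", "25-30", ">30"], n),
        smoking=rng.choice(["never", "former", "current"], n),
        hypertension=rng.binomial(1, 0.4, n),
        family_history=rng.binomial(1, 0.3, n),
        vegetable_freq=rng.binomial(18, 0.45, n),
        alcohol_freq=rng.binomial(10, 0.4, n),
    )
    base["country"] = base["center"]
    base.update(extra)
    return h.validate_subjects(pd.DataFrame(base))


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale single-gene cohort with the planted OR-1.37 haplotype."""
    cfg = h.single_gene_config(seed=11)
    gm, subjects, truth = h.simulate_cohort(cfg)
    return cfg, gm, subjects, truth


@pytest.fixture(scope="session")
def full_cohort():
    """Full 13-gene / 163-SNP study-scale cohort."""
    cfg = h.default_study_config(seed=7)
    gm, subjects, truth = h.simulate_cohort(cfg)
    return cfg, gm, subjects, truth
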