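import numpy as np
import pandas as pd
import pytest

from cpnet.synthetic_data import (
    CohortConfig,
    GenotypeMatrix,
    TruthNetwork,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with detectable planted structure (session-scoped)."""
    cfg = CohortConfig(
        n_individuals=1500,
        n_proteins=60,
        n_regulators=12,
        min_targets=8,
        cis_var_mean=0.1,
        cis_var_max=0.5,
        snps_per_gene=2,
    )
    return simulate_cohort(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_genotypes(dosages: np.ndarray, pos=None, chrom=None, maf=None) -> GenotypeMatrix:
    """Hand-built genotype fixture helper."""
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    freq = dosages.astype(float).mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"rs{i:06d}" for i in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object) if chrom is None else np.asarray(chrom, dtype=object),
        pos=np.arange(1, m + 1, dtype=np.int64) * 10_000 if pos is None else np.asarray(pos, dtype=np.int64),
        maf=np.minimum(freq, 1 - freq).clip(0.011, 0.5) if maf is None else np.asarray(maf),
    )


def cis_only_truth(n_proteins: int, regulators: list[int], cis_var: float) -> TruthNetwork:
    """Truth with no protein-protein edges: each regulator only has a cis SNP."""
    cis_snp = np.full(n_proteins, -1, dtype=int)
    cis = np.zeros(n_proteins)
    for r in regulators:
        cis_snp[r] = r
        cis[r] = cis_var
    return TruthNetwork(
        n_proteins=n_proteins,
        edges=np.zeros((0, 2), dtype=int),
        betas=np.zeros(0),
        cis_snp=cis_snp,
        cis_var=cis,
        confounder_loadings=np.zeros((n_proteins, 0)),
    )


def edges_df(triples) -> pd.DataFrame:
    return pd.DataFrame(triples, columns=["a", "b", "pp"])
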