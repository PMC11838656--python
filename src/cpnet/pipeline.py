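"""End-to-end network reconstruction from raw protein and genotype data.

Chains preprocessing (Box-Cox, scaling, outlier masking, covariate
adjustment, supernormalization), cis-pQTL instrument discovery, pairwise
causal scoring, global-FDR edge selection and subnetwork assembly into a
single call. This is the entry point the robustness analyses re-run on
subsamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import causal_tests, network, pqtl, preprocess
from .synthetic_data import GenotypeMatrix, ProteinMatrix

__all__ = ["CPNResult", "reconstruct_network"]


@dataclass
class CPNResult:
    supernormalized: np.ndarray
    preprocess_params: preprocess.PreprocessParams | None
    pqtl_results: pd.DataFrame
    scores: pd.DataFrame
    threshold: float | None
    achieved_fdr: float | None
    selected: pd.DataFrame
    network: network.CausalNetwork
    subnetworks: list[network.Subnetwork] = field(default_factory=list)

    @property
    def instruments(self) -> pd.DataFrame:
        if self.pqtl_results.empty:
            return self.pqtl_results
        return self.pqtl_results[self.pqtl_results["instrument"]]


def reconstruct_network(
    proteins: ProteinMatrix,
    genotypes: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    *,
    do_preprocess: bool = True,
    window_bp: int = 300_000,
    instrument_fdr: float = 0.05,
    edge_fdr: float = 0.01,
    min_targets: int = 10,
    rows: np.ndarray | None = None,
    dedup: bool = True,
    resolve_ld: bool = True,
    eigenproteins: bool = False,
    variance_threshold: float = 0.15,
) -> CPNResult:
    """Run the full reconstruction on (optionally a row subset of) a cohort.

    ``rows`` restricts the analysis to a subsample of individuals; all
    sample-size-sensitive steps (preprocessing, supernormalization, pQTL
    mapping, local-FDR fits) are refit on that subsample.
    """
    values = proteins.values
    dosage_rows = slice(None)
    if rows is not None:
        values = values[rows]
        dosage_rows = rows
        if covariates is not None:
            covariates = np.asarray(covariates)[rows]
    geno = genotypes
    if rows is not None:
        import dataclasses as _dc

        geno = _dc.replace(genotypes, dosages=genotypes.dosages[dosage_rows])
    prot = proteins.copy_with(values)

    params = None
    if do_preprocess:
        supern, params = preprocess.preprocess_matrix(
            values, covariates=covariates, covariate_names=covariate_names, names=proteins.aptamer_ids
        )
    else:
        supern = preprocess.supernormalize_matrix(values)

    pqtl_results = pqtl.map_cis_pqtls(prot, geno, values=supern, window_bp=window_bp, fdr=instrument_fdr)
    instruments = (
        pqtl_results[pqtl_results["instrument"]] if not pqtl_results.empty else pqtl_results
    )
    scores = causal_tests.score_all_pairs(instruments, prot, geno, values=supern)

    if scores.empty:
        empty = scores.copy()
        return CPNResult(
            supernormalized=supern,
            preprocess_params=params,
            pqtl_results=pqtl_results,
            scores=scores,
            threshold=None,
            achieved_fdr=None,
            selected=empty,
            network=network.CausalNetwork(edges=empty, fdr_level=edge_fdr, subnetworks=[]),
        )

    threshold, mask, achieved = causal_tests.bayesian_fdr_select(scores["pp"].to_numpy(), edge_fdr)
    selected = scores[mask].reset_index(drop=True)
    net = network.assemble_network(selected, min_targets=min_targets, fdr_level=edge_fdr)

    subs = net.subnetworks
    gene_of = dict(zip(proteins.aptamer_ids, proteins.gene))
    if dedup and subs:
        subs = network.dedup_aptamers(subs, gene_of)
    if resolve_ld and subs:
        lead_snp_of = dict(zip(pqtl_results["aptamer_id"], pqtl_results["lead_snp"]))
        _, subs = network.resolve_ld_blocks(subs, lead_snp_of, geno, aptamer_to_gene=gene_of)
    if eigenproteins:
        for sub in subs:
            try:
                sub.eigenprotein = network.compute_eigenprotein(
                    sub, prot, values=supern, variance_threshold=variance_threshold
                )
            except (KeyError, ValueError):
                sub.eigenprotein = None

    return CPNResult(
        supernormalized=supern,
        preprocess_params=params,
        pqtl_results=pqtl_results,
        scores=scores,
        threshold=threshold,
        achieved_fdr=achieved,
        selected=selected,
        network=net,
        subnetworks=subs,
    )
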