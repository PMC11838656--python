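"""Robustness and validation analyses.

* Subsampling robustness: the full-sample network at a fixed global FDR
  is the ground truth; subsample-inferred edge posteriors are scored
  against its binary edge labels by ROC AUC and precision-recall.
* PPI overlap: z-score of the network's overlap with an undirected
  protein-protein interaction reference against uniformly random networks
  of the same size over the measured-protein universe.
* Variance explained: adjusted R^2 of proteins on their independent
  cis-SNPs, and the parental-cis decomposition for targets (variance
  explained by parents' instruments beyond the target's own).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .pipeline import CPNResult, reconstruct_network
from .synthetic_data import GenotypeMatrix, ProteinMatrix

__all__ = [
    "RobustnessResult",
    "PpiOverlapResult",
    "VarianceResult",
    "subsample_robustness",
    "ppi_overlap_zscore",
    "variance_explained",
    "parental_variance",
    "adjusted_r2",
]

logger = logging.getLogger(__name__)


@dataclass
class RobustnessResult:
    sample_size: int
    replicate: int
    roc_auc: float
    precision: np.ndarray = field(repr=False, default=None)
    recall: np.ndarray = field(repr=False, default=None)


@dataclass
class PpiOverlapResult:
    confidence_threshold: float | None
    observed_overlap: int
    random_mean: float
    random_sd: float
    z_score: float
    p_value: float


@dataclass
class VarianceResult:
    protein: str
    adjusted_r2_local_cis: float
    adjusted_r2_with_parental_cis: float | None = None
    n_regulators: int = 0

    @property
    def delta_r2(self) -> float | None:
        if self.adjusted_r2_with_parental_cis is None:
            return None
        return self.adjusted_r2_with_parental_cis - self.adjusted_r2_local_cis


def subsample_robustness(
    proteins: ProteinMatrix,
    genotypes: GenotypeMatrix,
    sizes: list[int],
    replicates: int = 3,
    fdr: float = 0.01,
    seed: int = 0,
    full_result: CPNResult | None = None,
    **pipeline_kwargs,
) -> list[RobustnessResult]:
    """Score subsample-inferred posteriors against the full-sample network.

    The full-sample reconstruction at the given edge FDR defines the
    ground truth over the universe of ordered pairs it scored; each
    subsample is fully re-inferred (preprocessing, supernormalization,
    instruments, local-FDR fits) and its PP per pair — 0 for pairs not
    scored in the subsample — is compared to the binary labels by ROC AUC
    and a precision-recall curve.
    """
    n = proteins.n_individuals
    if any(s > n for s in sizes):
        raise ValueError("subsample size exceeds the cohort size")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if full_result is None:
        full_result = reconstruct_network(proteins, genotypes, edge_fdr=fdr, **pipeline_kwargs)
    universe = full_result.scores.set_index(["a", "b"])
    selected = set(zip(full_result.selected["a"], full_result.selected["b"]))
    labels = np.array([(a, b) in selected for a, b in universe.index], dtype=int)
    if labels.sum() == 0:
        raise ValueError("ground-truth network has no edges at the requested FDR")

    results = []
    for size in sizes:
        for rep in range(replicates):
            rows = np.sort(rng.choice(n, size=size, replace=False))
            sub = reconstruct_network(proteins, genotypes, rows=rows, edge_fdr=fdr, **pipeline_kwargs)
            pp = (
                sub.scores.set_index(["a", "b"])["pp"].reindex(universe.index).fillna(0.0).to_numpy()
                if not sub.scores.empty
                else np.zeros(len(universe))
            )
            auc = float(roc_auc_score(labels, pp))
            prec, rec, _ = precision_recall_curve(labels, pp)
            results.append(
                RobustnessResult(sample_size=size, replicate=rep, roc_auc=auc, precision=prec, recall=rec)
            )
            logger.info("subsample n=%d rep=%d: AUC=%.4f", size, rep, auc)
    return results


def _normalize_pairs(edges: pd.DataFrame, gene_of: dict[str, str] | None) -> set[frozenset]:
    pairs = set()
    for a, b in zip(edges["a"], edges["b"]):
        ga = gene_of.get(a, a) if gene_of else a
        gb = gene_of.get(b, b) if gene_of else b
        if ga != gb:
            pairs.add(frozenset((ga, gb)))
    return pairs


def ppi_overlap_zscore(
    network_edges: pd.DataFrame,
    ppi: pd.DataFrame,
    universe_genes: list[str],
    thresholds: list[float | None] = (None, 0.63, 0.72),
    n_random: int = 10,
    seed: int = 0,
    gene_of: dict[str, str] | None = None,
) -> list[PpiOverlapResult]:
    """Overlap of network gene pairs with an undirected PPI reference.

    ``ppi`` needs columns gene_a, gene_b, confidence. At each threshold
    (None keeps all PPIs; numeric thresholds keep confidence strictly
    above) the observed count of unordered network gene pairs present in
    the PPI set is compared to ``n_random`` random networks with the same
    number of distinct unordered pairs, drawn uniformly from the gene
    universe without self-pairs or duplicates:
    z = (observed - mean) / sd, one-sided p = 1 - Phi(z).
    """
    net_pairs = _normalize_pairs(network_edges, gene_of)
    n_edges = len(net_pairs)
    genes = np.asarray(sorted(set(universe_genes)))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    results = []
    for thr in thresholds:
        sub = ppi if thr is None else ppi[ppi["confidence"] > thr]
        ppi_pairs = {
            frozenset((a, b)) for a, b in zip(sub["gene_a"], sub["gene_b"]) if a != b
        }
        if not ppi_pairs:
            logger.warning("PPI table empty at threshold %s; skipped", thr)
            continue
        observed = sum(1 for p in net_pairs if p in ppi_pairs)
        rand_counts = []
        for _ in range(n_random):
            drawn: set[frozenset] = set()
            while len(drawn) < n_edges:
                k = n_edges - len(drawn)
                ii = rng.integers(0, len(genes), size=2 * k).reshape(-1, 2)
                for i, j in ii:
                    if i != j:
                        drawn.add(frozenset((genes[i], genes[j])))
                    if len(drawn) == n_edges:
                        break
            rand_counts.append(sum(1 for p in drawn if p in ppi_pairs))
        mean, sd = float(np.mean(rand_counts)), float(np.std(rand_counts, ddof=1))
        z = (observed - mean) / sd if sd > 0 else np.inf
        results.append(
            PpiOverlapResult(
                confidence_threshold=thr,
                observed_overlap=observed,
                random_mean=mean,
                random_sd=sd,
                z_score=float(z),
                p_value=float(1.0 - stats.norm.cdf(z)),
            )
        )
    return results


def adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted coefficient of determination of an OLS fit with intercept."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    obs = ~np.isnan(y)
    y, X = y[obs], X[obs]
    n, p = X.shape
    if p >= n - 1:
        raise ValueError("more predictors than the sample supports")
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_explained(
    protein_id: str,
    values: np.ndarray,
    genotypes: GenotypeMatrix,
    snp_ids: list[str],
) -> VarianceResult:
    """Adjusted R^2 of a protein on its independent cis-SNPs.

    Proteins with no cis instrument get adjusted R^2 = 0 by convention.
    """
    if not snp_ids:
        return VarianceResult(protein=protein_id, adjusted_r2_local_cis=0.0)
    cols = [genotypes.snp_index(s) for s in snp_ids]
    r2 = adjusted_r2(values, genotypes.dosages[:, cols].astype(float))
    return VarianceResult(protein=protein_id, adjusted_r2_local_cis=r2)


def parental_variance(
    protein_id: str,
    values: np.ndarray,
    genotypes: GenotypeMatrix,
    own_snps: list[str],
    parent_snps: dict[str, list[str]],
) -> VarianceResult:
    """Parental-cis decomposition for one target protein.

    delta_r2 = adjR^2(parents' + own independent cis-SNPs) - adjR^2(own
    only). Overlapping SNPs between the parental and own sets are
    deduplicated. ``n_regulators`` is the number of parents contributing
    instruments.
    """
    own = list(dict.fromkeys(own_snps))
    combined = list(own)
    for snps in parent_snps.values():
        for s in snps:
            if s not in combined:
                combined.append(s)
    local = (
        adjusted_r2(values, genotypes.dosages[:, [genotypes.snp_index(s) for s in own]].astype(float))
        if own
        else 0.0
    )
    if combined:
        full = adjusted_r2(
            values, genotypes.dosages[:, [genotypes.snp_index(s) for s in combined]].astype(float)
        )
    else:
        full = 0.0
    if len(combined) < len(own) + sum(len(v) for v in parent_snps.values()):
        logger.info("protein %s: overlapping parental/own SNPs deduplicated", protein_id)
    return VarianceResult(
        protein=protein_id,
        adjusted_r2_local_cis=local,
        adjusted_r2_with_parental_cis=full,
        n_regulators=len(parent_snps),
    )
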