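"""cis-pQTL mapping, Storey q-values and independent cis-SNP selection.

Instrument discovery: for each protein, every SNP inside a cis window
(default 300 kb centered on the gene's transcription start) is tested by
simple linear regression on additive dosage; the window-level p-value is
Bonferroni-adjusted for the number of SNPs in the window, and q-values
across proteins come from the Storey-Tibshirani estimator. Proteins with
q <= fdr carry a valid instrument; the lead pSNP is the SNP with the
smallest raw p.

Independent cis-SNPs (used by the variance-explained analyses) come from
forward conditional selection within +/-150 kb of the lead variant with a
joint-model p threshold (default 0.00763) and a dosage-r^2 collinearity
cutoff (default 0.9).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, interpolate

from .synthetic_data import GenotypeMatrix, ProteinMatrix

__all__ = [
    "PqtlResult",
    "IndependentCisSet",
    "map_cis_pqtls",
    "storey_qvalues",
    "select_independent_cis_snps",
]

logger = logging.getLogger(__name__)


@dataclass
class PqtlResult:
    aptamer_id: str
    lead_snp: str
    beta: float
    p_value: float
    window_adjusted_p: float
    q_value: float = np.nan
    n_snps_in_window: int = 0


@dataclass
class IndependentCisSet:
    aptamer_id: str
    snp_ids: list[str] = field(default_factory=list)
    joint_p: list[float] = field(default_factory=list)
    collinearity_cutoff: float = 0.9


def storey_qvalues(pvalues: np.ndarray, lambda_grid: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values.

    pi0 is estimated from pi0(lambda) = #{p > lambda} / (m (1 - lambda))
    over the grid, smoothed by a cubic spline and evaluated at the largest
    lambda. q_i = min_{t >= p_i} pi0 * m * t / #{p <= t}.

    Returns (qvalues, pi0_hat).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    if m < 2 * lam.size:
        pi0 = 1.0  # too few tests to smooth; conservative null proportion
    else:
        pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
        spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam.max()))
        pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def _regress_snps(y: np.ndarray, dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simple linear regression of y on each dosage column.

    Returns (betas, p-values) with NaN for monomorphic columns.
    """
    obs = ~np.isnan(y)
    yv = y[obs]
    X = dosages[obs].astype(float)
    n = yv.size
    yc = yv - yv.mean()
    Xc = X - X.mean(axis=0)
    sxx = (Xc**2).sum(axis=0)
    sxy = Xc.T @ yc
    syy = float((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        r2 = (sxy**2) / (sxx * syy)
    r2 = np.clip(r2, 0.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat2 = r2 * df / (1.0 - r2)
    pvals = stats.f.sf(tstat2, 1, df)
    pvals[sxx <= 0] = np.nan
    beta[sxx <= 0] = np.nan
    return beta, pvals


def map_cis_pqtls(
    proteins: ProteinMatrix,
    genotypes: GenotypeMatrix,
    values: np.ndarray | None = None,
    window_bp: int = 300_000,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Map the lead cis pSNP per protein and call instruments at the FDR.

    ``values`` (supernormalized or at least adjusted matrix, individuals x
    aptamers) defaults to ``proteins.values``. The window is
    ``window_bp`` centered on each gene's transcription start. Returns a
    DataFrame with one row per protein that has >= 1 SNP in its window and
    columns: aptamer_id, lead_snp, beta, p_value, window_adjusted_p,
    q_value, n_snps_in_window, instrument (bool).
    """
    vals = proteins.values if values is None else np.asarray(values, dtype=float)
    half = window_bp // 2
    rows = []
    for j in range(proteins.n_aptamers):
        chrom = proteins.gene_chrom[j]
        tss = proteins.gene_tss[j]
        if tss is None or (isinstance(tss, float) and np.isnan(tss)):
            logger.warning("aptamer %s: gene coordinates missing, skipped", proteins.aptamer_ids[j])
            continue
        in_window = (genotypes.chrom == chrom) & (np.abs(genotypes.pos - tss) <= half)
        idx = np.flatnonzero(in_window)
        if idx.size == 0:
            continue
        beta, pvals = _regress_snps(vals[:, j], genotypes.dosages[:, idx])
        valid = ~np.isnan(pvals)
        if not valid.any():
            continue
        best = idx[valid][np.argmin(pvals[valid])]
        best_p = float(np.nanmin(pvals))
        rows.append(
            {
                "aptamer_id": proteins.aptamer_ids[j],
                "lead_snp": genotypes.snp_ids[best],
                "lead_snp_idx": int(best),
                "beta": float(beta[np.flatnonzero(idx == best)[0]]),
                "p_value": best_p,
                "window_adjusted_p": min(1.0, int(valid.sum()) * best_p),
                "n_snps_in_window": int(valid.sum()),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["q_value"] = []
        result["instrument"] = []
        return result
    q, _ = storey_qvalues(result["window_adjusted_p"].to_numpy())
    result["q_value"] = q
    result["instrument"] = result["q_value"] <= fdr
    return result


def select_independent_cis_snps(
    protein_values: np.ndarray,
    genotypes: GenotypeMatrix,
    lead_snp: str,
    window_bp: int = 150_000,
    p_threshold: float = 0.00763,
    collinearity_r2: float = 0.9,
    aptamer_id: str = "",
) -> IndependentCisSet:
    """Forward conditional selection of independent cis-SNPs.

    Starting from the empty model, each step adds the SNP inside
    +/-``window_bp`` of the lead variant with the smallest conditional
    p-value (Wald p of its coefficient in the joint regression with the
    already-selected SNPs), provided p < ``p_threshold`` and its dosage
    r^2 with every selected SNP is below ``collinearity_r2``.
    """
    lead_idx = genotypes.snp_index(lead_snp)
    same_chrom = genotypes.chrom == genotypes.chrom[lead_idx]
    in_window = same_chrom & (np.abs(genotypes.pos - genotypes.pos[lead_idx]) <= window_bp)
    candidates = np.flatnonzero(in_window)

    y = np.asarray(protein_values, dtype=float)
    obs = ~np.isnan(y)
    y = y[obs]
    X = genotypes.dosages[np.ix_(obs, candidates)].astype(float)
    n = y.size

    selected: list[int] = []  # positions within `candidates`
    joint_p: list[float] = []
    while True:
        best_pos, best_p = None, np.inf
        for pos in range(len(candidates)):
            if pos in selected:
                continue
            x = X[:, pos]
            if np.ptp(x) == 0:
                continue
            # collinearity screen against already-selected SNPs
            collinear = False
            for s in selected:
                r = np.corrcoef(x, X[:, s])[0, 1]
                if not np.isfinite(r) or r * r >= collinearity_r2:
                    collinear = True
                    break
            if collinear:
                continue
            design = np.column_stack([np.ones(n), X[:, selected], x])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            dof = n - design.shape[1]
            if dof <= 0:
                continue
            sigma2 = float(resid @ resid) / dof
            xtx_inv = np.linalg.inv(design.T @ design)
            se = np.sqrt(sigma2 * xtx_inv[-1, -1])
            p = 2 * stats.t.sf(abs(coef[-1] / se), dof) if se > 0 else 1.0
            if p < best_p:
                best_p, best_pos = p, pos
        if best_pos is None or best_p >= p_threshold:
            break
        selected.append(best_pos)
        joint_p.append(float(best_p))

    return IndependentCisSet(
        aptamer_id=aptamer_id,
        snp_ids=[genotypes.snp_ids[candidates[s]] for s in selected],
        joint_p=joint_p,
        collinearity_cutoff=collinearity_r2,
    )
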