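"""Pairwise instrumented causal tests and global-FDR edge selection.

For each instrumented exposure protein A with categorical genotype
instrument E and each candidate target B the module computes two nested
likelihood-ratio tests on the supernormalized scale:

* the secondary-linkage test (does E associate with B?), with
  llr2 = -(n/2) ln(1 - rho^2) where rho^2 is the fraction of B's variance
  explained by the genotype-category means; under the null
  rho^2 ~ Beta((k-1)/2, (n-k)/2) for k genotype categories;

* the controlled test (are A and B still dependent after adjusting both
  for E?), with llr5 = (n/2) ln(RSS_null / RSS_alt) for the nested models
  B ~ category means vs B ~ category means + c*A; the partial explained
  fraction 1 - exp(-2 llr5 / n) ~ Beta(1/2, (n-k-1)/2) under the null.

LLRs are converted to posterior probabilities of the alternative with an
empirical-Bayes local false-discovery-rate fit per regulator row (null
density induced by the Beta law, alternative from a histogram on the LLR
scale, Storey null-proportion estimate, isotonic monotonization). The
edge posterior is PP = P2 * P5 and edges are selected by the global
Bayesian FDR rule: sort PP descending and keep the largest prefix whose
running FDR, 1 - mean(selected PP), stays at or below the target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .pqtl import storey_qvalues
from .synthetic_data import GenotypeMatrix, ProteinMatrix

__all__ = [
    "TestResult",
    "EdgeScore",
    "LocalFdrModel",
    "merge_genotype_categories",
    "llr_secondary",
    "llr_controlled",
    "fit_local_fdr",
    "score_all_pairs",
    "bayesian_fdr_select",
]

logger = logging.getLogger(__name__)

LLR_CAP = 700.0  # nats; beyond this the posterior is 1 to machine precision


@dataclass
class TestResult:
    llr: float
    p_value: float
    n_used: int
    k: int


@dataclass
class EdgeScore:
    a: str
    b: str
    p2: float
    p5: float

    @property
    def pp(self) -> float:
        return self.p2 * self.p5


def merge_genotype_categories(e: np.ndarray) -> tuple[np.ndarray, int]:
    """Recode a dosage vector to 0..k-1, merging categories with < 2 members
    into the nearest dosage level that has >= 2.

    Returns (codes, k). Raises if fewer than 2 viable categories remain.
    """
    e = np.asarray(e)
    levels, counts = np.unique(e, return_counts=True)
    viable = levels[counts >= 2]
    if viable.size < 2:
        raise ValueError("need >= 2 genotype categories with >= 2 members")
    # map every level to the nearest viable level (ties -> lower dosage)
    remap = {}
    for lv in levels:
        j = np.argmin(np.abs(viable.astype(float) - float(lv)))
        remap[lv] = viable[j]
    merged = np.array([remap[v] for v in e])
    codes = np.searchsorted(viable, merged)
    return codes.astype(np.int64), int(viable.size)


def _pair_tests_vectorized(
    codes: np.ndarray,
    k: int,
    B: np.ndarray,
    A: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Complete-case secondary (and optionally controlled) tests for all
    columns of B against one categorical instrument.

    codes: (n,) int in 0..k-1 (no missing); B: (n, p) float, NaN = masked;
    A: (n,) float for the controlled test. Columns whose complete cases
    are degenerate come back as NaN ("no-test").
    """
    n_all, p = B.shape
    V = ~np.isnan(B)
    if A is not None:
        V &= ~np.isnan(A)[:, None]
    G = np.zeros((n_all, k))
    G[np.arange(n_all), codes] = 1.0

    nb = V.sum(axis=0).astype(float)  # (p,)
    counts = G.T @ V  # (k, p) category sizes per column
    k_eff = (counts >= 2).sum(axis=0).astype(float)

    Bz = np.where(V, B, 0.0)
    meanB = Bz.sum(axis=0) / np.maximum(nb, 1)
    Bc = np.where(V, B - meanB, 0.0)
    varB = (Bc**2).sum(axis=0) / np.maximum(nb, 1)  # MLE variance on complete cases
    ok = (nb >= k_eff + 2) & (k_eff >= 2) & (varB > 0)
    sdB = np.sqrt(np.where(varB > 0, varB, 1.0))
    Bs = Bc / sdB  # standardized on complete cases, zeros at masked entries

    sums = G.T @ Bs  # (k, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    rho2 = np.clip(((counts / np.maximum(nb, 1)) * mu**2).sum(axis=0), 0.0, 1.0 - 1e-16)

    llr2 = np.minimum(-(nb / 2.0) * np.log1p(-rho2), LLR_CAP)
    p2 = stats.beta.sf(rho2, (k_eff - 1) / 2.0, np.maximum(nb - k_eff, 1) / 2.0)
    llr2[~ok] = np.nan
    p2[~ok] = np.nan
    out = {"llr2": llr2, "p2_pvalue": p2, "n_used": nb.astype(int), "k": k_eff.astype(int)}

    if A is not None:
        Az = np.where(V, A[:, None], 0.0)
        sumsA = G.T @ Az  # (k, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            muA = np.where(counts > 0, sumsA / np.maximum(counts, 1), 0.0)
        residA = np.where(V, A[:, None] - muA[codes], 0.0)
        # genotype-demeaned B residuals: Bs already centered globally; demean per category
        muB_cat = mu  # (k, p) means of standardized B per category
        residB = np.where(V, Bs - muB_cat[codes], 0.0)
        sAA = (residA**2).sum(axis=0)
        sBB = (residB**2).sum(axis=0)
        sAB = (residA * residB).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2p = np.clip(sAB**2 / (sAA * sBB), 0.0, 1.0 - 1e-16)
        ok5 = ok & (sAA > 1e-12) & (sBB > 1e-12) & (nb >= k_eff + 3)
        llr5 = np.minimum(-(nb / 2.0) * np.log1p(-r2p), LLR_CAP)
        p5 = stats.beta.sf(r2p, 0.5, np.maximum(nb - k_eff - 1, 1) / 2.0)
        llr5[~ok5] = np.nan
        p5[~ok5] = np.nan
        out["llr5"] = llr5
        out["p5_pvalue"] = p5
    return out


def llr_secondary(e: np.ndarray, b: np.ndarray) -> TestResult:
    """Secondary-linkage test of one instrument against one target."""
    e = np.asarray(e)
    b = np.asarray(b, dtype=float)
    obs = ~np.isnan(b)
    codes, k = merge_genotype_categories(e[obs])
    full_codes = np.zeros(e.shape[0], dtype=np.int64)
    full_codes[obs] = codes
    bb = np.where(obs, b, np.nan)[:, None]
    res = _pair_tests_vectorized(full_codes, k, bb)
    llr, p = float(res["llr2"][0]), float(res["p2_pvalue"][0])
    if np.isnan(llr):
        raise ValueError("degenerate pair: no test possible")
    return TestResult(llr=llr, p_value=p, n_used=int(res["n_used"][0]), k=int(res["k"][0]))


def llr_controlled(e: np.ndarray, a: np.ndarray, b: np.ndarray) -> TestResult:
    """Controlled test of A-B dependence after adjusting both for E."""
    e = np.asarray(e)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    obs = ~(np.isnan(a) | np.isnan(b))
    codes, k = merge_genotype_categories(e[obs])
    full_codes = np.zeros(e.shape[0], dtype=np.int64)
    full_codes[obs] = codes
    bb = np.where(obs, b, np.nan)[:, None]
    aa = np.where(obs, a, np.nan)
    res = _pair_tests_vectorized(full_codes, k, bb, A=aa)
    llr, p = float(res["llr5"][0]), float(res["p5_pvalue"][0])
    if np.isnan(llr):
        raise ValueError("degenerate pair: no test possible")
    return TestResult(llr=llr, p_value=p, n_used=int(res["n_used"][0]), k=int(res["k"][0]))


@dataclass
class LocalFdrModel:
    """LLR -> posterior-probability map fitted by empirical Bayes.

    The posterior of the alternative is 1 - pi0 * f0(llr) / fhat(llr),
    evaluated on histogram bins, clipped to [0, 1] and monotonized by
    isotonic regression in llr.
    """

    pi0: float
    bin_edges: np.ndarray
    posterior_bins: np.ndarray

    def posterior(self, llrs: np.ndarray) -> np.ndarray:
        llrs = np.asarray(llrs, dtype=float)
        idx = np.clip(np.digitize(llrs, self.bin_edges) - 1, 0, len(self.posterior_bins) - 1)
        out = self.posterior_bins[idx]
        return np.where(np.isnan(llrs), np.nan, out)


def _null_beta_params(n: float, k: float, test: str) -> tuple[float, float]:
    if test == "secondary":
        return (k - 1) / 2.0, (n - k) / 2.0
    if test == "controlled":
        return 0.5, (n - k - 1) / 2.0
    raise ValueError(f"unknown test {test!r}")


def _pi0_fixed_lambda(pvals: np.ndarray, lam: float = 0.5) -> float:
    """Storey null-proportion estimate at a fixed lambda.

    Less variable than the spline smoother on short rows, and conservative
    (signal p-values concentrate near 0, inflating the estimate at most
    marginally); used for the local-FDR fits where an underestimated pi0
    directly inflates null posteriors.
    """
    pvals = np.asarray(pvals, dtype=float)
    return float(min(1.0, np.mean(pvals > lam) / (1.0 - lam)))


def fit_local_fdr(
    llrs: np.ndarray,
    n: float,
    k: int,
    test: str = "secondary",
    nbins: int | None = None,
) -> LocalFdrModel:
    """Fit the per-row local-FDR posterior curve on the LLR scale.

    ``n`` and ``k`` are the (representative) complete-case sample size and
    genotype-category count inducing the null Beta law. The alternative
    density is a histogram of the row's LLRs over equal-width bins on
    [0, max(llr)] with a one-pseudo-count floor per bin; the bin count
    defaults to ~sqrt(row length), capped at 200, so sparse rows keep
    enough mass per bin for the density ratio to be stable.
    """
    llrs = np.asarray(llrs, dtype=float)
    llrs = llrs[~np.isnan(llrs)]
    if llrs.size == 0:
        raise ValueError("no LLRs to fit")
    if nbins is None:
        nbins = int(max(10, min(200, round(np.sqrt(llrs.size)))))
    a, b = _null_beta_params(float(n), float(k), test)
    if np.ptp(llrs) == 0:
        warnings.warn("degenerate all-equal LLRs; posterior set to 0")
        edges = np.array([0.0, max(llrs[0], 1.0)])
        return LocalFdrModel(pi0=1.0, bin_edges=edges, posterior_bins=np.zeros(1))

    rho2 = -np.expm1(-2.0 * llrs / n)
    pvals = stats.beta.sf(np.clip(rho2, 0, 1), a, b)
    pi0 = _pi0_fixed_lambda(pvals)

    top = max(float(llrs.max()), 1e-6)
    edges = np.linspace(0.0, top * (1 + 1e-9), nbins + 1)
    width = edges[1] - edges[0]
    counts, _ = np.histogram(llrs, bins=edges)
    fhat = (counts + 1.0) / (llrs.size + nbins) / width

    # null mass per bin from the Beta law, via the monotone rho2(llr) map
    rho2_edges = np.clip(-np.expm1(-2.0 * edges / n), 0.0, 1.0)
    f0 = np.diff(stats.beta.cdf(rho2_edges, a, b)) / width

    with np.errstate(divide="ignore", invalid="ignore"):
        post = np.clip(1.0 - pi0 * f0 / fhat, 0.0, 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    post = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True).fit_transform(centers, post)
    return LocalFdrModel(pi0=float(pi0), bin_edges=edges, posterior_bins=post)


def _pooled_posteriors(pvals: np.ndarray, nbins: int = 200) -> np.ndarray:
    """Local-FDR posteriors pooled across rows (fallback for short rows).

    Works on the common null scale s = -ln p, where the null density is
    exactly Exp(1) regardless of each pair's (n, k). The alternative
    density is a histogram over ``nbins`` equal-width bins on [0, max s]
    with a one-pseudo-count floor; the posterior 1 - pi0 * f0 / fhat is
    clipped to [0, 1] and monotonized to be non-decreasing in s.
    """
    pvals = np.asarray(pvals, dtype=float)
    obs = ~np.isnan(pvals)
    out = np.full(pvals.shape, np.nan)
    pv = np.clip(pvals[obs], np.exp(-LLR_CAP), 1.0)
    if pv.size == 0:
        return out
    _, pi0 = storey_qvalues(pv)
    s = -np.log(pv)
    top = max(float(s.max()), 1e-6)
    edges = np.linspace(0.0, top * (1 + 1e-9), nbins + 1)
    width = edges[1] - edges[0]
    counts, _ = np.histogram(s, bins=edges)
    fhat = (counts + 1.0) / (s.size + nbins) / width
    f0 = np.diff(-np.exp(-edges)) / width  # exact Exp(1) mass per bin
    post = np.clip(1.0 - pi0 * f0 / fhat, 0.0, 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    post = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True).fit_transform(centers, post)
    idx = np.clip(np.digitize(s, edges) - 1, 0, nbins - 1)
    out[obs] = post[idx]
    return out


def score_all_pairs(
    instruments: pd.DataFrame,
    proteins: ProteinMatrix,
    genotypes: GenotypeMatrix,
    values: np.ndarray | None = None,
    min_row_for_local_fit: int = 100,
) -> pd.DataFrame:
    """Score every ordered (A, B) pair, A instrumented, B any other aptamer
    not encoded by A's own gene.

    ``instruments`` is the pQTL result table filtered to instrument rows
    (columns aptamer_id, lead_snp_idx or lead_snp). Returns a DataFrame
    with per-pair LLRs, null p-values, posteriors P2/P5 and PP = P2*P5.
    Rows with fewer than ``min_row_for_local_fit`` testable pairs fall
    back to a pooled posterior fit across all short rows.
    """
    vals = proteins.values if values is None else np.asarray(values, dtype=float)
    gene_of = dict(zip(proteins.aptamer_ids, proteins.gene))

    frames = []
    pending_pool: list[pd.DataFrame] = []
    n_no_test = 0
    for _, inst in instruments.iterrows():
        a_apt = inst["aptamer_id"]
        a_col = proteins.column(a_apt)
        snp_idx = int(inst["lead_snp_idx"]) if "lead_snp_idx" in inst else genotypes.snp_index(inst["lead_snp"])
        e = genotypes.dosages[:, snp_idx]
        try:
            codes, k = merge_genotype_categories(e)
        except ValueError:
            logger.warning("instrument for %s has a single genotype category; row skipped", a_apt)
            continue
        a_gene = gene_of[a_apt]
        b_mask = np.array([apt != a_apt and gene_of[apt] != a_gene for apt in proteins.aptamer_ids])
        b_cols = np.flatnonzero(b_mask)
        if b_cols.size == 0:
            continue
        B = vals[:, b_cols]
        res = _pair_tests_vectorized(codes, k, B, A=vals[:, a_col])
        df = pd.DataFrame(
            {
                "a": a_apt,
                "b": proteins.aptamer_ids[b_cols],
                "llr2": res["llr2"],
                "llr5": res["llr5"],
                "p2_pvalue": res["p2_pvalue"],
                "p5_pvalue": res["p5_pvalue"],
                "n_used": res["n_used"],
                "k": res["k"],
            }
        )
        testable = df[["llr2", "llr5"]].notna().all(axis=1)
        n_no_test += int((~testable).sum())
        df = df[testable].reset_index(drop=True)
        if df.empty:
            continue
        n_rep = float(np.median(df["n_used"]))
        k_rep = int(df["k"].mode().iat[0])
        if len(df) >= min_row_for_local_fit:
            m2 = fit_local_fdr(df["llr2"].to_numpy(), n_rep, k_rep, test="secondary")
            m5 = fit_local_fdr(df["llr5"].to_numpy(), n_rep, k_rep, test="controlled")
            df["p2"] = m2.posterior(df["llr2"].to_numpy())
            df["p5"] = m5.posterior(df["llr5"].to_numpy())
            frames.append(df)
        else:
            pending_pool.append(df)

    if pending_pool:
        pooled = pd.concat(pending_pool, ignore_index=True)
        pooled["p2"] = _pooled_posteriors(pooled["p2_pvalue"].to_numpy())
        pooled["p5"] = _pooled_posteriors(pooled["p5_pvalue"].to_numpy())
        frames.append(pooled)
    if n_no_test:
        logger.info("%d pairs skipped as no-test (degenerate complete cases)", n_no_test)
    if not frames:
        return pd.DataFrame(
            columns=["a", "b", "llr2", "llr5", "p2_pvalue", "p5_pvalue", "n_used", "k", "p2", "p5", "pp"]
        )
    scores = pd.concat(frames, ignore_index=True)
    scores["pp"] = scores["p2"] * scores["p5"]
    return scores


def bayesian_fdr_select(
    pp: np.ndarray,
    target_fdr: float,
) -> tuple[float | None, np.ndarray, float | None]:
    """Global Bayesian FDR selection.

    Sort posteriors descending; after keeping the top i edges the running
    FDR is 1 - mean(top-i PP). The selected set is the largest prefix with
    running FDR <= target. Returns (threshold, boolean selection mask over
    the input order, achieved FDR); threshold and achieved are None when
    nothing qualifies.
    """
    pp = np.asarray(pp, dtype=float)
    if np.any((pp < 0) | (pp > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    if pp.size == 0:
        return None, np.zeros(0, dtype=bool), None
    order = np.argsort(-pp, kind="mergesort")
    sorted_pp = pp[order]
    running_fdr = 1.0 - np.cumsum(sorted_pp) / np.arange(1, pp.size + 1)
    qualifying = np.flatnonzero(running_fdr <= target_fdr + 1e-12)
    mask = np.zeros(pp.size, dtype=bool)
    if qualifying.size == 0:
        logger.warning("no edge qualifies at global FDR %.3g", target_fdr)
        return None, mask, None
    n_sel = int(qualifying.max()) + 1
    mask[order[:n_sel]] = True
    return float(sorted_pp[n_sel - 1]), mask, float(running_fdr[n_sel - 1])
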