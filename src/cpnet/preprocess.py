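"""Protein preprocessing: Box-Cox, scaling, outlier masking, adjustment.

The chain applied before causal inference is

    Box-Cox transform -> center/scale -> global extreme-outlier masking
    -> covariate (age/sex) adjustment -> rank-based inverse normal
    transform ("supernormalization") per protein.

Percentiles use linear interpolation between order statistics (numpy's
default, the classic "type 7" rule). Masked values propagate as NaN and
are excluded pairwise downstream, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PreprocessParams",
    "boxcox_transform",
    "mask_extreme_outliers",
    "adjust_covariates",
    "supernormalize",
    "preprocess_matrix",
]


@dataclass
class PreprocessParams:
    """Fitted parameters of the preprocessing chain (reproducibility sidecar)."""

    boxcox_lambda: np.ndarray
    shift_offsets: np.ndarray
    outlier_threshold: float | None = None
    adjustment_covariates: list[str] = field(default_factory=list)
    stage_order: tuple[str, ...] = ("boxcox", "center_scale", "mask", "adjust", "supernormalize")

    def to_dict(self) -> dict:
        return {
            "boxcox_lambda": np.asarray(self.boxcox_lambda).tolist(),
            "shift_offsets": np.asarray(self.shift_offsets).tolist(),
            "outlier_threshold": self.outlier_threshold,
            "adjustment_covariates": list(self.adjustment_covariates),
            "stage_order": list(self.stage_order),
        }


def boxcox_transform(values: np.ndarray, names=None) -> tuple[np.ndarray, PreprocessParams]:
    """Per-protein maximum-likelihood Box-Cox, then center to 0 / scale to SD 1.

    Columns must be strictly positive; otherwise they are shifted by
    ``1 - min`` and the offset recorded so the transform stays invertible.
    Constant columns are refused (zero variance has no Box-Cox MLE).
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    out = np.empty_like(values)
    lambdas = np.empty(p)
    offsets = np.zeros(p)
    for j in range(p):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        name = names[j] if names is not None else str(j)
        if obs.size < 3:
            raise ValueError(f"protein {name}: too few observed values")
        if np.ptp(obs) == 0:
            raise ValueError(f"protein {name}: constant column, Box-Cox undefined")
        mn = obs.min()
        if mn <= 0:
            offsets[j] = 1.0 - mn
        shifted = col + offsets[j]
        if np.nanmin(shifted) <= 0:
            raise ValueError(f"protein {name}: non-positive values after shifting")
        mask = ~np.isnan(shifted)
        transformed, lam = stats.boxcox(shifted[mask])
        lambdas[j] = lam
        colt = np.full(n, np.nan)
        colt[mask] = transformed
        colt = (colt - np.nanmean(colt)) / np.nanstd(colt, ddof=1)
        out[:, j] = colt
    return out, PreprocessParams(boxcox_lambda=lambdas, shift_offsets=offsets)


def mask_extreme_outliers(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Mask globally extreme values on the transformed scale.

    The cutoff is the 99.5th percentile of the distribution of per-protein
    99th-percentile cutoffs; every value strictly above it becomes NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 proteins to define the global cutoff")
    per_protein_99 = np.nanpercentile(values, 99, axis=0)
    threshold = float(np.percentile(per_protein_99, 99.5))
    masked = values.copy()
    masked[masked > threshold] = np.nan
    return masked, threshold


def adjust_covariates(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualize each protein on the covariates (with intercept), per protein
    on its complete cases. Masked entries stay masked.
    """
    values = np.asarray(values, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    n = values.shape[0]
    design = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    out = np.full_like(values, np.nan)
    nan_cols = np.isnan(values).any(axis=0)
    # fast path: shared design for fully observed columns
    full = ~nan_cols
    if full.any():
        beta, *_ = np.linalg.lstsq(design, values[:, full], rcond=None)
        out[:, full] = values[:, full] - design @ beta
    for j in np.flatnonzero(nan_cols):
        col = values[:, j]
        obs = ~np.isnan(col)
        d = design[obs]
        if np.linalg.matrix_rank(d) < d.shape[1]:
            raise ValueError(f"rank-deficient design on complete cases of column {j}")
        beta, *_ = np.linalg.lstsq(d, col[obs], rcond=None)
        out[obs, j] = col[obs] - d @ beta
    return out


def supernormalize(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset, unit variance.

    Ties receive average ranks; ranks r over the m non-missing values map
    through Phi^-1((r - 3/8) / (m + 1/4)), then the result is rescaled to
    unit sample variance. Strictly monotone in the input ordering.
    """
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    m = int(obs.sum())
    if m < 3:
        raise ValueError("need at least 3 non-missing values")
    vals = x[obs]
    if np.ptp(vals) == 0:
        raise ValueError("all-equal input: ranks undefined")
    ranks = stats.rankdata(vals, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (m + 0.25))
    z = (z - z.mean()) / z.std(ddof=1)
    out = np.full_like(x, np.nan)
    out[obs] = z
    return out


def supernormalize_matrix(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = supernormalize(values[:, j])
    return out


def preprocess_matrix(
    values: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    names=None,
) -> tuple[np.ndarray, PreprocessParams]:
    """Run the full chain; returns the supernormalized matrix and fitted params."""
    transformed, params = boxcox_transform(values, names=names)
    masked, threshold = mask_extreme_outliers(transformed)
    params.outlier_threshold = threshold
    if covariates is not None:
        masked = adjust_covariates(masked, covariates)
        params.adjustment_covariates = list(covariate_names or [])
    return supernormalize_matrix(masked), params
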