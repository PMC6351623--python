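"""Negative-binomial differential expression testing.

The analysis chain is: (1) remove features with low raw expression
(<= 40 RPK in at least two thirds of the libraries), (2) estimate
per-library size factors by the median-of-ratios method, (3) estimate a
per-feature NB dispersion by method of moments on normalized counts
pooled within groups, (4) fit a log-link NB regression per feature
(intercept + group indicator, size factors as offsets) by IRLS with the
dispersion held fixed, and test the group coefficient with a two-sided
Wald test, (5) adjust p-values by Benjamini-Hochberg, (6) call a feature
up (down) when log2FC >= +1.5 (<= -1.5) and adjusted p < 0.001.

The NB Wald procedure is deliberately simple and fully documented: no
dispersion-trend or fold-change shrinkage, no outlier replacement. Its
calibration is checked by simulation in the test-suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counting import CountMatrix, rpk

logger = logging.getLogger(__name__)

DEFAULT_RPK_THRESHOLD = 40.0
DEFAULT_LFC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.001
DISPERSION_FLOOR = 1e-8

_IRLS_MAX_ITER = 100
_IRLS_TOL = 1e-10
_BETA_CLIP = 30.0  # natural-log scale; guards separation when a group is all zero


@dataclass
class FilterSpec:
    """Low-expression filter: drop a feature when its raw RPK is at or
    below ``rpk_threshold`` in at least ``min_low_libraries`` libraries
    (default: two thirds of the libraries, rounded up — 10 of 15)."""

    rpk_threshold: float = DEFAULT_RPK_THRESHOLD
    min_low_libraries: int | None = None

    def resolve_min_low(self, n_libraries: int) -> int:
        if self.min_low_libraries is not None:
            if not (1 <= self.min_low_libraries <= n_libraries):
                raise ValueError("min_low_libraries out of range")
            return self.min_low_libraries
        return math.ceil(2.0 / 3.0 * n_libraries)


@dataclass
class SizeFactors:
    """Per-library scaling constants; geometric mean 1 after rescaling."""

    factors: pd.Series
    method: str  # 'median_of_ratios' or 'total_count'

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


def low_count_filter(
    matrix: CountMatrix, spec: FilterSpec | None = None
) -> tuple[list[str], list[str]]:
    """Partition feature ids into (kept, removed) by the RPK filter.

    The boundary is inclusive: RPK exactly equal to the threshold counts
    as low.
    """
    spec = spec or FilterSpec()
    min_low = spec.resolve_min_low(len(matrix.library_ids))
    r = rpk(matrix)
    n_low = (r <= spec.rpk_threshold).sum(axis=1)
    removed_mask = n_low >= min_low
    kept = list(r.index[~removed_mask])
    removed = list(r.index[removed_mask])
    return kept, removed


def size_factors_median_of_ratios(matrix: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    The per-feature reference is the geometric mean of its counts across
    libraries, over features positive in every library; each library's
    factor is the median ratio of its counts to the reference, rescaled
    so the factors have geometric mean 1. Falls back to total counts
    (with a warning) when no feature is positive everywhere.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        logger.warning(
            "no feature positive in all libraries; "
            "falling back to total-count size factors"
        )
        return size_factors_total_count(matrix)
    sub = counts[all_positive]
    log_ref = np.log(sub).mean(axis=1)
    log_ratios = np.log(sub) - log_ref[:, None]
    s = np.exp(np.median(log_ratios, axis=0))
    s /= np.exp(np.mean(np.log(s)))
    return SizeFactors(pd.Series(s, index=matrix.library_ids),
                       method="median_of_ratios")


def size_factors_total_count(matrix: CountMatrix) -> SizeFactors:
    """Total-count size factors (library depth), geometric mean 1."""
    totals = matrix.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("library with zero total counts")
    s = totals / np.exp(np.mean(np.log(totals)))
    return SizeFactors(s, method="total_count")


def estimate_dispersion(
    matrix: CountMatrix,
    size_factors: SizeFactors,
    groups: pd.Series,
) -> pd.Series:
    """Method-of-moments NB dispersion per feature.

    On normalized counts, within-group variances are pooled (weighted by
    degrees of freedom) and compared with the pooled mean:
    ``alpha = max((var - mean) / mean**2, 1e-8)``. Poisson-like or
    constant features land on the floor.
    """
    norm = matrix.counts.to_numpy(dtype=float) / \
        size_factors.factors.loc[matrix.library_ids].to_numpy()
    labels = groups.loc[matrix.library_ids].to_numpy()
    pooled_var = np.zeros(norm.shape[0])
    total_df = 0
    for g in np.unique(labels):
        cols = labels == g
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        pooled_var += norm[:, cols].var(axis=1, ddof=1) * (n_g - 1)
        total_df += n_g - 1
    if total_df == 0:
        raise ValueError("need >=2 replicates in at least one group")
    pooled_var /= total_df
    pooled_mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / np.square(pooled_mean)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=matrix.feature_ids)


def _nb_irls(
    y: np.ndarray,
    x: np.ndarray,
    log_s: np.ndarray,
    alpha: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for per-feature NB regression with log link.

    ``y`` is features x libraries, ``x`` the 0/1 group indicator,
    ``log_s`` the per-library offset, ``alpha`` the fixed per-feature
    dispersion. Returns (beta0, beta1, converged) with beta on the
    natural-log scale; the Wald SE is derived from the same weights.
    """
    n_feat = y.shape[0]
    s = np.exp(log_s)
    in_grp = x == 1
    # initialize at group means of normalized counts (pseudocount for zeros)
    m0 = (y[:, ~in_grp] / s[~in_grp]).mean(axis=1)
    m1 = (y[:, in_grp] / s[in_grp]).mean(axis=1)
    b0 = np.log(np.maximum(m0, 1e-8))
    b1 = np.log(np.maximum(m1, 1e-8)) - b0
    active = np.ones(n_feat, dtype=bool)
    for _ in range(_IRLS_MAX_ITER):
        if not active.any():
            break
        eta = b0[:, None] + b1[:, None] * x[None, :] + log_s[None, :]
        mu = np.exp(np.clip(eta, -_BETA_CLIP, _BETA_CLIP + np.max(np.abs(log_s)) + 5))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - log_s[None, :]) + (y - mu) / mu
        a11 = w.sum(axis=1)
        a12 = (w * x[None, :]).sum(axis=1)
        a22 = a12  # x is 0/1 so x^2 = x
        r1 = (w * z).sum(axis=1)
        r2 = (w * x[None, :] * z).sum(axis=1)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new_b0 = (a22 * r1 - a12 * r2) / det
        new_b1 = (a11 * r2 - a12 * r1) / det
        new_b0 = np.clip(np.nan_to_num(new_b0, nan=0.0), -_BETA_CLIP, _BETA_CLIP)
        new_b1 = np.clip(np.nan_to_num(new_b1, nan=0.0), -_BETA_CLIP, _BETA_CLIP)
        delta = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0 = np.where(active, new_b0, b0)
        b1 = np.where(active, new_b1, b1)
        active = active & (delta > _IRLS_TOL)
    converged = ~active
    return b0, b1, converged


def nb_wald_test(
    matrix: CountMatrix,
    size_factors: SizeFactors,
    dispersion: pd.Series,
    control: str,
    mutant: str,
) -> pd.DataFrame:
    """Per-feature NB Wald test of mutant vs control.

    Returns a data frame indexed by feature id with columns baseMean,
    log2fc, se, p, converged. Features with all-zero counts in both
    groups return the null result (log2fc 0, p 1); non-converged fits
    are flagged and also return p = 1.
    """
    groups = matrix.meta["strain"]
    lib_ctrl = matrix.libraries_of_strain(control)
    lib_mut = matrix.libraries_of_strain(mutant)
    if not lib_ctrl or not lib_mut:
        raise ValueError(f"missing libraries for contrast {mutant} vs {control}")
    libs = lib_ctrl + lib_mut
    y = matrix.counts[libs].to_numpy(dtype=float)
    x = np.array([0] * len(lib_ctrl) + [1] * len(lib_mut), dtype=float)
    s = size_factors.factors.loc[libs].to_numpy(dtype=float)
    log_s = np.log(s)
    alpha = dispersion.loc[matrix.feature_ids].to_numpy(dtype=float)

    all_zero = (y == 0).all(axis=1)
    b0, b1, converged = _nb_irls(y, x, log_s, alpha)

    eta = b0[:, None] + b1[:, None] * x[None, :] + log_s[None, :]
    mu = np.exp(np.clip(eta, -700, 700))
    w = mu / (1.0 + alpha[:, None] * mu)
    a11 = w.sum(axis=1)
    a12 = (w * x[None, :]).sum(axis=1)
    det = a11 * a12 - a12 * a12  # a22 == a12 for 0/1 x
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = a11 / det
    se = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    zstat = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    p = np.where(np.isfinite(p), p, 1.0)

    log2fc = b1 / math.log(2.0)
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.where(all_zero | ~converged, 1.0, p)
    if (~converged).any():
        logger.warning("%d features did not converge; p set to 1",
                       int((~converged).sum()))
    base_mean = (y / s[None, :]).mean(axis=1)
    se_out = np.where(all_zero, np.nan, se / math.log(2.0))
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se_out,  # on the log2 scale, like log2fc
            "p": np.clip(p, 0.0, 1.0),
            "converged": converged,
        },
        index=matrix.feature_ids,
    )


def bh_adjust(pvalues: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr if not isinstance(pvalues, pd.Series) else pvalues.copy()
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values outside [0, 1]")
    padj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(padj, index=pvalues.index)
    return padj


def classify_de(
    results: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Status per feature: up / down / ns.

    A feature is up when log2fc >= +lfc_threshold and padj < alpha, down
    when log2fc <= -lfc_threshold and padj < alpha (the fold-change
    boundary is inclusive). Requires columns log2fc and padj.
    """
    sig = results["padj"] < alpha
    status = pd.Series("ns", index=results.index, dtype=object)
    status[sig & (results["log2fc"] >= lfc_threshold)] = "up"
    status[sig & (results["log2fc"] <= -lfc_threshold)] = "down"
    return status


def de_analysis(
    matrix: CountMatrix,
    control: str,
    mutant: str,
    filter_spec: FilterSpec | None = None,
    size_factors: SizeFactors | None = None,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Full gene-level differential expression for one contrast.

    Filters low-expression features, estimates (or reuses) size factors
    and dispersions, runs the NB Wald test and BH adjustment, and
    classifies. Filtered features appear with status 'filtered' and NaN
    statistics.
    """
    kept, removed = low_count_filter(matrix, filter_spec)
    sub = matrix.subset_features(kept)
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(sub)
    disp = estimate_dispersion(sub, size_factors, sub.meta["strain"])
    res = nb_wald_test(sub, size_factors, disp, control, mutant)
    res["padj"] = bh_adjust(res["p"])
    res["dispersion"] = disp
    res["status"] = classify_de(res, lfc_threshold, alpha)
    if removed:
        filt = pd.DataFrame(
            {
                "baseMean": np.nan, "log2fc": np.nan, "se": np.nan,
                "p": np.nan, "converged": True, "padj": np.nan,
                "dispersion": np.nan, "status": "filtered",
            },
            index=pd.Index(removed),
        )
        res = pd.concat([res, filt])
    res.index.name = "feature_id"
    return res.loc[[f for f in matrix.feature_ids]]
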