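"""Reliability statistics: one-way random ICC(1,1), AUC, paired tests.

The intraclass correlation used throughout treats patients as subjects and
perturbations as raters:

    ICC(1,1) = (MS_R - MS_W) / (MS_R + (k - 1) MS_W)

with ``MS_R`` the between-subject (rows) mean square, ``MS_W`` the residual
within-subject mean square and ``k`` the number of raters.  Values can be
negative when rater noise dominates; they are reported raw, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ICCReport",
    "icc_1_1",
    "icc_matrix",
    "feature_icc_table",
    "auc",
    "generalizability_gap",
    "paired_ttest",
]


@dataclass(frozen=True)
class ICCReport:
    """ICC(1,1) estimate together with its ANOVA mean squares."""

    icc: float
    ms_r: float
    ms_w: float
    n: int
    k: int
    ci95: tuple[float, float] | None = None


def _anova_mean_squares(m: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA mean squares for a subjects x raters matrix."""
    n, k = m.shape
    row_means = m.mean(axis=1)
    grand = m.mean()
    ss_r = k * float(((row_means - grand) ** 2).sum())
    ss_w = float(((m - row_means[:, None]) ** 2).sum())
    ms_r = ss_r / (n - 1)
    ms_w = ss_w / (n * (k - 1))
    return ms_r, ms_w


def icc_1_1(m: np.ndarray, ci: bool = False) -> ICCReport:
    """One-way random, single-rater intraclass correlation.

    Parameters
    ----------
    m
        Ratings matrix, subjects (patients) x raters (perturbations); at least
        2 subjects and 2 raters, no missing cells.
    ci
        If True, also compute the standard F-distribution 95% confidence
        interval (reporting only).

    Raises
    ------
    ValueError
        If the matrix is too small, contains non-finite cells, or has zero
        total variance (all cells equal), where the ICC is undefined.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"ratings matrix must be >= 2x2, got {m.shape}")
    if not np.isfinite(m).all():
        raise ValueError("ratings matrix contains non-finite cells")
    n, k = m.shape
    ms_r, ms_w = _anova_mean_squares(m)
    denom = ms_r + (k - 1) * ms_w
    if denom == 0.0:
        raise ValueError("ICC undefined: zero total variance (all cells equal)")
    icc = (ms_r - ms_w) / denom
    interval = None
    if ci:
        # Standard one-way interval via the F ratio (Shrout & Fleiss).
        if ms_w > 0:
            f_obs = ms_r / ms_w
            f_upper = sps.f.ppf(0.975, n - 1, n * (k - 1))
            f_lower = sps.f.ppf(0.025, n - 1, n * (k - 1))
            fl, fu = f_obs / f_upper, f_obs / f_lower
            interval = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        else:
            interval = (1.0, 1.0)
    return ICCReport(icc=float(icc), ms_r=ms_r, ms_w=ms_w, n=n, k=k, ci95=interval)


def icc_matrix(data: np.ndarray) -> np.ndarray:
    """Vectorised ICC(1,1) over a stack of ratings matrices.

    Parameters
    ----------
    data
        Array of shape ``(n_subjects, k_raters, n_features)``.

    Returns
    -------
    Array of ``n_features`` ICC values; NaN where the ICC is undefined
    (zero total variance for that feature).
    """
    data = np.asarray(data, dtype=float)
    n, k, _ = data.shape
    row_means = data.mean(axis=1)  # (n, f)
    grand = data.mean(axis=(0, 1))  # (f,)
    ms_r = k * ((row_means - grand) ** 2).sum(axis=0) / (n - 1)
    ms_w = ((data - row_means[:, None, :]) ** 2).sum(axis=(0, 1)) / (n * (k - 1))
    denom = ms_r + (k - 1) * ms_w
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (ms_r - ms_w) / denom, np.nan)
    bad = ~np.isfinite(data).all(axis=(0, 1))
    icc[bad] = np.nan
    return icc


def feature_icc_table(replicates: np.ndarray | dict[str, np.ndarray],
                      feature_names: list[str] | None = None) -> pd.Series:
    """Per-feature ICC(1,1) across perturbation replicates.

    Parameters
    ----------
    replicates
        Either an array ``(n_subjects, k_raters, n_features)`` (with
        ``feature_names`` giving the last-axis labels), or a mapping from
        feature name to its own subjects x raters matrix.

    Returns
    -------
    Series indexed by feature name.  Features whose ICC is undefined carry
    NaN and are treated as non-robust by the downstream filter.
    """
    if isinstance(replicates, dict):
        names = list(replicates)
        stack = np.stack([np.asarray(replicates[f], dtype=float) for f in names],
                         axis=-1)
    else:
        stack = np.asarray(replicates, dtype=float)
        names = (feature_names if feature_names is not None
                 else [f"f{i}" for i in range(stack.shape[-1])])
        if len(names) != stack.shape[-1]:
            raise ValueError("feature_names length does not match data")
    return pd.Series(icc_matrix(stack), index=names, name="icc")


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    The probability that a random positive outranks a random negative, with
    ties counted one half (midranks).  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = sps.rankdata(scores)  # midranks handle ties
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def generalizability_gap(train_auc: float, test_auc: float) -> float:
    """Test-minus-train AUC; negative when the model degrades on test data."""
    for v, name in ((train_auc, "train_auc"), (test_auc, "test_auc")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return float(test_auc) - float(train_auc)


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on ``a - b``.

    Raises on fewer than 3 pairs or zero-variance differences (the t statistic
    is undefined there).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t-test needs two equal-length vectors")
    if a.size < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    d = a - b
    if np.allclose(d.var(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)
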