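"""Feature robustness filtering and two-step feature selection.

Selection follows the filter-based protocol: (1) rank features by how often
their one-way ANOVA p-value against the outcome falls below 0.1 across 100
class-balancing downsample bootstraps, keep the top 10%; (2) among each pair
of features with |Pearson r| above 0.6, drop the member with the higher mean
absolute correlation to the remaining features; cap the final list at 10.
An mRMR selector is provided as the bias-check alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "robustness_filter",
    "bootstrap_anova_rank",
    "prune_correlated",
    "mrmr_select",
]


class EmptySurvivorError(ValueError):
    """No feature survives the robustness filter at the given threshold."""


def robustness_filter(icc_table: pd.Series, threshold: float) -> list[str]:
    """Features with ICC strictly above ``threshold``, sorted by name.

    Undefined (NaN) ICCs count as non-robust.  Raises if nothing survives.
    """
    if len(icc_table) == 0:
        raise ValueError("empty ICC table")
    keep = icc_table[icc_table > threshold]
    if keep.empty:
        raise EmptySurvivorError(
            f"no features with ICC > {threshold}")
    return sorted(keep.index)


def _anova_p_two_group(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised one-way ANOVA p-values, one per column, two groups.

    Equivalent to the F-test from a standard one-way ANOVA; columns with
    zero within+between variance return NaN.
    """
    from scipy import stats as sps
    g0, g1 = x[y == 0], x[y == 1]
    n0, n1 = len(g0), len(g1)
    m0, m1 = g0.mean(axis=0), g1.mean(axis=0)
    grand = x.mean(axis=0)
    ss_b = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ss_w = ((g0 - m0) ** 2).sum(axis=0) + ((g1 - m1) ** 2).sum(axis=0)
    df_b, df_w = 1, n0 + n1 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_b / df_b) / (ss_w / df_w)
    p = sps.f.sf(f, df_b, df_w)
    p[~np.isfinite(f)] = np.nan
    return p


def bootstrap_anova_rank(features: pd.DataFrame, labels: pd.Series,
                         n_iter: int = 100, p_cut: float = 0.1,
                         top_frac: float = 0.1,
                         seed: int = 0) -> pd.DataFrame:
    """Rank features by ANOVA hit frequency under downsample bootstrapping.

    Each iteration draws, without replacement, a majority-class subsample of
    the minority-class size (class balancing), computes each feature's
    one-way ANOVA p-value against the outcome, and records a hit when
    ``p < p_cut``.  Returns the top ``ceil(top_frac * n_features)`` features
    by hit frequency (ties broken by mean p-value, then name), as a
    DataFrame with columns ``frequency`` and ``mean_p`` sorted by rank.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y = labels.loc[features.index].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("minority class must have at least 2 members")
    # with perfectly balanced classes, argmin == argmax; break the tie
    if counts[0] <= counts[1]:
        minority, majority = classes[0], classes[1]
    else:
        minority, majority = classes[1], classes[0]
    n_min = counts.min()
    idx_min = np.flatnonzero(y == minority)
    idx_maj = np.flatnonzero(y == majority)

    x = features.to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA404A]))
    hits = np.zeros(x.shape[1], dtype=int)
    p_sum = np.zeros(x.shape[1])
    p_count = np.zeros(x.shape[1], dtype=int)
    for _ in range(n_iter):
        take = rng.choice(idx_maj, size=n_min, replace=False)
        sel = np.concatenate([idx_min, take])
        p = _anova_p_two_group(x[sel], (y[sel] == minority).astype(int))
        ok = np.isfinite(p)
        hits += ok & (p < p_cut)
        p_sum[ok] += p[ok]
        p_count[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_p = np.where(p_count > 0, p_sum / np.maximum(p_count, 1), np.inf)

    table = pd.DataFrame({"frequency": hits, "mean_p": mean_p,
                          "_name": features.columns},
                         index=features.columns)
    table = table.sort_values(["frequency", "mean_p", "_name"],
                              ascending=[False, True, True],
                              kind="stable").drop(columns="_name")
    n_top = int(np.ceil(top_frac * features.shape[1]))
    return table.head(max(n_top, 1))


def prune_correlated(features: pd.DataFrame, ranked: list[str],
                     r_cut: float = 0.6, k_max: int = 10) -> list[str]:
    """Drop the more-redundant member of each highly correlated pair.

    Iteratively, among all pairs of surviving features with ``|r| > r_cut``,
    the member with the higher mean absolute correlation to all remaining
    features is removed; the survivors are then capped at ``k_max`` in the
    supplied rank order.
    """
    ranked = [f for f in ranked if f in features.columns]
    if not ranked:
        return []
    cols = list(ranked)
    corr = features[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or (sub <= r_cut).all():
            break
        mean_corr = np.full(len(cols), -np.inf)
        live_idx = np.flatnonzero(alive)
        means = sub.sum(axis=1) / max(len(live_idx) - 1, 1)
        # candidates: members of at least one offending pair
        offenders = (sub > r_cut).any(axis=1)
        cand = live_idx[offenders]
        mean_corr[cand] = means[offenders]
        drop = int(cand[np.argmax(mean_corr[cand])])
        alive[drop] = False
    survivors = [c for c, a in zip(cols, alive) if a]
    return survivors[:k_max]


def mrmr_select(features: pd.DataFrame, labels: pd.Series,
                k: int = 10) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance feature selection.

    Relevance is the one-way ANOVA F statistic against the binary outcome,
    mapped to the correlation scale as sqrt(F / (F + dof)) (the point-
    biserial |r|) so it is commensurable with the redundancy term, the mean
    absolute Pearson correlation to the already selected set.  The first
    pick maximizes relevance; subsequent picks maximize relevance minus
    redundancy.  Ties break by column order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    k = min(k, features.shape[1])
    y = labels.loc[features.index].to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    x = features.to_numpy(dtype=float)
    g0, g1 = x[y == 0], x[y == 1]
    n0, n1 = len(g0), len(g1)
    m0, m1 = g0.mean(axis=0), g1.mean(axis=0)
    grand = x.mean(axis=0)
    ss_b = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ss_w = ((g0 - m0) ** 2).sum(axis=0) + ((g1 - m1) ** 2).sum(axis=0)
    dof = max(n0 + n1 - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_b / 1.0) / (ss_w / dof)
        relevance = np.sqrt(f_stat / (f_stat + dof))
    relevance = np.nan_to_num(relevance, nan=0.0, posinf=1.0)

    corr = np.abs(np.corrcoef(x, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    selected: list[int] = []
    remaining = list(range(x.shape[1]))
    while len(selected) < k:
        if not selected:
            scores = relevance[remaining]
        else:
            red = corr[np.ix_(remaining, selected)].mean(axis=1)
            scores = relevance[remaining] - red
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
    return [features.columns[i] for i in selected]
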