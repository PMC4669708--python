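"""Competition-specificity scoring of protein groups.

Specific drug binders are separated from bead-matrix background by a
quantile-based competition statistic.  For each of three abundance
measures — spectral counts and the two engine protein scores — every
value is first replaced by its mid-rank quantile within the
condition-wide empirical distribution across all groups, which makes the
test invariant to any strictly monotone transform of the measure.  A
one-sided permutation test on the condition labels of each group's
quantile values (statistic: mean non-competed quantile minus mean
competed quantile) yields a measure-specific P-value; the three
P-values are combined by Fisher's method (chi-square with 6 degrees of
freedom).  Groups with combined P below the significance threshold
(default 0.05) are called specific binders.

The magnitude of competition is summarized separately as the fold
reduction: the ratio of median spectral counts with versus without
competition (four replicate counts per condition enter each median), and
its complement as percent reduction.  Bubble-plot exports place combined
P on the x-axis, percent reduction on the y-axis, and scale bubbles by
the mean non-competed spectral count.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_transform",
    "measure_pvalue",
    "fisher_combine",
    "fold_reduction",
    "TargetScorer",
    "score_targets",
    "plot_targets",
]

MEASURES = ("spectral_count", "score_a", "score_b")
CONDITIONS = ("non_competed", "competed")


def quantile_transform(values) -> np.ndarray:
    """Mid-rank quantiles of ``values`` within their own empirical distribution.

    Each value maps to ``(rank - 0.5) / n`` with ties receiving averaged
    ranks, so results lie in (0, 1) and all-equal inputs map to 0.5.
    Any strictly monotone transform of the input leaves the output
    unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("quantile transform needs at least 2 values")
    ranks = stats.rankdata(values, method="average")
    return (ranks - 0.5) / values.size


def measure_pvalue(q_non_competed, q_competed, n_permutations: int = 10000,
                   max_exhaustive: int = 12, seed: int = 0) -> float:
    """One-sided permutation P-value for reduction under competition.

    The statistic is mean(non-competed quantiles) - mean(competed
    quantiles).  Condition labels are permuted exhaustively when the
    total number of replicates is at most ``max_exhaustive`` (all
    C(n, n_nc) assignments), otherwise by ``n_permutations`` seeded
    Monte-Carlo draws.  In both cases

        P = (#permutations with statistic >= observed + 1) / (#permutations + 1),

    so P is never 0 and identical quantile vectors give P = 1 under
    exhaustive enumeration.
    """
    q_nc = np.asarray(q_non_competed, dtype=float)
    q_c = np.asarray(q_competed, dtype=float)
    if q_nc.size == 0 or q_c.size == 0:
        raise ValueError("both conditions need at least one replicate")
    pooled = np.concatenate([q_nc, q_c])
    n, k = pooled.size, q_nc.size
    observed = q_nc.mean() - q_c.mean()
    tol = 1e-12  # floating-point ties count as >=
    if n <= max_exhaustive:
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), k):
            take = pooled[list(idx)]
            rest_sum = pooled.sum() - take.sum()
            stat = take.mean() - rest_sum / (n - k)
            if stat >= observed - tol:
                count += 1
            total += 1
        return (count + 1) / (total + 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = perm[:k].mean() - perm[k:].mean()
        if stat >= observed - tol:
            count += 1
    return (count + 1) / (n_permutations + 1)


def fisher_combine(*pvalues) -> float:
    """Fisher's method: combine P-values via chi-square with 2m d.f.

    With the three measure P-values this is the upper chi-square(6) tail
    of ``-2 * sum(log p)``.  Inputs must lie in (0, 1]; the permutation
    convention guarantees no exact zeros.
    """
    ps = np.asarray(pvalues, dtype=float)
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("P-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(ps))
    return float(stats.chi2.sf(x, df=2 * ps.size))


def fold_reduction(counts_competed, counts_non_competed):
    """Median-count competition summary.

    Returns ``(ratio, percent_reduction, bubble_size)`` with
    ``ratio = median(competed) / median(non-competed)``,
    ``percent_reduction = 100 * (1 - ratio)`` and ``bubble_size`` the
    mean non-competed count.  With four counts per condition the median
    is the mean of the middle two.  A zero non-competed median makes the
    ratio undefined (NaN) — such groups are excluded from bubble plots.
    """
    c = np.asarray(counts_competed, dtype=float)
    nc = np.asarray(counts_non_competed, dtype=float)
    med_nc = float(np.median(nc))
    bubble = float(np.mean(nc))
    if med_nc == 0:
        return float("nan"), float("nan"), bubble
    ratio = float(np.median(c)) / med_nc
    return ratio, 100.0 * (1.0 - ratio), bubble


class TargetScorer(BaseEstimator, TransformerMixin):
    """Quantile/permutation/Fisher competition-specificity scorer.

    Consumes the long-form profile table produced by protein inference
    (columns ``group_id, condition, replicate, spectral_count, score_a,
    score_b``) and emits one row per group with the three measure
    P-values, the Fisher-combined P-value, fold-reduction summaries and
    the specific-binder flag (``p_combined < alpha``).

    Missing cells are filled before scoring: absent spectral counts
    become 0 (absence under competition is evidence), absent engine
    scores take the condition-minimum quantile.  ``min_attainable_p``
    reports the permutation-grid floor ``2 / (n_permutations + 1)`` so
    the granularity of small-replicate designs stays visible.

    Parameters
    ----------
    alpha : float
        Combined-P threshold for the specific flag.
    max_exhaustive : int
        Largest total replicate number for exhaustive label enumeration.
    n_permutations : int
        Monte-Carlo permutations above that size.
    random_state : int
        Seed for Monte-Carlo permutations.
    """

    def __init__(self, alpha: float = 0.05, max_exhaustive: int = 12,
                 n_permutations: int = 10000, random_state: int = 0):
        self.alpha = alpha
        self.max_exhaustive = max_exhaustive
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self._score(X)

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self._score(X)

    def _score(self, profiles: pd.DataFrame) -> pd.DataFrame:
        groups = sorted(profiles["group_id"].unique())
        if len(groups) < 2:
            raise ValueError("scoring needs at least 2 groups to define quantiles")
        replicates = sorted(profiles["replicate"].unique())
        grid = pd.MultiIndex.from_product([groups, CONDITIONS, replicates],
                                          names=["group_id", "condition", "replicate"])
        full = profiles.set_index(["group_id", "condition", "replicate"]).reindex(grid)
        full["spectral_count"] = full["spectral_count"].fillna(0)
        full = full.reset_index()

        # condition-wide quantiles per measure over the complete grid;
        # absent counts are zero (absence is evidence), absent scores take
        # the condition-minimum value, i.e. the condition-minimum quantile
        for measure in MEASURES:
            qcol = f"q_{measure}"
            full[qcol] = np.nan
            for cond in CONDITIONS:
                mask = full["condition"] == cond
                vals = full.loc[mask, measure].astype(float)
                if vals.isna().any():
                    fill = vals.min() if vals.notna().any() else 0.0
                    vals = vals.fillna(fill)
                full.loc[mask, qcol] = quantile_transform(vals.to_numpy())

        rows = []
        n_total = 2 * len(replicates)
        if n_total <= self.max_exhaustive:
            n_perm = math.comb(n_total, len(replicates))
        else:
            n_perm = self.n_permutations
        min_p = 2.0 / (n_perm + 1)
        for gid, grp in full.groupby("group_id", sort=True):
            nc = grp[grp["condition"] == "non_competed"]
            c = grp[grp["condition"] == "competed"]
            pvals = {}
            for measure in MEASURES:
                pvals[measure] = measure_pvalue(
                    nc[f"q_{measure}"].to_numpy(), c[f"q_{measure}"].to_numpy(),
                    n_permutations=self.n_permutations,
                    max_exhaustive=self.max_exhaustive, seed=self.random_state,
                )
            p_comb = fisher_combine(*pvals.values())
            ratio, reduction, bubble = fold_reduction(
                c["spectral_count"].to_numpy(), nc["spectral_count"].to_numpy()
            )
            if math.isnan(ratio):
                logger.info("group %s: non-competed median count is 0; "
                            "fold reduction undefined, excluded from bubble plot", gid)
            rows.append((gid, pvals["score_a"], pvals["score_b"], pvals["spectral_count"],
                         p_comb, ratio, reduction, bubble, p_comb < self.alpha, min_p))
        return pd.DataFrame(rows, columns=[
            "group_id", "p_score_a", "p_score_b", "p_counts", "p_combined",
            "fold_reduction_ratio", "percent_reduction", "bubble_size",
            "specific", "min_attainable_p",
        ])


def score_targets(profiles: pd.DataFrame, alpha: float = 0.05, seed: int = 0,
                  **kwargs) -> pd.DataFrame:
    """Score every protein group's competition specificity.

    Thin wrapper over :class:`TargetScorer`; see its docstring for the
    statistic and output columns.
    """
    return TargetScorer(alpha=alpha, random_state=seed, **kwargs).fit_transform(profiles)


def plot_targets(scores: pd.DataFrame, path: str, alpha: float = 0.05,
                 label_specific: bool = True):
    """Bubble plot of combined P (x, log scale) vs percent reduction (y).

    Bubble area scales with the mean non-competed spectral count; the
    dashed line marks the significance threshold.  Groups with an
    undefined fold reduction are omitted.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = scores.dropna(subset=["percent_reduction"])
    fig, ax = plt.subplots(figsize=(7, 5))
    sizes = 20.0 + 8.0 * ok["bubble_size"]
    colors = np.where(ok["specific"], "#c0392b", "#7f8c8d")
    ax.scatter(ok["p_combined"], ok["percent_reduction"], s=sizes, c=colors, alpha=0.6,
               edgecolors="k", linewidths=0.4)
    ax.axvline(alpha, linestyle="--", color="k", linewidth=1)
    ax.set_xscale("log")
    ax.invert_xaxis()
    ax.set_xlabel("combined P-value (Fisher, quantile permutation)")
    ax.set_ylabel("reduction in spectral counts upon competition (%)")
    if label_specific:
        for _, row in ok[ok["specific"]].iterrows():
            ax.annotate(str(row["group_id"]), (row["p_combined"], row["percent_reduction"]),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
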