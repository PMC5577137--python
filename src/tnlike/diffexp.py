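"""SAM-style permutation differential expression and subtype labelling.

The d statistic is a moderated two-sample t: the mean difference divided by
the pooled standard error plus a fudge factor s0 chosen to stabilise the
coefficient of variation of |d| across the spread of standard errors.
Significance is assessed by permuting sample labels: the false discovery
rate at a cut-off delta is

    FDR(delta) = pi0 * median_perm #{|d_perm| >= delta} / #{|d_obs| >= delta}

with pi0 estimated from the fraction of observed d falling inside the
central 50% of the permuted null.  Per-feature q-values are the smallest
FDR at which the feature is called.

Samples are then clustered on the selected features (1 - Pearson r
distance, average linkage, two-cluster cut at the dendrogram root) and ER+
tumours that co-cluster with the TNBC majority are labelled TN-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "DeResult",
    "sam_d",
    "choose_s0",
    "sam_fdr",
    "cluster_average_pearson",
    "label_tn_like",
]


@dataclass
class DeResult:
    """Per-feature SAM statistics and the permutation settings that made them."""

    table: pd.DataFrame          # columns: d_statistic, mean_diff, pooled_se, q_value
    s0: float
    delta: float                 # smallest |d| among selected features (inf if none)
    n_permutations: int
    fdr_cut: float
    pi0: float
    seed: int | None = None

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["q_value"] < self.fdr_cut]


def _pooled_se(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    ss = np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
    return float(np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2)))


def sam_d(x, y, s0: float = 0.0) -> float:
    """Moderated d = (mean(x) - mean(y)) / (pooled SE + s0).

    With s0 = 0 this is the ordinary equal-variance two-sample t statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 samples")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    s = _pooled_se(x, y)
    num = x.mean() - y.mean()
    if s + s0 == 0:
        return 0.0 if num == 0 else float(np.sign(num)) * np.inf
    return float(num / (s + s0))


def choose_s0(s: np.ndarray, r: np.ndarray, n_windows: int = 10) -> float:
    """Pick the fudge factor s0.

    Candidates are percentiles 0, 5, ..., 100 of the per-feature standard
    errors ``s``; chosen is the candidate minimising the coefficient of
    variation of the median |d| across ``n_windows`` s-quantile windows
    (``r`` holds the per-feature mean differences).
    """
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    if len(s) < 20:
        raise ValueError("need >= 20 features to tune s0")
    if np.allclose(s, s[0]):
        return 0.0
    # window assignment by s rank
    order = np.argsort(s, kind="stable")
    win = np.empty(len(s), dtype=int)
    win[order] = np.minimum((np.arange(len(s)) * n_windows) // len(s), n_windows - 1)

    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(s + s0 > 0, r / (s + s0), 0.0)
        med = np.array([np.median(np.abs(d[win == j])) for j in range(n_windows)])
        m = med.mean()
        if m == 0:
            continue
        cv = med.std(ddof=0) / m
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _d_for_masks(x: np.ndarray, x2: np.ndarray, masks: np.ndarray, s0: float):
    """Vectorised d statistics.

    ``masks`` is (n_arrangements, n_samples) boolean, True = group 1.
    Returns (d, r, s) each of shape (n_features, n_arrangements).
    """
    n = x.shape[1]
    n1 = masks.sum(axis=1).astype(float)
    n2 = n - n1
    m1 = x @ masks.T / n1
    m2 = x @ (~masks).T / n2
    ss1 = x2 @ masks.T - n1 * m1**2
    ss2 = x2 @ (~masks).T - n2 * m2**2
    se = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n - 2))
    r = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(se + s0 > 0, r / (se + s0), 0.0)
    return d, r, se


def sam_fdr(
    matrix: pd.DataFrame,
    labels,
    n_perm: int = 1000,
    fdr_cut: float = 0.05,
    seed: int | None = None,
    s0: float | None = None,
) -> DeResult:
    """Two-class SAM with permutation FDR and per-feature q-values.

    If fewer distinct label arrangements than ``n_perm`` exist they are
    enumerated exactly, making the result deterministic given the data.
    """
    labels = pd.Series(np.asarray(labels), index=matrix.columns)
    levels = labels.unique()
    if len(levels) != 2:
        raise ValueError("exactly two label levels required")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: FDR estimates will be coarse")

    x = matrix.to_numpy(dtype=float)
    x2 = x**2
    n = x.shape[1]
    obs_mask = (labels == levels[0]).to_numpy()[None, :]
    d_obs, r_obs, se_obs = (a[:, 0] for a in _d_for_masks(x, x2, obs_mask, 0.0))

    if s0 is None:
        s0 = choose_s0(se_obs, r_obs) if len(se_obs) >= 20 else 0.0
    d_obs = np.where(se_obs + s0 > 0, r_obs / (se_obs + s0), 0.0)

    n1 = int(obs_mask.sum())
    n_distinct = comb(n, n1)
    rng = np.random.default_rng(seed)
    if n_distinct <= n_perm:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for k, idx in enumerate(combinations(range(n), n1)):
            masks[k, list(idx)] = True
        n_perm = n_distinct
    else:
        masks = np.zeros((n_perm, n), dtype=bool)
        for k in range(n_perm):
            masks[k, rng.choice(n, n1, replace=False)] = True
    d_perm, _, _ = _d_for_masks(x, x2, masks, s0)

    # pi0 from the central 50% of the permuted null
    q25, q75 = np.percentile(d_perm, [25, 75])
    pi0 = min(1.0, np.mean((d_obs > q25) & (d_obs < q75)) / 0.5)

    abs_obs = np.abs(d_obs)
    abs_perm_sorted = np.sort(np.abs(d_perm), axis=0)
    m = len(abs_obs)
    # counts beyond each candidate delta (= each observed |d|)
    obs_sorted = np.sort(abs_obs)
    obs_count = m - np.searchsorted(obs_sorted, abs_obs, side="left")
    perm_counts = m - np.stack(
        [np.searchsorted(abs_perm_sorted[:, k], abs_obs, side="left")
         for k in range(d_perm.shape[1])]
    )
    med_perm_count = np.median(perm_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_at = np.where(obs_count > 0, pi0 * med_perm_count / obs_count, 1.0)
    fdr_at = np.clip(fdr_at, 0.0, 1.0)

    # q = smallest FDR over thresholds the feature passes (monotone in |d|)
    order = np.argsort(abs_obs, kind="stable")
    q = np.empty(m)
    running = np.minimum.accumulate(fdr_at[order])
    q[order] = running
    q[abs_obs == 0] = 1.0

    table = pd.DataFrame(
        {
            "d_statistic": d_obs,
            "mean_diff": r_obs,
            "pooled_se": se_obs,
            "q_value": q,
        },
        index=matrix.index,
    )
    sel = table.index[q < fdr_cut]
    delta = float(np.min(abs_obs[q < fdr_cut])) if len(sel) else np.inf
    return DeResult(
        table=table,
        s0=float(s0),
        delta=delta,
        n_permutations=int(d_perm.shape[1]),
        fdr_cut=fdr_cut,
        pi0=float(pi0),
        seed=seed,
    )


def cluster_average_pearson(matrix: pd.DataFrame):
    """Cluster samples with 1 - Pearson r distance and average linkage.

    Returns ``(linkage_matrix, labels)`` where labels is a per-sample
    Series of cluster ids {1, 2} from cutting the dendrogram at the root.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 features and >= 2 samples")
    x = matrix.to_numpy(dtype=float)
    if np.any(x.std(axis=0) == 0):
        raise ValueError("zero-variance sample profile")
    corr = np.corrcoef(x, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=2, criterion="maxclust")
    return link, pd.Series(labels, index=matrix.columns, name="cluster")


def label_tn_like(cluster_labels: pd.Series, receptor_status: pd.Series) -> pd.Series:
    """Assign ER-true / TN-like / TNBC subtypes from a two-cluster cut.

    The cluster holding the majority of TNBC (``"ER-"``) samples is
    "cluster II"; ER+ samples falling in it are TN-like, the rest ER-true.
    A tie in the TNBC majority is an error requiring manual assignment.
    """
    receptor_status = receptor_status.reindex(cluster_labels.index)
    is_tnbc = receptor_status.isin(["ER-", "TNBC"])
    if not is_tnbc.any():
        raise ValueError("no TNBC samples; cannot orient clusters")
    counts = cluster_labels[is_tnbc].value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        raise ValueError("TNBC samples split evenly; manual cluster assignment needed")
    cluster_ii = counts.index[0]
    out = pd.Series(
        np.where(
            is_tnbc, "TNBC",
            np.where(cluster_labels == cluster_ii, "TN-like", "ER-true"),
        ),
        index=cluster_labels.index,
        name="subtype",
    )
    return out
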