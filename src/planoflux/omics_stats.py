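"""Time-course omics statistics: TPM, ANOVA+BH, trend clustering, iGA.

The analysis chain for a genes × samples count matrix over a fermentation
time course (five sampling times, three replicates):

1. TPM (transcripts per million): length-normalized abundances summing to
   1e6 per sample.
2. Differential expression: one-way fixed-effects ANOVA across time points
   on log-transformed normalized values, Benjamini-Hochberg adjusted,
   selected at FDR 5% (metabolite intensities add a max |log2 FC| > 1
   requirement).
3. Trend clustering: per-feature z-scored time-point means, k-means into
   eight clusters relabeled A..H by centroid peak time.
4. iGA (iterative Group Analysis): for a functional group inside a ranked
   gene list, the PC-value (probability of change) is the minimum over the
   group members' ranks t of the hypergeometric tail
   P(X >= x_t), X ~ Hypergeom(N, K, t), where x_t is the number of members
   at rank <= t.  Computed in log space so values like 1e-92 are exact to
   working precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedGroup",
    "ClusterResult",
    "compute_tpm",
    "log_normalize",
    "detected_features",
    "anova_bh",
    "de_filter",
    "kmeans_trends",
    "iga_pc",
]


# ---------------------------------------------------------------------------
# TPM and normalization
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from raw counts and feature lengths (bp).

    Per sample: rate_i = count_i / length_i, TPM_i = 1e6 rate_i / sum(rate).
    An all-zero sample stays all-zero.  Invariant to scaling a sample's
    counts by a constant.
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every feature needs a length")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    total = total.replace(0.0, np.nan)  # all-zero sample -> 0/NaN -> 0
    return (rate.div(total, axis=1) * 1e6).fillna(0.0)


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features positive in all samples)."""
    arr = counts.to_numpy(dtype=float)
    mask = (arr > 0).all(axis=1)
    if not mask.any():
        return pd.Series(1.0, index=counts.columns)
    log_geo = np.log(arr[mask]).mean(axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(arr[mask]) - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns)


def log_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(count / size_factor + 1) with median-of-ratios size factors.

    A variance-stabilizing log transform of library-size-normalized counts,
    used as the ANOVA response for count data.
    """
    sf = _size_factors(counts)
    return np.log2(counts.div(sf, axis=1) + 1.0)


def detected_features(
    tpm: pd.DataFrame, groups: pd.Series | None = None, threshold: float = 5.0
) -> pd.Series:
    """Features whose (per-time-point mean) expression exceeds ``threshold`` TPM
    at one or more time points."""
    if groups is not None:
        means = tpm.T.groupby(groups.to_numpy()).mean().T
    else:
        means = tpm
    return means.max(axis=1) > threshold


# ---------------------------------------------------------------------------
# ANOVA + Benjamini-Hochberg
# ---------------------------------------------------------------------------

def anova_bh(
    matrix: pd.DataFrame, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per feature with BH FDR control.

    ``groups`` labels each sample column with its time point; at least two
    groups with two replicates each are required.  Features constant across
    all samples get p = 1 (no evidence of change) so the BH denominator is
    stable.  Returns a frame with columns p, p_adj, significant.
    """
    groups = pd.Series(np.asarray(groups), index=matrix.columns)
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    blocks = [matrix.loc[:, groups[groups == g].index].to_numpy() for g in levels]
    if any(b.shape[1] < 2 for b in blocks):
        raise ValueError("need at least two replicates per group")

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(*blocks, axis=1)

    values = matrix.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    p = np.where(constant, 1.0, p)
    # degenerate non-constant cases (e.g. zero within-group variance) give
    # F = inf -> p = 0, which is a legitimate extreme
    p = np.nan_to_num(p, nan=1.0)

    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"p": p, "p_adj": p_adj, "significant": p_adj < alpha},
        index=matrix.index,
    )


def de_filter(
    adjusted_p: pd.Series,
    profile: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.Series:
    """Select features passing both the FDR gate and a fold-change gate.

    ``profile`` holds per-group means (features × groups).  A feature is
    selected iff p_adj < alpha and the maximum |log2 ratio| over group
    pairs exceeds ``lfc_threshold``.  Zero means are offset by the smallest
    positive value in the profile (pseudo-count) before taking ratios.
    """
    vals = profile.to_numpy(dtype=float)
    positive = vals[vals > 0]
    pseudo = positive.min() if positive.size else 1.0
    shifted = np.where(vals > 0, vals, pseudo)
    log2 = np.log2(shifted)
    max_lfc = log2.max(axis=1) - log2.min(axis=1)
    selected = (adjusted_p.to_numpy() < alpha) & (max_lfc > lfc_threshold)
    return pd.Series(selected, index=profile.index, name="selected")


# ---------------------------------------------------------------------------
# k-means trend clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    assignments: pd.Series          # feature -> letter label
    centroids: pd.DataFrame         # letter × time point, normalized profiles
    k: int
    seed: int
    inertia: float                  # within-cluster sum of squares


def kmeans_trends(
    matrix: pd.DataFrame,
    groups: pd.Series | None = None,
    k: int = 8,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterResult:
    """Cluster temporal trend shapes with k-means into ``k`` groups (A, B, ...).

    Columns are averaged within ``groups`` (time points) first, then each
    feature's profile is z-scored so only the shape matters.  k-means runs
    ``n_init`` k-means++ restarts under ``seed``; clusters are relabeled
    deterministically by the time of their centroid peak (earliest = A),
    ties broken by cluster size (larger first).
    """
    if groups is not None:
        groups = pd.Series(np.asarray(groups), index=matrix.columns)
        means = matrix.T.groupby(groups.to_numpy(), sort=True).mean().T
    else:
        means = matrix.astype(float)
    if k > means.shape[0]:
        raise ValueError(f"k={k} exceeds the {means.shape[0]} features")

    profiles = means.to_numpy(dtype=float)
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (profiles - mu) / sd

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(Z)

    sizes = np.bincount(raw, minlength=k)
    peak = km.cluster_centers_.argmax(axis=1)
    # ties (same peak time, same size) fall back to the profile itself so
    # the ordering depends only on the fitted centroids, not k-means labels
    order = sorted(
        range(k),
        key=lambda c: (
            peak[c], -sizes[c],
            tuple(np.round(-km.cluster_centers_[c], 9)),
        ),
    )
    letters = [chr(ord("A") + i) for i in range(k)]
    relabel = {c: letters[i] for i, c in enumerate(order)}

    assignments = pd.Series(
        [relabel[c] for c in raw], index=means.index, name="cluster"
    )
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=letters, columns=means.columns
    )
    return ClusterResult(
        assignments=assignments, centroids=centroids,
        k=k, seed=seed, inertia=float(km.inertia_),
    )


# ---------------------------------------------------------------------------
# iterative Group Analysis
# ---------------------------------------------------------------------------

@dataclass
class RankedGroup:
    """A ranked feature list with a membership mask (index 0 = best rank)."""

    membership: np.ndarray  # boolean, length n_total

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.ndim != 1:
            raise ValueError("membership must be a 1-D boolean mask")
        if self.group_size == 0:
            raise ValueError("the group must have at least one member")

    @property
    def n_total(self) -> int:
        return int(self.membership.size)

    @property
    def group_size(self) -> int:
        return int(self.membership.sum())


def iga_pc(ranked: RankedGroup) -> float:
    """iGA probability-of-change for a group inside a ranked list.

    PC = min over member-occupied ranks t of P(X >= x_t) where
    X ~ Hypergeometric(N = n_total, K = group_size, n = t) and x_t counts the
    members at rank <= t.  The minimum is taken only at ranks where a member
    sits, and the tail is accumulated from log-gamma terms so extremely
    small values keep full relative precision.
    """
    N, K = ranked.n_total, ranked.group_size
    member_ranks = np.flatnonzero(ranked.membership) + 1  # 1-based cutoffs
    best = np.inf
    for x, t in enumerate(member_ranks, start=1):
        upper = min(K, t)
        ks = np.arange(x, upper + 1)
        log_tail = logsumexp(stats.hypergeom.logpmf(ks, N, K, t))
        best = min(best, log_tail)
    if best > -1e-12:  # certain event up to summation dust
        return 1.0
    return float(np.exp(best))
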