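"""Tuning-curve clustering with leave-one-out consensus ROIs.

Voxels in the release mask are clustered by the shape of their similarity
tuning curve (the 4-vector of betas over SC, C, D, SD, z-scored per voxel).
The number of clusters is chosen by the Calinski-Harabasz index; k-means is
re-run once per leave-one-subject-out fold on the remaining subjects' mean
curves, cluster labels are aligned across folds by centroid matching, and
each held-out subject's curves are extracted from the fold's ROIs (so no
subject contributes to the ROI it is read from).  Consensus cluster masks
keep voxels assigned to a cluster in at least 75% of folds.  Cluster tuning
is compared via per-subject SC-to-SD slopes (paired one-tailed t and
Wilcoxon signed-rank) and per-cluster pairwise deviant contrasts with
Bonferroni correction, after excluding subjects whose grand-mean beta lies
more than 3 SD above the group mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .norms import BIN_LABELS

logger = logging.getLogger(__name__)

RANK_X = np.arange(1.0, 5.0)


@dataclass
class KSelection:
    k: int
    scores: dict[int, float]
    low_confidence: bool  # best/second-best CH ratio < 1.2


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray        # cluster id in {1..k} per voxel
    centroids: np.ndarray     # k x 4 centroid curves
    ch_value: float
    fold: int                 # held-out subject index
    heldout_curves: np.ndarray  # k x 4 mean curves of the held-out subject


def zscore_rows(curves: np.ndarray) -> np.ndarray:
    """Z-score each row (voxel curve) across its 4 conditions; constant rows map to 0."""
    mu = curves.mean(axis=1, keepdims=True)
    sd = curves.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (curves - mu) / sd


def _kmeans(curves: np.ndarray, k: int, seed, n_restarts: int = 20) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(curves)


def select_k_calinski_harabasz(curves: np.ndarray, k_range=range(2, 7),
                               seed: int | None = None,
                               n_restarts: int = 20) -> KSelection:
    """Choose the number of clusters maximizing the Calinski-Harabasz index.

    CH(k) = [B/(k-1)] / [W/(n-k)] with B/W the between/within dispersion of
    the k-means solution.  A best-to-runner-up CH ratio below 1.2 flags a
    low-confidence selection (no pronounced peak).
    """
    curves = np.asarray(curves, dtype=float)
    n = curves.shape[0]
    ks = [k for k in k_range if k < n]
    if not ks:
        raise ValueError(f"need more than {min(k_range)} curves, got {n}")
    if len(ks) < len(list(k_range)):
        logger.warning("k range shrunk to %s (only %d curves)", ks, n)
    scores = {}
    for k in ks:
        km = _kmeans(curves, k, seed, n_restarts)
        scores[k] = float(calinski_harabasz_score(curves, km.labels_))
    ordered = sorted(scores.values(), reverse=True)
    best = max(scores, key=scores.get)
    low_conf = len(ordered) > 1 and ordered[1] > 0 and ordered[0] / ordered[1] < 1.2
    return KSelection(k=best, scores=scores, low_confidence=low_conf)


def _match_labels(centroids: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permutation aligning ``centroids`` rows to ``reference`` rows by
    minimal summed squared distance (Hungarian assignment)."""
    cost = ((centroids[:, None, :] - reference[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


def loo_cluster_rois(subject_betas: np.ndarray, k: int,
                     seed: int | None = None,
                     n_restarts: int = 20) -> list[ClusterSolution]:
    """Leave-one-subject-out k-means ROIs over release-mask voxels.

    ``subject_betas`` has shape (n_subjects, 4, n_voxels): each subject's
    deviant betas (SC, C, D, SD) at every release-mask voxel.  For each
    fold, voxel curves are averaged over the retained subjects, z-scored
    per voxel and clustered; labels are matched to the first fold's
    centroids so cluster c means the same archetype in every fold.  The
    held-out subject's mean curve per cluster ROI is recorded.
    """
    betas = np.asarray(subject_betas, dtype=float)
    n_subj, n_cond, n_vox = betas.shape
    if n_cond != 4:
        raise ValueError("subject_betas must carry the four deviant conditions")
    if k > n_vox:
        raise ValueError(f"cannot form {k} clusters from {n_vox} voxels")
    solutions: list[ClusterSolution] = []
    reference: np.ndarray | None = None
    for fold in range(n_subj):
        keep = np.arange(n_subj) != fold
        mean_curves = betas[keep].mean(axis=0).T        # n_vox x 4
        z = zscore_rows(mean_curves)
        km = _kmeans(z, k, seed, n_restarts)
        centroids = km.cluster_centers_
        labels = km.labels_
        if reference is None:
            # cluster 1 is the steepest (largest SC-to-SD slope) archetype
            order = np.argsort(-_slopes(centroids))
            reference = centroids[order]
            perm = np.empty(k, dtype=int)
            perm[order] = np.arange(k)
        else:
            perm = _match_labels(centroids, reference)
        labels = perm[labels] + 1                        # 1-based, aligned
        centroids = centroids[np.argsort(perm)]
        held = np.full((k, 4), np.nan)
        for c in range(1, k + 1):
            roi = labels == c
            if roi.any():
                held[c - 1] = betas[fold][:, roi].mean(axis=1)
        solutions.append(ClusterSolution(
            k=k, labels=labels, centroids=centroids,
            ch_value=float(calinski_harabasz_score(z, labels)) if k > 1 else np.nan,
            fold=fold, heldout_curves=held,
        ))
    return solutions


def consensus_mask(solutions: list[ClusterSolution], threshold: float = 0.75) -> dict[int, np.ndarray]:
    """Per-cluster consensus: voxels assigned to the cluster in strictly
    more than ``threshold * n_folds`` folds (capped at all folds), i.e.
    16 of 20 folds at the default 75% threshold."""
    n_folds = len(solutions)
    k = solutions[0].k
    need = min(n_folds, int(np.floor(threshold * n_folds)) + 1)
    labels = np.stack([s.labels for s in solutions])  # folds x voxels
    return {c: (labels == c).sum(axis=0) >= need for c in range(1, k + 1)}


def _slopes(curves: np.ndarray) -> np.ndarray:
    """OLS slope over similarity rank 1..4 for each row of curves."""
    xc = RANK_X - RANK_X.mean()
    return (curves - curves.mean(axis=-1, keepdims=True)) @ xc / (xc @ xc)


@dataclass
class ClusterComparison:
    excluded_subjects: list[int]
    z_curves: np.ndarray       # (n_kept, k, 4) z-scored curves
    slopes: np.ndarray         # (n_kept, k)
    slope_t: float
    slope_p_one_tailed: float
    wilcoxon_stat: float
    wilcoxon_p: float
    deviant_tests: pd.DataFrame
    identity_means: np.ndarray | None = None


def compare_clusters(curves: np.ndarray,
                     identity: np.ndarray | None = None,
                     outlier_sd: float = 3.0) -> ClusterComparison:
    """Compare tuning between the (first two) consensus clusters.

    ``curves`` has shape (n_subjects, k, 4): each subject's mean deviant
    betas per cluster, from the leave-one-out extraction.  Subjects whose
    grand-mean beta exceeds the group mean by more than ``outlier_sd``
    standard deviations are excluded.  Curves are then z-scored per subject
    across the concatenated cluster x condition set; slopes over the
    similarity ranks are compared with a paired one-tailed t-test (cluster
    1 steeper than cluster 2) and a Wilcoxon signed-rank test, and the six
    deviant pairs are compared within each cluster (two-tailed,
    Bonferroni).  Identity means, if given, are carried descriptively only.
    """
    curves = np.asarray(curves, dtype=float)
    n_subj, k, _ = curves.shape
    grand = curves.reshape(n_subj, -1).mean(axis=1)
    cut = grand.mean() + outlier_sd * grand.std(ddof=1)
    keep = grand <= cut
    excluded = list(np.flatnonzero(~keep))
    if excluded:
        logger.info("excluding outlier subject(s) %s (grand-mean beta > %g SD)",
                    excluded, outlier_sd)
    curves = curves[keep]
    if curves.shape[0] < 3:
        raise ValueError("fewer than 3 subjects remain after outlier exclusion")

    flat = curves.reshape(curves.shape[0], -1)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = ((flat - mu) / sd).reshape(curves.shape)

    slopes = _slopes(z)
    if k >= 2:
        d = slopes[:, 0] - slopes[:, 1]
        if np.allclose(d, 0):
            slope_t, slope_p = 0.0, 0.5
            w_stat, w_p = np.nan, 1.0
        else:
            slope_t, slope_p = stats.ttest_rel(slopes[:, 0], slopes[:, 1],
                                               alternative="greater")
            w_stat, w_p = stats.wilcoxon(slopes[:, 0], slopes[:, 1],
                                         alternative="greater")
    else:
        slope_t = slope_p = w_stat = w_p = np.nan

    rows = []
    m = len(list(combinations(range(4), 2)))
    for c in range(k):
        for i, j in combinations(range(4), 2):
            diff = z[:, c, i] - z[:, c, j]
            sd_d = diff.std(ddof=1)
            if sd_d == 0:
                t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
                p_raw = 1.0 if t == 0 else 0.0
            else:
                t, p_raw = stats.ttest_rel(z[:, c, i], z[:, c, j])
            rows.append({
                "cluster": c + 1, "pair": f"{BIN_LABELS[i]}-{BIN_LABELS[j]}",
                "t": float(t), "df": curves.shape[0] - 1,
                "p_raw": float(p_raw), "p_adj": min(1.0, m * float(p_raw)),
            })

    return ClusterComparison(
        excluded_subjects=excluded,
        z_curves=z,
        slopes=slopes,
        slope_t=float(slope_t),
        slope_p_one_tailed=float(slope_p),
        wilcoxon_stat=float(w_stat) if w_stat == w_stat else np.nan,
        wilcoxon_p=float(w_p),
        deviant_tests=pd.DataFrame(rows),
        identity_means=None if identity is None else np.asarray(identity)[keep].mean(axis=0),
    )
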