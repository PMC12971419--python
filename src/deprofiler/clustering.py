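"""Differential-profile clustering with reproducibility-based k selection.

Genes whose genotype x transgene interaction survives a lenient FDR cut are
described by a differential profile: per pairwise contrast, the product of
the log2 fold-change and -log10 p-value, normalized by the column standard
deviation. k-means (Lloyd's algorithm) is run with several random
initializations for each candidate k; the distance between two clustering
results is one minus the mean fraction of shared co-clustered gene pairs,
and the selected k* is the largest k whose average pairwise distance across
initializations falls below a reproducibility tolerance — i.e. the finest
granularity at which the partition is essentially independent of the random
start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AnalysisConfig, InputError
from .de import DEResult

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class ProfileMatrix:
    """Gene x contrast matrix of SD-normalized differential profiles."""

    values: pd.DataFrame  # normalized profiles
    raw: pd.DataFrame  # log2fc x (-log10 p) before normalization
    column_sd: pd.Series


@dataclass
class ClusteringRun:
    """One k-means result: labels in 0..k-1 plus within-cluster sum of squares."""

    k: int
    init_index: int
    labels: np.ndarray
    wss: float


@dataclass
class KSelection:
    """Average pairwise reproducibility distance per k and the selected k*."""

    table: pd.DataFrame  # columns: k, mean_distance
    k_star: int
    selection_rule: str  # "threshold" or "fallback"


@dataclass
class ClusterResult:
    """Final assignments at k* (minimum-WSS run) with cluster mean profiles."""

    k_star: int
    assignments: pd.Series  # gene -> label
    centroids: pd.DataFrame  # label x contrast


def select_cluster_genes(de: DEResult, cluster_gene_fdr: float) -> list[str]:
    """Genes with interaction FDR strictly below the threshold, input order."""
    fdr = de.interaction["fdr"]
    genes = list(fdr.index[fdr < cluster_gene_fdr])
    if not genes:
        raise InputError(
            f"no genes for clustering at interaction FDR < {cluster_gene_fdr}"
        )
    return genes


def build_profiles(
    de: DEResult,
    genes: Sequence[str],
    contrasts: Sequence[str] | None = None,
    sd_scope: str = "column",
) -> ProfileMatrix:
    """Differential profiles s_gc = log2fc x (-log10 p), SD-normalized.

    p-values are floored at 1e-300 before the log. Normalization divides
    each column by its standard deviation (``sd_scope="column"``, the
    default) or every column by the global SD (``"global"``); a constant
    column is left unscaled with a warning. The log base is immaterial
    under per-column SD normalization (a base change rescales a column by a
    constant), so log10 is fixed for the reported raw products.
    """
    if contrasts is None:
        contrasts = list(de.pairwise.keys())
    raw = {}
    for cname in contrasts:
        tab = de.pairwise[cname].loc[list(genes)]
        p = np.maximum(tab["p"].to_numpy(float), P_FLOOR)
        raw[cname] = tab["log2fc"].to_numpy(float) * (-np.log10(p))
    raw_df = pd.DataFrame(raw, index=list(genes))
    sd = raw_df.std(ddof=1)
    if sd_scope == "global":
        g = float(np.std(raw_df.to_numpy().ravel(), ddof=1))
        sd = pd.Series(g, index=sd.index)
    scale = sd.copy()
    constant = ~(scale > 0)
    if constant.any():
        logger.warning(
            "constant profile columns left unscaled: %s",
            list(scale.index[constant]),
        )
        scale[constant] = 1.0
    values = raw_df / scale
    return ProfileMatrix(values=values, raw=raw_df, column_sd=sd)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: rows drawn with probability prop. to D^2."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining rows duplicate chosen centroids
            probs = np.full(n, 1.0 / n)
        else:
            probs = d2 / total
        centroids[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, float]:
    """One Lloyd's iteration sequence from a k-means++ start."""
    centroids = _kmeanspp_init(X, k, rng)
    labels = np.full(X.shape[0], -1, dtype=np.int64)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        own = d2[np.arange(X.shape[0]), new_labels]
        for c in range(k):
            if not (new_labels == c).any():  # re-seed an emptied cluster
                far = int(np.argmax(own))
                centroids[c] = X[far]
                new_labels[far] = c
                own[far] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = X[labels == c].mean(axis=0)
    d2 = ((X - centroids[labels]) ** 2).sum(axis=1)
    return labels, float(d2.sum())


def kmeans_run(
    profiles: np.ndarray | pd.DataFrame,
    k: int,
    init_index: int,
    base_seed: int,
    max_iter: int = 300,
    n_restarts: int = 10,
) -> ClusteringRun:
    """One seeded k-means result on the profile rows.

    Each result is the minimum-WSS partition over ``n_restarts`` Lloyd
    sequences from k-means++ starts — how practitioners run k-means (both
    sklearn and R return the best of several starts by default), and the
    only regime in which a clustering of well-separated structure is
    reproducible enough for the downstream average-distance rule to fire:
    a single uniformly-seeded Lloyd pass routinely traps two centroids in
    one blob, so no k above 2 would ever look stable. Deterministic given
    (base_seed, k, init_index). Iteration stops when assignments stabilize
    or after max_iter rounds; an emptied cluster is re-seeded with the
    point farthest from its current centroid.
    """
    X = profiles.to_numpy(float) if isinstance(profiles, pd.DataFrame) else np.asarray(
        profiles, float
    )
    if k < 1:
        raise InputError("k must be >= 1")
    if n_restarts < 1:
        raise InputError("n_restarts must be >= 1")
    uniq = np.unique(X, axis=0)
    if k > uniq.shape[0]:
        raise InputError(
            f"k={k} exceeds the number of distinct profile rows ({uniq.shape[0]})"
        )
    best: tuple[np.ndarray, float] | None = None
    for j in range(n_restarts):
        rng = np.random.default_rng([base_seed, k, init_index, j])
        labels, wss = _lloyd(X, k, rng, max_iter)
        if best is None or wss < best[1]:
            best = (labels, wss)
    return ClusteringRun(
        k=k, init_index=init_index, labels=best[0], wss=best[1]
    )


def coclustered_pairs(run: ClusteringRun) -> set[tuple[int, int]]:
    """All unordered index pairs assigned to the same cluster."""
    pairs: set[tuple[int, int]] = set()
    for c in np.unique(run.labels):
        members = np.flatnonzero(run.labels == c)
        pairs.update(combinations(members.tolist(), 2))
    return pairs


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(|P_a|, |P_b|, |P_a intersect P_b|) via the contingency table."""
    def n_pairs(x):
        _, counts = np.unique(x, return_counts=True)
        return float((counts * (counts - 1) // 2).sum())

    joint = a.astype(np.int64) * (b.max() + 1) + b.astype(np.int64)
    return n_pairs(a), n_pairs(b), n_pairs(joint)


def clustering_distance(run_a: ClusteringRun, run_b: ClusteringRun) -> float:
    """Reproducibility distance between two partitions of the same genes.

    With P_a, P_b the co-clustered pair sets, the shared fraction is
    f = (|P_a & P_b|/|P_a| + |P_a & P_b|/|P_b|) / 2 and d = 1 - f. Both
    pair sets empty gives d = 0; exactly one empty gives d = 1. Invariant
    to cluster relabeling, symmetric, and 0 for identical partitions.
    """
    if run_a.labels.shape != run_b.labels.shape:
        raise InputError("clustering results cover different gene sets")
    pa, pb, inter = _pair_counts(run_a.labels, run_b.labels)
    if pa == 0 and pb == 0:
        return 0.0
    if pa == 0 or pb == 0:
        return 1.0
    f = 0.5 * (inter / pa + inter / pb)
    return float(1.0 - f)


def select_k(
    profiles: ProfileMatrix | pd.DataFrame,
    config: AnalysisConfig,
    base_seed: int | None = None,
) -> tuple[KSelection, ClusterResult]:
    """Scan k over the configured range and pick the reproducible granularity.

    For each k, n_init seeded k-means runs are compared pairwise; k* is the
    largest k whose average distance is strictly below repro_tol. If no k
    qualifies the fallback takes the argmin of the average distance
    (smallest k on ties) with a warning. Final assignments come from the
    minimum-WSS run at k*.
    """
    if base_seed is None:
        base_seed = config.base_seed
    values = profiles.values if isinstance(profiles, ProfileMatrix) else profiles
    gene_ids = list(values.index)
    X = values.to_numpy(float)
    if X.shape[0] < config.k_min:
        raise InputError(
            f"only {X.shape[0]} genes selected; need >= k_min={config.k_min}"
        )
    n_unique = np.unique(X, axis=0).shape[0]

    rows = []
    runs_by_k: dict[int, list[ClusteringRun]] = {}
    for k in range(config.k_min, config.k_max + 1):
        if k > n_unique:
            logger.warning("skipping k=%d: only %d distinct rows", k, n_unique)
            rows.append({"k": k, "mean_distance": np.nan})
            continue
        runs = [
            kmeans_run(X, k, i, base_seed) for i in range(config.n_init)
        ]
        runs_by_k[k] = runs
        dists = [
            clustering_distance(ra, rb) for ra, rb in combinations(runs, 2)
        ]
        rows.append({"k": k, "mean_distance": float(np.mean(dists))})
    table = pd.DataFrame(rows)

    ok = table["mean_distance"] < config.repro_tol
    if ok.any():
        k_star = int(table.loc[ok, "k"].max())
        rule = "threshold"
    else:
        valid = table.dropna(subset=["mean_distance"])
        k_star = int(valid.loc[valid["mean_distance"].idxmin(), "k"])
        rule = "fallback"
        logger.warning(
            "no k reached average distance < %g; falling back to argmin (k=%d)",
            config.repro_tol,
            k_star,
        )
    best = min(runs_by_k[k_star], key=lambda r: (r.wss, r.init_index))
    centroids = (
        values.groupby(best.labels).mean().rename_axis("cluster")
    )
    return (
        KSelection(table=table, k_star=k_star, selection_rule=rule),
        ClusterResult(
            k_star=k_star,
            assignments=pd.Series(best.labels, index=gene_ids, name="cluster"),
            centroids=centroids,
        ),
    )
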