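"""Consensus clustering of samples on the signature genes and
rule-based merging of clusters into the three immune phenotypes.

"Pearson distance + k-means" is realised as k-means on row-standardized
sample profiles: after centring each sample's gene vector and scaling it
to unit norm, squared Euclidean distance is proportional to one minus
the Pearson correlation, so the named combination is well defined.

The published pipeline merged six clusters into three phenotypes by
hand; here the merge is an explicit rule on cluster-level mean polar
metrics (low mean R -> desert; high mean theta among the rest ->
excluded; remainder -> infiltrated). The rule is a documented surrogate
for a manual step, with its thresholds recorded in the merge map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = [
    "ConsensusResult",
    "standardize_samples",
    "consensus_matrix",
    "consensus_clusters",
    "merge_to_phenotypes",
    "run_consensus",
]


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame  # samples x samples, in [0, 1]
    cosample_counts: pd.DataFrame
    cluster_labels_k6: pd.Series = field(default=None)
    phenotype_labels: pd.Series = field(default=None)
    merge_map: dict = field(default_factory=dict)


def standardize_samples(expr: pd.DataFrame) -> np.ndarray:
    """Samples-as-rows matrix with zero mean, unit norm per sample."""
    x = expr.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def consensus_matrix(
    expr: pd.DataFrame,
    k: int = 6,
    n_reps: int = 1000,
    sample_frac: float = 0.8,
    feature_frac: float = 1.0,
    seed: int = 0,
    n_init: int = 10,
    require_full_cosampling: bool = True,
) -> ConsensusResult:
    """Subsampled k-means consensus.

    Per replicate: draw ``floor(sample_frac * n)`` samples without
    replacement (and optionally a gene subset), run k-means on the
    standardized profiles, and tally co-clustering. The consensus entry
    for a pair is co-cluster count / co-sample count; the diagonal is 1
    by convention. Pairs never jointly subsampled are an error by
    default (more replicates are needed for a usable matrix); with
    ``require_full_cosampling=False`` they are reported as NaN instead.
    """
    samples = list(expr.columns)
    n = len(samples)
    if n < 3 * k:
        raise ValueError(f"need at least {3 * k} samples for k={k}")
    m = int(np.floor(sample_frac * n))
    if m < k:
        raise ValueError("sample_frac leaves fewer samples than clusters")
    x = standardize_samples(expr)
    g = x.shape[1]
    gsub = int(np.floor(feature_frac * g))

    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for rep in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        xs = x[idx]
        if gsub < g:
            cols = rng.choice(g, size=gsub, replace=False)
            xs = xs[:, cols]
        km = KMeans(
            n_clusters=k,
            n_init=n_init,
            max_iter=300,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(xs)
        labels = km.labels_
        same = labels[:, None] == labels[None, :]
        co_sample[np.ix_(idx, idx)] += 1.0
        co_cluster[np.ix_(idx, idx)] += same
    off = ~np.eye(n, dtype=bool)
    if (co_sample[off] == 0).any() and require_full_cosampling:
        raise ValueError(
            "some sample pairs were never co-subsampled; increase n_reps"
        )
    with np.errstate(invalid="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), np.nan)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    return ConsensusResult(
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        cosample_counts=pd.DataFrame(co_sample, index=samples, columns=samples),
    )


def consensus_clusters(consensus: pd.DataFrame, k: int = 6) -> pd.Series:
    """Final cluster call: average-linkage agglomeration on 1 - M cut
    at ``k``. Errors if ``k`` non-empty clusters cannot be produced."""
    n = consensus.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    diss = 1.0 - consensus.to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = linkage(squareform(diss, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise ValueError(
            f"could not produce {k} non-empty clusters "
            f"(got {len(np.unique(labels))}); consensus may be degenerate"
        )
    return pd.Series(labels, index=consensus.index, name="cluster_k6")


def merge_to_phenotypes(
    cluster_labels: pd.Series,
    polar_table: pd.DataFrame,
    r_quantile: float = 0.40,
    theta_threshold: float | None = None,
) -> tuple[pd.Series, dict]:
    """Map clusters to phenotypes from cluster-level mean polar metrics.

    Clusters whose mean R falls below the cohort ``r_quantile`` quantile
    of R are desert; among the rest, clusters whose mean theta exceeds
    ``theta_threshold`` (default: median theta of samples in non-desert
    clusters) are excluded; the remainder are infiltrated.
    """
    pt = polar_table.set_index("sample_id") if "sample_id" in polar_table.columns else polar_table
    missing = [s for s in cluster_labels.index if s not in pt.index]
    if missing:
        raise ValueError(f"samples missing polar metrics: {missing[:5]}")
    pt = pt.loc[cluster_labels.index]

    r_cut = float(np.quantile(pt["R"].to_numpy(), r_quantile))
    stats = pd.DataFrame(
        {
            "mean_R": pt.groupby(cluster_labels)["R"].mean(),
            "mean_theta": pt.groupby(cluster_labels)["theta"].mean(),
            "n": cluster_labels.value_counts().sort_index(),
        }
    )
    desert_clusters = stats.index[stats["mean_R"] < r_cut]
    non_desert_samples = ~cluster_labels.isin(desert_clusters)
    if theta_threshold is None:
        if non_desert_samples.any():
            theta_cut = float(pt.loc[non_desert_samples, "theta"].median())
        else:
            theta_cut = float(np.median(pt["theta"]))
    else:
        theta_cut = float(theta_threshold)

    merge_map: dict = {"r_cutoff": r_cut, "theta_cutoff": theta_cut, "clusters": {}}
    assign = {}
    for c in stats.index:
        if c in desert_clusters:
            pheno = "desert"
        elif stats.loc[c, "mean_theta"] > theta_cut:
            pheno = "excluded"
        else:
            pheno = "infiltrated"
        assign[c] = pheno
        merge_map["clusters"][int(c)] = {
            "phenotype": pheno,
            "mean_R": float(stats.loc[c, "mean_R"]),
            "mean_theta": float(stats.loc[c, "mean_theta"]),
            "n_samples": int(stats.loc[c, "n"]),
        }
    phenotypes = cluster_labels.map(assign).rename("phenotype")
    present = set(phenotypes)
    for pheno in ("infiltrated", "excluded", "desert"):
        if pheno not in present:
            warnings.warn(
                f"no cluster was assigned phenotype {pheno!r}; "
                f"merge map: {merge_map['clusters']}",
                stacklevel=2,
            )
    return phenotypes, merge_map


def run_consensus(
    expr: pd.DataFrame,
    polar_table: pd.DataFrame,
    k: int = 6,
    n_reps: int = 1000,
    sample_frac: float = 0.8,
    feature_frac: float = 1.0,
    seed: int = 0,
    r_quantile: float = 0.40,
) -> ConsensusResult:
    """Consensus matrix -> k clusters -> phenotype merge, in one call."""
    result = consensus_matrix(expr, k, n_reps, sample_frac, feature_frac, seed)
    result.cluster_labels_k6 = consensus_clusters(result.consensus, k)
    result.phenotype_labels, result.merge_map = merge_to_phenotypes(
        result.cluster_labels_k6, polar_table, r_quantile=r_quantile
    )
    return result
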