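"""Count-matrix preparation: low-expression filter, TMM, log2 CPM,
housekeeping scaling.

All functions operate on pandas DataFrames with genes as rows (index =
gene ids) and samples as columns. The full chain is::

    counts -> filter_low_expression -> tmm_factors -> log2_cpm
           -> housekeeping_normalize

and is bundled by :func:`prep_pipeline`, which records the exact
parameterisation in a provenance dict so downstream classification can
verify that new cohorts were prepared identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HK_GENES",
    "NormalizedMatrix",
    "cpm",
    "filter_low_expression",
    "tmm_factors",
    "log2_cpm",
    "identify_housekeeping",
    "housekeeping_normalize",
    "prep_pipeline",
]

#: Stable reference genes used for the final scaling step.
DEFAULT_HK_GENES = ("ACTB", "ACTG1", "HSP90AB1", "UBC")


@dataclass
class NormalizedMatrix:
    """Housekeeping-scaled log2 CPM values plus normalization metadata."""

    values: pd.DataFrame
    tmm_factors: pd.Series
    hk_genes: list[str]
    provenance: dict = field(default_factory=dict)


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("gene and sample ids must be unique")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million on raw library sizes (column sums)."""
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    return counts / lib * 1e6


def filter_low_expression(
    counts: pd.DataFrame, cpm_cutoff: float = 0.25, frac_cutoff: float = 0.10
) -> pd.DataFrame:
    """Drop lowly expressed genes.

    A gene is removed iff the fraction of samples in which its CPM falls
    below ``cpm_cutoff`` is at least ``frac_cutoff`` (a fraction of
    exactly ``frac_cutoff`` removes). CPM is computed on raw library
    sizes, before any scale-factor normalization.
    """
    _validate_counts(counts)
    frac_low = (cpm(counts) < cpm_cutoff).mean(axis=1)
    keep = frac_low < frac_cutoff
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    return counts.loc[keep]


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
    a_cutoff: float,
) -> float:
    """TMM factor of one sample against the reference column."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no expressed genes with the reference")
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # inverse asymptotic (delta-method) variance of M
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    keep_finite = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, w = m[keep_finite], a[keep_finite], w[keep_finite]
    n = m.size
    if n == 0:
        raise ValueError("no usable genes for TMM after filtering")
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # double trim by rank on M and A, matching the canonical rule:
    # keep ranks in [floor(n*trim)+1, n - floor(n*trim)]
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, one per sample.

    The reference sample is the one whose upper-quartile CPM is closest
    to the mean upper-quartile across samples. Factors are rescaled to
    geometric mean 1.
    """
    _validate_counts(counts)
    vals = counts.to_numpy(dtype=float)
    lib = vals.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    uq = np.array([np.quantile(vals[:, j] / lib[j], 0.75) for j in range(vals.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        try:
            factors[j] = _tmm_pair_factor(
                vals[:, j], vals[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, abs_trim, a_cutoff,
            )
        except ValueError as exc:
            raise ValueError(f"TMM failed for sample {counts.columns[j]!r}: {exc}") from exc
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log2_cpm(
    counts: pd.DataFrame, factors: pd.Series | None = None, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    value = log2( (count + prior) / (lib * factor + 2 * prior) * 1e6 )
    """
    _validate_counts(counts)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("factors must be positive and cover every sample")
    lib = counts.sum(axis=0)
    eff = lib * factors + 2 * prior
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    return np.log2((counts + prior) / eff * 1e6)


def identify_housekeeping(
    log2cpm: pd.DataFrame, mean_cutoff: float = 10.0, var_quantile: float = 0.25
) -> list[str]:
    """Highly expressed, low-variance genes.

    Returns genes whose mean log2 CPM strictly exceeds ``mean_cutoff``
    and whose variance is strictly below the ``var_quantile`` quantile
    of all gene variances.
    """
    if log2cpm.shape[0] < 4:
        raise ValueError("need at least 4 genes")
    means = log2cpm.mean(axis=1)
    variances = log2cpm.var(axis=1, ddof=1)
    var_cut = float(np.quantile(variances.to_numpy(), var_quantile))
    selected = log2cpm.index[(means > mean_cutoff) & (variances < var_cut)].tolist()
    if not selected:
        warnings.warn("no genes passed the housekeeping criteria", stacklevel=2)
    return selected


def housekeeping_normalize(
    log2cpm: pd.DataFrame, hk_genes: tuple[str, ...] | list[str] = DEFAULT_HK_GENES
) -> NormalizedMatrix:
    """Divide each sample column by its mean log2 CPM over ``hk_genes``."""
    hk_genes = list(hk_genes)
    missing = [g for g in hk_genes if g not in log2cpm.index]
    if missing:
        raise ValueError(f"housekeeping genes missing from matrix: {missing}")
    hk_mean = log2cpm.loc[hk_genes].mean(axis=0)
    bad = hk_mean[hk_mean <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive housekeeping mean in samples: {bad.index.tolist()}"
        )
    return NormalizedMatrix(
        values=log2cpm / hk_mean,
        tmm_factors=pd.Series(np.nan, index=log2cpm.columns),
        hk_genes=hk_genes,
        provenance={"hk_genes": hk_genes},
    )


def prep_pipeline(
    counts: pd.DataFrame,
    cpm_cutoff: float = 0.25,
    frac_cutoff: float = 0.10,
    hk_genes: tuple[str, ...] | list[str] = DEFAULT_HK_GENES,
    prior: float = 0.5,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> NormalizedMatrix:
    """Full preparation chain with provenance.

    filter -> TMM -> log2 CPM (prior 0.5, lib*factor + 2*prior
    denominator) -> housekeeping scaling. Also records a small PCA
    diagnostic (variance explained by the leading components) in the
    provenance; no samples are excluded automatically.
    """
    filtered = filter_low_expression(counts, cpm_cutoff, frac_cutoff)
    factors = tmm_factors(filtered, logratio_trim=logratio_trim, abs_trim=abs_trim)
    logmat = log2_cpm(filtered, factors, prior=prior)
    norm = housekeeping_normalize(logmat, hk_genes)
    norm.tmm_factors = factors
    centred = logmat.to_numpy() - logmat.to_numpy().mean(axis=1, keepdims=True)
    sv = np.linalg.svd(centred, compute_uv=False)
    var_explained = (sv**2 / np.sum(sv**2))[: min(5, sv.size)]
    norm.provenance = {
        "transforms": [
            {"name": "filter_low_expression",
             "cpm_cutoff": cpm_cutoff, "frac_cutoff": frac_cutoff},
            {"name": "tmm", "logratio_trim": logratio_trim, "abs_trim": abs_trim},
            {"name": "log2_cpm", "prior": prior,
             "denominator": "lib*factor + 2*prior"},
            {"name": "housekeeping_normalize", "hk_genes": list(hk_genes)},
        ],
        "hk_genes": list(hk_genes),
        "n_genes_in": int(counts.shape[0]),
        "n_genes_kept": int(filtered.shape[0]),
        "pca_variance_explained": [float(v) for v in var_explained],
    }
    return norm
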