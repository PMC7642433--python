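"""Per-gene random-forest regression against (R, theta) and gene-set
partitioning.

For each gene a regression forest ``expression ~ R + theta`` is fitted
with bootstrap resampling of samples and no predictor subsampling (both
predictors are candidates at every split). Association strength is the
percent increase in out-of-bag MSE when one predictor is permuted.
Genes are then partitioned:

* the bottom ``drop_quantile`` of genes by average importance are
  dropped as unassociated;
* among retained genes, those above the third quartile of the R
  importance only are *quantity_only*, above the theta quartile only
  are *distribution_only*, above both are *both*, the rest *none*;
* the signature is quantity_only union distribution_only.

Quantiles use numpy's inclusive linear-interpolation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._forest import forest_oob_importance

__all__ = [
    "SelectionThresholds",
    "GeneSets",
    "fit_gene_models",
    "select_genes",
]

CATEGORIES = ("quantity_only", "distribution_only", "both", "none", "dropped")


@dataclass(frozen=True)
class SelectionThresholds:
    """Knobs for the drop filter and the per-metric selection."""

    drop_quantile: float = 0.25
    select_quantile: float = 0.75
    n_trees: int = 500
    min_leaf: int = 5
    seed: int = 0
    # literal reading of the drop rule: drop genes with *low OOB MSE*
    # instead of low importance (see select_genes docstring)
    drop_on_oob_mse: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.drop_quantile < self.select_quantile < 1.0):
            raise ValueError("need 0 < drop_quantile < select_quantile < 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")


@dataclass
class GeneSets:
    """Partitioned gene sets plus the logged thresholds."""

    quantity_only: list[str]
    distribution_only: list[str]
    both: list[str]
    none: list[str]
    dropped: list[str]
    signature: list[str]
    log: dict


def fit_gene_models(
    expr: pd.DataFrame,
    polar_table: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Fit one forest per gene; return the importance table.

    Parameters
    ----------
    expr : DataFrame
        Normalized expression, genes x samples.
    polar_table : DataFrame
        Must contain ``sample_id``, ``R`` and ``theta``; degenerate-flag
        theta values are used as-is.

    Returns
    -------
    DataFrame indexed by gene id with columns ``oob_mse``,
    ``inc_mse_R``, ``inc_mse_theta``, ``avg_importance``, ``note``.
    """
    pt = polar_table.set_index("sample_id") if "sample_id" in polar_table.columns else polar_table
    missing = [s for s in expr.columns if s not in pt.index]
    if missing:
        raise ValueError(f"samples missing polar metrics: {missing[:5]}")
    pt = pt.loc[expr.columns]
    n = expr.shape[1]
    if n < 20:
        raise ValueError(f"need at least 20 samples, got {n}")

    X = np.column_stack(
        [pt["R"].to_numpy(dtype=float), pt["theta"].to_numpy(dtype=float)]
    )
    Y = expr.to_numpy(dtype=float)

    # one master stream: bootstraps/permutations per gene are spawned so
    # the full table is reproducible from the single seed
    ss = np.random.SeedSequence(thresholds.seed)
    child_seeds = ss.spawn(expr.shape[0])

    rows = np.empty((expr.shape[0], 3))
    notes = [""] * expr.shape[0]
    X = np.ascontiguousarray(X)
    for gi in range(expr.shape[0]):
        y = np.ascontiguousarray(Y[gi])
        if np.ptp(y) == 0:
            rows[gi] = (0.0, 0.0, 0.0)
            notes[gi] = "constant response; importances set to 0"
            continue
        rng = np.random.default_rng(child_seeds[gi])
        boot = rng.integers(0, n, size=(thresholds.n_trees, n), dtype=np.int64)
        perms = rng.permuted(
            np.broadcast_to(np.arange(n, dtype=np.int64),
                            (thresholds.n_trees, 2, n)),
            axis=-1,
        )
        oob_mse, inc = forest_oob_importance(X, y, boot, perms, thresholds.min_leaf)
        rows[gi] = (oob_mse, inc[0], inc[1])

    table = pd.DataFrame(
        rows, index=expr.index, columns=["oob_mse", "inc_mse_R", "inc_mse_theta"]
    )
    table["avg_importance"] = (table["inc_mse_R"] + table["inc_mse_theta"]) / 2.0
    table["note"] = notes
    return table


def select_genes(
    table: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> GeneSets:
    """Partition genes by importance quartiles.

    The drop filter defaults to "average permutation importance below
    its ``drop_quantile`` quantile" — the reading on which dropped genes
    are the ones *not* associated with the metrics. Setting
    ``drop_on_oob_mse=True`` instead drops genes with OOB MSE below the
    quantile (the literal low-error reading, which discards the
    best-predicted genes).
    """
    drop_metric = table["oob_mse"] if thresholds.drop_on_oob_mse else table["avg_importance"]
    drop_cut = float(np.quantile(drop_metric.to_numpy(), thresholds.drop_quantile))
    dropped_mask = drop_metric < drop_cut
    retained = table.loc[~dropped_mask]
    if len(retained) < 4:
        raise ValueError(f"only {len(retained)} genes retained; need at least 4")

    q3_r = float(np.quantile(retained["inc_mse_R"].to_numpy(), thresholds.select_quantile))
    q3_t = float(np.quantile(retained["inc_mse_theta"].to_numpy(), thresholds.select_quantile))
    hi_r = retained["inc_mse_R"] > q3_r
    hi_t = retained["inc_mse_theta"] > q3_t

    quantity_only = retained.index[hi_r & ~hi_t].tolist()
    distribution_only = retained.index[~hi_r & hi_t].tolist()
    both = retained.index[hi_r & hi_t].tolist()
    none = retained.index[~hi_r & ~hi_t].tolist()
    signature = quantity_only + distribution_only
    if not (quantity_only or distribution_only or both):
        raise ValueError(
            "selection is empty: no gene strictly exceeds the importance "
            f"quartiles (Q3_R={q3_r:.4g}, Q3_theta={q3_t:.4g}); importances "
            "may be degenerate/tied"
        )
    log = {
        "drop_quantile": thresholds.drop_quantile,
        "select_quantile": thresholds.select_quantile,
        "drop_on_oob_mse": thresholds.drop_on_oob_mse,
        "drop_cutoff": drop_cut,
        "q3_inc_mse_R": q3_r,
        "q3_inc_mse_theta": q3_t,
        "n_dropped": int(dropped_mask.sum()),
        "set_sizes": {
            "quantity_only": len(quantity_only),
            "distribution_only": len(distribution_only),
            "both": len(both),
            "none": len(none),
            "signature": len(signature),
        },
    }
    return GeneSets(
        quantity_only=quantity_only,
        distribution_only=distribution_only,
        both=both,
        none=none,
        dropped=table.index[dropped_mask].tolist(),
        signature=signature,
        log=log,
    )


def categorize(table: pd.DataFrame, sets: GeneSets) -> pd.Series:
    """Per-gene category column consistent with a GeneSets partition."""
    cat = pd.Series("none", index=table.index, dtype=object)
    for name in ("quantity_only", "distribution_only", "both", "dropped"):
        cat.loc[getattr(sets, name)] = name
    return cat
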