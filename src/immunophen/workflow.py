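"""End-to-end orchestration: prep -> polar -> gene selection ->
consensus -> classifier training, plus deployment of a trained model on
new cohorts, with a JSON run manifest for reproducibility.

Training labels come from consensus clustering, not from any simulation
truth; when truth is supplied it is used only to compute recovery
metrics recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__, consensus, exprprep, geneselect, nsc, polar
from .simdata import GroundTruth

__all__ = ["PipelineConfig", "PipelineResult", "run_training_pipeline", "run_classification"]

logger = logging.getLogger("immunophen")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Per-stage parameters; every field maps 1:1 to a config key."""

    # exprprep
    cpm_cutoff: float = 0.25
    frac_cutoff: float = 0.10
    hk_genes: tuple = exprprep.DEFAULT_HK_GENES
    prior: float = 0.5
    # geneselect
    n_trees: int = 500
    drop_quantile: float = 0.25
    select_quantile: float = 0.75
    # consensus
    k: int = 6
    n_reps: int = 1000
    sample_frac: float = 0.8
    feature_frac: float = 1.0
    r_quantile: float = 0.40
    # nsc
    cv_folds: int = 10
    hi: float = 0.7
    lo: float = 0.5
    # master seed; per-stage seeds are derived via a counter scheme
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        order = {"geneselect": 1, "consensus": 2, "nsc": 3}
        return int(
            np.random.SeedSequence([self.seed, order[stage]]).generate_state(1)[0]
        )

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["hk_genes"] = list(self.hk_genes)
        return d


@dataclass
class PipelineResult:
    normalized: exprprep.NormalizedMatrix
    polar_table: pd.DataFrame
    importance_table: pd.DataFrame
    gene_sets: geneselect.GeneSets
    consensus_result: consensus.ConsensusResult
    model: nsc.NSCModel
    manifest: dict = field(default_factory=dict)


def _digest(obj) -> str:
    """Stable sha256 of a DataFrame/str/bytes."""
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv(sep="\t", float_format="%.12g").encode()
    elif isinstance(obj, str):
        payload = obj.encode()
    else:
        payload = bytes(obj)
    return hashlib.sha256(payload).hexdigest()


def run_training_pipeline(
    counts: pd.DataFrame,
    densities: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    truth: GroundTruth | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full training workflow on one cohort.

    ``counts`` is genes x samples; ``densities`` must carry
    ``sample_id``, ``cd8_tumour_density`` and ``cd8_stroma_density`` for
    the same samples.
    """
    sample_ids = list(counts.columns)
    dens_ids = list(densities["sample_id"])
    if set(sample_ids) != set(dens_ids):
        raise ValueError("counts and densities cover different samples")
    densities = densities.set_index("sample_id").loc[sample_ids].reset_index()

    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "digests": {},
    }

    def stage(name):
        logger.info("stage=%s status=start", name)
        return time.perf_counter()

    def done(name, t0):
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"seconds": round(dt, 3)}
        logger.info("stage=%s status=done seconds=%.2f", name, dt)

    t0 = stage("exprprep")
    norm = exprprep.prep_pipeline(
        counts,
        cpm_cutoff=config.cpm_cutoff,
        frac_cutoff=config.frac_cutoff,
        hk_genes=config.hk_genes,
        prior=config.prior,
    )
    done("exprprep", t0)

    t0 = stage("polar")
    polar_table = polar.add_polar_columns(densities)
    done("polar", t0)

    t0 = stage("geneselect")
    thresholds = geneselect.SelectionThresholds(
        drop_quantile=config.drop_quantile,
        select_quantile=config.select_quantile,
        n_trees=config.n_trees,
        seed=config.stage_seed("geneselect"),
    )
    importance = geneselect.fit_gene_models(norm.values, polar_table, thresholds)
    sets = geneselect.select_genes(importance, thresholds)
    importance["category"] = geneselect.categorize(importance, sets)
    done("geneselect", t0)

    t0 = stage("consensus")
    cons = consensus.run_consensus(
        norm.values.loc[sets.signature],
        polar_table,
        k=config.k,
        n_reps=config.n_reps,
        sample_frac=config.sample_frac,
        feature_frac=config.feature_frac,
        seed=config.stage_seed("consensus"),
        r_quantile=config.r_quantile,
    )
    done("consensus", t0)

    t0 = stage("nsc")
    model = nsc.train_nsc(
        norm.values.loc[sets.signature],
        cons.phenotype_labels,
        cv_folds=config.cv_folds,
        seed=config.stage_seed("nsc"),
    )
    done("nsc", t0)

    manifest["digests"] = {
        "normalized": _digest(norm.values),
        "polar_table": _digest(polar_table),
        "importance_table": _digest(importance),
        "consensus_matrix": _digest(cons.consensus),
        "labels": _digest(cons.phenotype_labels.to_frame()),
        "model": _digest(model.to_json()),
    }
    manifest["gene_set_sizes"] = sets.log["set_sizes"]
    manifest["chosen_delta"] = model.delta
    manifest["n_classifier_genes"] = model.n_active_genes()

    if truth is not None:
        truth_pheno = pd.Series(truth.phenotype, index=truth.sample_ids).loc[sample_ids]
        agree = float((cons.phenotype_labels == truth_pheno).mean())
        ari = float(adjusted_rand_score(truth_pheno, cons.phenotype_labels))
        modules = truth.gene_module
        selected = set(sets.signature) | set(sets.both)
        quantity_cats = set(sets.quantity_only) | set(sets.both)
        distribution_cats = set(sets.distribution_only) | set(sets.both)
        cyt = modules.index[modules == "cytotoxic"]
        theta_genes = modules.index[modules.isin(["antigen_presentation", "tgfb_stroma"])]
        noise_genes = modules.index[modules == "noise"]
        kept = norm.values.index
        cyt, theta_genes, noise_genes = (
            cyt.intersection(kept), theta_genes.intersection(kept),
            noise_genes.intersection(kept),
        )
        manifest["recovery"] = {
            "phenotype_agreement": agree,
            "ari": ari,
            "quantity_gene_sensitivity": float(
                np.mean([g in quantity_cats for g in cyt])
            ) if len(cyt) else np.nan,
            "distribution_gene_sensitivity": float(
                np.mean([g in distribution_cats for g in theta_genes])
            ) if len(theta_genes) else np.nan,
            "noise_gene_selection_rate": float(
                np.mean([g in selected for g in noise_genes])
            ) if len(noise_genes) else np.nan,
        }

    result = PipelineResult(
        normalized=norm,
        polar_table=polar_table,
        importance_table=importance,
        gene_sets=sets,
        consensus_result=cons,
        model=model,
        manifest=manifest,
    )
    if outdir is not None:
        _write_training_outputs(Path(outdir), result)
    return result


def _write_training_outputs(outdir: Path, result: PipelineResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.normalized.values.to_csv(outdir / "normalized.tsv", sep="\t")
    result.polar_table.to_csv(outdir / "polar.tsv", sep="\t", index=False)
    result.importance_table.to_csv(outdir / "importance.tsv", sep="\t")
    for name in ("quantity_only", "distribution_only", "both", "none", "dropped", "signature"):
        (outdir / f"genes_{name}.txt").write_text(
            "\n".join(getattr(result.gene_sets, name)) + "\n"
        )
    result.consensus_result.consensus.to_csv(outdir / "consensus_matrix.tsv", sep="\t")
    labels = pd.DataFrame(
        {
            "sample_id": result.consensus_result.cluster_labels_k6.index,
            "cluster_k6": result.consensus_result.cluster_labels_k6.values,
            "phenotype": result.consensus_result.phenotype_labels.values,
        }
    )
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    (outdir / "merge_map.json").write_text(
        json.dumps(result.consensus_result.merge_map, indent=1)
    )
    result.model.to_json(outdir / "model.json")
    (outdir / "provenance.json").write_text(
        json.dumps(result.normalized.provenance, indent=1)
    )
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))


def run_classification(
    model: nsc.NSCModel,
    counts: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    provenance: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Prepare a new cohort identically and apply the gated classifier.

    ``provenance`` is the training provenance dict; when given, its
    housekeeping genes and prep parameters must match ``config`` or an
    error is raised (classifying with a different normalization than the
    model was trained under is not meaningful).
    """
    if counts.shape[1] == 0:
        summary = {
            "n": 0,
            "counts": {c: 0 for c in model.classes} | {nsc.UNCLASSIFIED: 0},
            "fractions": {},
        }
        cols = ["sample_id"] + [f"p_{c}" for c in model.classes] + ["label"]
        return pd.DataFrame(columns=cols), summary
    if provenance is not None:
        if list(provenance.get("hk_genes", [])) != list(config.hk_genes):
            raise ValueError(
                "provenance mismatch: housekeeping genes differ from training "
                f"({provenance.get('hk_genes')} vs {list(config.hk_genes)})"
            )
        for t in provenance.get("transforms", []):
            if t["name"] == "filter_low_expression" and (
                t["cpm_cutoff"] != config.cpm_cutoff
                or t["frac_cutoff"] != config.frac_cutoff
            ):
                raise ValueError("provenance mismatch: filter parameters differ")
            if t["name"] == "log2_cpm" and t["prior"] != config.prior:
                raise ValueError("provenance mismatch: log2 CPM prior differs")

    norm = exprprep.prep_pipeline(
        counts,
        cpm_cutoff=config.cpm_cutoff,
        frac_cutoff=config.frac_cutoff,
        hk_genes=config.hk_genes,
        prior=config.prior,
    )
    missing = [g for g in model.gene_ids if g not in norm.values.index]
    if missing:
        raise ValueError(
            f"model genes absent from cohort after preparation: {missing[:10]}"
        )
    calls = nsc.call_phenotypes(model, norm.values, hi=config.hi, lo=config.lo)
    label_counts = calls["label"].value_counts().to_dict()
    all_labels = list(model.classes) + [nsc.UNCLASSIFIED]
    counts_out = {c: int(label_counts.get(c, 0)) for c in all_labels}
    n = len(calls)
    summary = {
        "n": n,
        "counts": counts_out,
        "fractions": {c: counts_out[c] / n for c in all_labels},
        "confident_fraction": 1.0 - counts_out[nsc.UNCLASSIFIED] / n,
    }
    return calls, summary
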