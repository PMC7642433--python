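# immunophen

Tumour-immune phenotype classification (infiltrated / excluded / desert)
from compartmental CD8 densities and bulk RNA-seq, exercised end-to-end
on synthetic cohorts with planted ground truth.

The pipeline:

1. **simdata** — synthetic cohorts (negative-binomial counts + CD8
   density tables + truth) and cartoon 2-channel IHC images
   (haematoxylin nuclei / DAB CD8 blobs) with per-pixel compartment
   truth masks.
2. **histoquant** — digital pathology: nucleus segmentation (watershed),
   tumour vs stroma compartments from nuclear shape/size (large + round
   → tumour; dilated tumour-nucleus disks → tumour compartment), DAB+
   CD8 counting per compartment.
3. **polar** — (tumour, stroma) densities → quantity `R = sqrt(t² + s²)`
   and spatial distribution `theta = atan2(s, t) ∈ [0, π/2]`.
4. **exprprep** — low-expression filter (CPM < 0.25 in ≥ 10% of
   samples), TMM size factors, log2 CPM (prior 0.5), housekeeping
   scaling (ACTB, ACTG1, HSP90AB1, UBC).
5. **geneselect** — one regression forest per gene
   (`expression ~ R + theta`, no predictor subsampling); out-of-bag
   permutation importance (% increase in MSE); drop the bottom quartile,
   partition the rest by per-metric third-quartile thresholds into
   quantity / distribution / both; signature = the two exclusive sets.
6. **consensus** — subsampled k-means consensus clustering (k = 6, 80%
   sample selection, Pearson distance via row standardization), final
   call by average-linkage on 1 − consensus, rule-based 6 → 3 merge
   using cluster-level mean (R, theta).
7. **nsc** — nearest-shrunken-centroid classifier with cross-validated
   shrinkage and a deployment confidence gate (posterior > 0.7 for the
   winner and < 0.5 for both others, else *unclassified*).
8. **workflow** — orchestration, JSON run manifest with digests and
   recovery metrics, master-seed fan-out.

## CLI

One umbrella command (`immunophen <subcommand>`) plus standalone
aliases. Typical session:

```sh
simulate-cohort --seed 1 --n-samples 150 --n-genes 2000 --out cohort/
run-all --seed 1 --out run/                 # simulate + full training pipeline
metrics  --densities cohort/densities.tsv --out metrics.tsv
prep     --counts cohort/counts.tsv --out prep/
select-genes --expr prep/normalized.tsv --metrics metrics.tsv --seed 1 --out sel/
cluster  --expr run/normalized.tsv --metrics metrics.tsv --k 6 --reps 1000 --seed 1 --out clus/
train    --expr sig.tsv --labels clus/labels.tsv --folds 10 --seed 1 --out model.json
classify --model model.json --expr new_normalized.tsv --out calls.tsv

simulate-ihc --seed 2 --out ihc/            # synthetic 2-channel image
quantify --image ihc/image.tif --pixel-size 0.5 --out quant/
```

`run-all` accepts a YAML config with `simdata:` and `pipeline:` sections
mirroring the CLI flags. All tables are TSV with headers; models,
manifests and truth sidecars are JSON; images are 2-channel TIFF with a
PNG preview and a {0 = background, 1 = stroma, 2 = tumour} mask PNG.

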