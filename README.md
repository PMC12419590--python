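# stmir

Spatially resolved miRNA activity prediction from mRNA expression profiles.

`stmir` learns per-miRNA regressors from two integrated paired bulk cohorts
(mRNA features, miRNA targets) and transfers them to spatial transcriptomics
spots, producing per-spot "predicted miRNA activity" with cell-type
attribution and downstream differential/correlation statistics.

## How it works

1. **Integration** (`stmir.datafusion`): both cohorts are restricted to
   shared features (near-all-zero features dropped), `log2(x+1)`-transformed,
   converted to intra-sample percentile ranks, mapped per feature through a
   rank-based inverse normal transform, concatenated by samples, and min-max
   scaled to `[0, 1]`. The rank steps make the result invariant to any
   strictly increasing per-sample distortion, removing monotone batch
   effects between cohorts.
2. **Regression** (`stmir.regression`): one gradient-boosted tree regressor
   per target miRNA (scikit-learn histogram gradient boosting), with an
   exhaustive grid search over learning rate / tree depth / number of
   estimators, seeded k-fold cross-validation, per-miRNA Spearman rho plus
   MSE/MAE/R² reporting, and baselines (ridge, lasso, random forest,
   feed-forward neural network).
3. **Spatial transfer** (`stmir.spatial`): Visium-style input (10x MTX
   triplet or HDF5 feature-barcode matrix) is QC-filtered (spot total-count
   cutoff, gene detection floor), total-count normalized, log10-transformed,
   re-encoded with the same rank → inverse-normal → min-max pipeline within
   the spatial dataset, and pushed through the trained model.
4. **Attribution** (`stmir.attribution`): an externally produced spot ×
   cell-type abundance matrix assigns each spot its dominant cell type
   (argmax with optional purity threshold; exact ties unassigned), and
   per-cell-type miRNA profiles (median activity, consistency, rank) plus
   cross-context conserved miRNA sets are derived.
5. **Statistics** (`stmir.diffstats`): Wilcoxon rank-sum differential
   activity with Benjamini-Hochberg FDR, Pearson miRNA-target correlation
   with the |r| > 0.3 / Bonferroni-adjusted p < 0.05 dual threshold, and
   hypergeometric gene-set enrichment from GMT files.
6. **Synthetic data** (`stmir.synthdata`): fully seeded generators for
   paired bulk cohorts (with monotone batch distortions and nonlinear
   miRNA-mRNA dependencies) and Poisson spot mixtures with known cell-type
   composition and latent activity — the test and demo input surface.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (batch-invariance
bit-identity, inverse-normal correctness, regression recovery on the
default synthetic generator, exact Wilcoxon/BH behavior, null FDR control,
QC fidelity, attribution recovery, hypergeometric exactness, determinism).

## CLI

```bash
# synthetic fixtures exercising the full input surface
stmir simulate --seed 7 --out fixtures/

stmir integrate \
  --cohort-a-mrna fixtures/cohortA_mrna.tsv --cohort-a-mirna fixtures/cohortA_mirna.tsv \
  --cohort-b-mrna fixtures/cohortB_mrna.tsv --cohort-b-mirna fixtures/cohortB_mirna.tsv \
  --out integrated.h5

stmir train --input integrated.h5 --seed 7 --out model.stmir
stmir benchmark --input integrated.h5 --out comparison.tsv

stmir predict-st --model model.stmir --visium fixtures/visium \
  --positions fixtures/positions.csv --max-counts 38000 \
  --min-cells-per-gene 10 --out activity.h5

stmir attribute --activity activity.h5 --abundance fixtures/abundance.csv \
  --min-purity 0.5 --out profiles.tsv

stmir diff --activity activity.h5 --labels labels.tsv --out diff.tsv
stmir corr --activity activity.h5 --expression st_expr.tsv \
  --pairs fixtures/pairs.tsv --out corr.tsv
stmir enrich --query query.txt --gmt fixtures/genesets.gmt \
  --universe universe.txt --out enrichment.tsv

# or the whole chain from a config file (per-stage caching included)
stmir run --config run.toml
```

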