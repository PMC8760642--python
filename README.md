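# stratacause

Stratified causal discovery for high-dimensional binary omics data.

## The problem

In pharmacogenomics and related settings, a positive outcome (say, an
adverse drug reaction) often arises through **several distinct biological
mechanisms**, each active only in a hidden subgroup — a *stratum* — of the
affected samples. A variant that causes the outcome in one stratum may be
absent everywhere else, so its association with the *global* outcome is
diluted and classical causal-discovery methods miss it. Stratified causal
discovery asks for both things at once: the strata of positive-outcome
samples, and for each stratum the features that potentially cause the
outcome there.

`stratacause` implements a five-phase pipeline for this problem on binary
inputs: a feature matrix `G ∈ {0,1}^{p×n}` (e.g. SNP presence indicators),
an outcome vector `R ∈ {−1,+1}^n`, an optional binary confounder matrix
`Z ∈ {0,1}^{m×n}`, and optional pathway gene sets (GMT):

1. **Grouping** — features are split into pathway-based groups
   `G_1 … G_D` (features in no pathway are discarded; without pathways,
   one group).
2. **Feature weighting** — per group, a supervised biclustering assigns
   each feature an outcome-relevance weight `W_d` while clustering
   features (haplotype-style blocks) and samples (strata) under a
   Bernoulli block model tempered by the weights.
3. **Filtering** — per group, outlier weights are promoted to candidate
   causes using the scaled median absolute deviation,
   `MAD_d = M(|W_d − M(W_d)|) / (√2 · erf⁻¹(½))`,
   selecting features with `w − M(W_d) > L·MAD_d` (default `L = 3`).
4. **Stratification** — the biclustering is re-run on the merged
   candidate set `C = ∪ C_d` to produce strata `P_1 … P_K` with
   homogeneous outcomes.
5. **Quasi-experimental design (QED)** — every candidate is tested
   against every positive stratum with a matched-pairs design: carriers
   ("treated") are paired with non-carriers that agree exactly on `Z` and
   are maximally similar on the other candidates (minimum-cost matching
   under the Manhattan distance, Hungarian algorithm); discordant pair
   counts `b, c` enter McNemar's test with Yates' correction,
   `χ² = (|b−c|−1)² / (b+c)`; and all p-values are pooled into an
   adaptive Benjamini–Hochberg step, with the number of true nulls `m0`
   estimated from the slope of the sorted p-value sequence.

The package also ships the synthetic-data generator used to validate the
method: features come in clusters with binomially distributed sizes whose
members share one presence pattern (haplotype blocks); a few clusters are
causal and coincide exactly with planted positive strata; pathways form by
rich-gets-richer assignment so each pathway is dominated by few clusters;
and a fixed fraction of matrix and outcome entries is flipped as noise.

## Worked example

```python
from stratacause import (SimulationParams, generate_dataset,
                         run_pipeline_arrays, precision_recall)
from stratacause.evaluation import positive_strata_rand

params = SimulationParams(
    n_features=2000, n_feature_clusters=50, n_pathways=5,
    n_positive_samples=40, n_causal_clusters=2, seed=7,
)
dataset, pathways, truth = generate_dataset(params)
result = run_pipeline_arrays(dataset, pathways, K=4, seed=7)

precision, recall = precision_recall(
    result.report.significant_features, truth.causal_features)
rand = positive_strata_rand(
    result.strat_fit.stratum_of_sample, truth, dataset.sample_ids)
print(f"candidates after filtering: {len(result.candidates)}")
print(f"hypotheses tested: {len(result.report.tuples)}  "
      f"(estimated true nulls m0 = {result.report.m0_estimate})")
print(f"significant features: {len(result.report.significant_features)}")
print(f"precision = {precision:.3f}  recall = {recall:.3f}  "
      f"Rand index vs planted strata = {rand:.3f}")
```

prints

```
candidates after filtering: 81
hypotheses tested: 243  (estimated true nulls m0 = 183)
significant features: 75
precision = 1.000  recall = 0.926  Rand index vs planted strata = 0.906
```

Of the 2000 features, 81 survive the per-pathway MAD filter; each is
tested against each of the three positive-majority strata (243
hypotheses). 75 features pass the adaptive-FDR step at q = 0.05 — all of
them truly causal (precision 1.0), covering 92.6% of the planted causal
features — and the learned strata agree with the planted ones on 90.6% of
positive sample pairs.

The same run is available from the shell:

```sh
stratacause simulate --config sim.yaml --out data/ --seed 7
stratacause run --g data/G.tsv --r data/R.tsv --gmt data/pathways.gmt \
                --out results/ --seed 7
stratacause benchmark --config grid.yaml --out bench.tsv
```

`run` writes the causal report (feature, stratum, discordant counts,
p-value, decision), the strata table, per-feature weights, the discard and
skip logs, and a manifest with per-phase counts.

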