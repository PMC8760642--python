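"""Metrics and the synthetic benchmark harness.

Stratification quality is scored with the Rand index against the planted
strata (over the truly positive samples, where the truth is defined);
causal-feature discovery with precision/recall of the features appearing
in at least one significant (feature, stratum) tuple.  The benchmark
varies one generation parameter at a time with the others at their
defaults, and optionally runs two ablated QED settings on the same
filtered candidates: (1) unstratified QED against the global outcome and
(2) QED supplied with the ground-truth strata.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .core import OmicsDataset
from .qed import run_qed
from .simulate import SimulationParams, SyntheticTruth, generate_dataset

logger = logging.getLogger(__name__)


def rand_index(labels_a, labels_b) -> float:
    """Fraction of unordered sample pairs on which two labelings agree."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        return 1.0
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return (x * (x - 1) / 2.0).sum()

    total = n * (n - 1) / 2.0
    same_same = comb2(cont)
    agree = total + 2.0 * same_same - comb2(cont.sum(axis=1)) - comb2(cont.sum(axis=0))
    return float(agree / total)


def precision_recall(predicted: set, true: set) -> tuple[float, float]:
    """Precision and recall of predicted causal features.

    An empty prediction set yields precision 1 by convention (logged);
    recall requires a non-empty truth set.
    """
    predicted, true = set(predicted), set(true)
    if not true:
        raise ValueError("true causal feature set must be non-empty")
    hits = len(predicted & true)
    if not predicted:
        logger.info("empty prediction set; precision defined as 1")
        precision = 1.0
    else:
        precision = hits / len(predicted)
    return precision, hits / len(true)


def positive_strata_rand(fit_labels: np.ndarray, truth: SyntheticTruth, sample_ids) -> float:
    """Rand index between learned and planted strata, over true positives."""
    true_labels = truth.strata_labels(list(sample_ids))
    mask = true_labels >= 0
    return rand_index(np.asarray(fit_labels)[mask], true_labels[mask])


def truth_strata_arrays(truth: SyntheticTruth, dataset: OmicsDataset):
    """Ground-truth stratum labels as a full-sample vector for QED.

    Planted strata keep their indices 0..K-1; all remaining samples share
    one background stratum K.  Returns ``(labels, positive_strata)``.
    """
    labels = truth.strata_labels(dataset.sample_ids)
    k_bg = len(truth.causal_clusters)
    labels = np.where(labels < 0, k_bg, labels)
    return labels, list(range(k_bg))


def run_benchmark(
    base_params: SimulationParams | None = None,
    vary: dict | None = None,
    seeds=(0, 1, 2),
    scale_factor: int = 10,
    ablations: bool = False,
    K: int | None = None,
    pipeline_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Run the pipeline over a one-at-a-time parameter grid.

    Returns a long-format table with one row per (cell, seed) holding the
    Rand index, precision and recall (and ablation metrics when
    requested).  Results are bit-reproducible given (grid, seeds,
    scale_factor).
    """
    from .pipeline import run_pipeline_arrays  # local import to avoid a cycle

    base_params = base_params or SimulationParams()
    vary = vary if vary is not None else {
        "n_causal_clusters": [2, 3, 4, 5],
        "outcome_noise": [0.0, 0.05, 0.1, 0.2],
        "n_positive_samples": [75, 100, 125, 150],
    }
    pipeline_kwargs = pipeline_kwargs or {}

    cells: list[tuple[str, SimulationParams]] = [("defaults", base_params)]
    seen = {(base_params.n_causal_clusters, base_params.outcome_noise,
             base_params.n_positive_samples)}
    for name, values in vary.items():
        for v in values:
            cell = replace(base_params, **{name: v})
            key = (cell.n_causal_clusters, cell.outcome_noise, cell.n_positive_samples)
            if key in seen:
                continue
            seen.add(key)
            cells.append((f"{name}={v}", cell))

    rows = []
    for cell_name, cell in cells:
        params = cell.scaled(scale_factor) if scale_factor > 1 else cell
        for seed in seeds:
            params_s = replace(params, seed=int(seed))
            dataset, pathways, truth = generate_dataset(params_s)
            # one stratum per planted mechanism, one residual stratum for
            # noise-affected positives, one negative background stratum
            k_run = K if K is not None else params_s.n_causal_clusters + 2
            result = run_pipeline_arrays(
                dataset, pathways, K=k_run, seed=int(seed), **pipeline_kwargs,
            )
            precision, recall = precision_recall(
                result.report.significant_features, truth.causal_features
            )
            row = {
                "cell": cell_name,
                "n_causal_clusters": params_s.n_causal_clusters,
                "outcome_noise": params_s.outcome_noise,
                "n_positive_samples": params_s.n_positive_samples,
                "seed": int(seed),
                "rand_index": positive_strata_rand(
                    result.strat_fit.stratum_of_sample, truth, dataset.sample_ids
                ),
                "precision": precision,
                "recall": recall,
                "n_candidates": len(result.candidates),
            }
            if ablations:
                rep1 = run_qed(
                    dataset.G, result.candidates, dataset.feature_ids,
                    strata=result.strat_fit.stratum_of_sample,
                    positive_strata=[], R=dataset.R, Z=dataset.Z,
                    sample_ids=dataset.sample_ids, q=result.report.q_level,
                    stratified=False,
                )
                p1, r1 = precision_recall(rep1.significant_features, truth.causal_features)
                labels, pos_k = truth_strata_arrays(truth, dataset)
                rep2 = run_qed(
                    dataset.G, result.candidates, dataset.feature_ids,
                    strata=labels, positive_strata=pos_k,
                    R=dataset.R, Z=dataset.Z,
                    sample_ids=dataset.sample_ids, q=result.report.q_level,
                )
                p2, r2 = precision_recall(rep2.significant_features, truth.causal_features)
                row.update(
                    precision_unstratified=p1, recall_unstratified=r1,
                    precision_truth_strata=p2, recall_truth_strata=r2,
                )
            rows.append(row)
            logger.info("benchmark cell %s seed %d: %s", cell_name, seed, row)
    return pd.DataFrame(rows)
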