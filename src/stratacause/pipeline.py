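"""End-to-end orchestration of the five pipeline phases.

grouping -> per-group supervised biclustering -> MAD filtering -> merge ->
stratification -> matched-pairs QED.  Phase outputs are pure functions of
(inputs, config, seed); per-group fits use seeds derived from the group
index so execution order cannot change results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bicluster import BiclusterFit, BiclusterHyper, fit_bicluster, select_k, stratify
from .core import CausalReport, OmicsDataset, PathwayCollection
from .filtering import merge_candidates, select_outlier_features
from .grouping import group_features
from .qed import run_qed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """User-facing configuration of a pipeline run.

    ``K`` is the stratum count for the stratification phase (``None``
    selects it by held-out outcome likelihood over ``k_grid``); ``L`` the
    MAD multiplier of the filtering phase; ``q`` the FDR level;
    ``min_prevalence`` the smallest treated-sample count a candidate needs
    to be tested.
    """

    K: int | None = None
    group_K: int | None = None          # strata per feature-group fit; defaults to K
    L: float = 3.0
    q: float = 0.05
    min_prevalence: int = 5
    seed: int = 0
    k_grid: tuple = (2, 3, 4, 5, 6)
    exclude_other_positive: bool = False
    hyper: BiclusterHyper = field(default_factory=BiclusterHyper)


@dataclass
class PipelineResult:
    candidates: np.ndarray               # dataset feature indices
    candidate_ids: list[str]
    report: CausalReport
    strat_fit: BiclusterFit
    group_names: list[str]
    group_selections: dict[str, list[str]]
    discarded: list[str]
    weights: dict[str, float]            # per-feature weight within its group
    manifest: dict


def _group_seed(seed: int, index: int) -> int:
    return int((seed * 1_000_003 + index) % (2**31 - 1))


def run_pipeline_arrays(
    dataset: OmicsDataset,
    pathways: PathwayCollection | None,
    K: int | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
    **overrides,
) -> PipelineResult:
    """Run all phases on in-memory inputs and return the full result."""
    if config is None:
        config = PipelineConfig(K=K, seed=seed, **overrides)
    groups, names, discarded = group_features(dataset, pathways)
    logger.info("phase 1: %d groups, %d features discarded", len(groups), len(discarded))

    group_k = config.group_K or config.K
    selections: list[np.ndarray] = []
    group_selections: dict[str, list[str]] = {}
    weights: dict[str, float] = {}
    for gi, (name, idx) in enumerate(zip(names, groups)):
        sub = dataset.G[idx]
        k_g = group_k or max(2, min(4, sub.shape[1]))
        fit = fit_bicluster(
            sub, dataset.R, K=min(k_g, sub.shape[1]),
            hyper=config.hyper, seed=_group_seed(config.seed, gi),
            sample_ids=dataset.sample_ids,
            feature_ids=[dataset.feature_ids[i] for i in idx],
        )
        sel_local = select_outlier_features(fit.weights, L=config.L)
        selections.append(idx[sel_local])
        group_selections[name] = [dataset.feature_ids[i] for i in idx[sel_local]]
        for i, wv in zip(idx, fit.weights):
            fid = dataset.feature_ids[i]
            weights[fid] = max(weights.get(fid, 0.0), float(wv))
    candidates = merge_candidates(selections)
    candidate_ids = [dataset.feature_ids[i] for i in candidates]
    logger.info("phases 2-3: %d candidate features", len(candidates))

    K_strat = config.K
    if K_strat is None:
        K_strat = select_k(
            dataset.G[candidates], dataset.R,
            k_grid=config.k_grid, hyper=config.hyper, seed=config.seed,
        )
        logger.info("phase 4: selected K=%d by held-out outcome likelihood", K_strat)
    strat_fit = stratify(
        dataset.G[candidates], dataset.R, K=K_strat,
        hyper=config.hyper, seed=config.seed,
        sample_ids=dataset.sample_ids, feature_ids=candidate_ids,
    )
    logger.info(
        "phase 4: strata sizes %s, positive strata %s",
        np.bincount(strat_fit.stratum_of_sample, minlength=K_strat).tolist(),
        strat_fit.positive_strata,
    )

    report = run_qed(
        dataset.G, candidates, dataset.feature_ids,
        strata=strat_fit.stratum_of_sample,
        positive_strata=strat_fit.positive_strata,
        R=dataset.R, Z=dataset.Z, sample_ids=dataset.sample_ids,
        q=config.q, min_prevalence=config.min_prevalence,
        exclude_other_positive=config.exclude_other_positive,
    )
    logger.info(
        "phase 5: %d hypotheses, m0=%d, %d significant tuples, %d skips",
        len(report.tuples), report.m0_estimate,
        len(report.significant_pairs()), len(report.skips),
    )

    cfg = asdict(config)
    cfg["hyper"] = asdict(config.hyper)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "n_features_in": dataset.n_features,
        "n_samples": dataset.n_samples,
        "n_groups": len(groups),
        "n_discarded": len(discarded),
        "n_candidates": int(candidates.size),
        "K": int(K_strat),
        "strata_sizes": np.bincount(strat_fit.stratum_of_sample, minlength=K_strat).tolist(),
        "positive_strata": strat_fit.positive_strata,
        "n_hypotheses": len(report.tuples),
        "m0_estimate": report.m0_estimate,
        "n_significant": len(report.significant_pairs()),
        "n_skipped": len(report.skips),
    }
    return PipelineResult(
        candidates=candidates,
        candidate_ids=candidate_ids,
        report=report,
        strat_fit=strat_fit,
        group_names=names,
        group_selections=group_selections,
        discarded=discarded,
        weights=weights,
        manifest=manifest,
    )


def write_result(result: PipelineResult, dataset: OmicsDataset, out_dir) -> dict[str, Path]:
    """Write all phase artifacts as TSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["report"] = out / "causal_report.tsv"
    pd.DataFrame(
        [
            {
                "feature_id": t.feature_id, "stratum": t.stratum,
                "b": t.b, "c": t.c, "n_pairs": t.n_pairs,
                "statistic": t.statistic, "p": t.raw_p, "significant": t.significant,
            }
            for t in result.report.tuples
        ]
    ).to_csv(paths["report"], sep="\t", index=False)

    paths["strata"] = out / "strata.tsv"
    pd.DataFrame({
        "sample_id": dataset.sample_ids,
        "stratum": result.strat_fit.stratum_of_sample,
        "outcome": dataset.R,
    }).to_csv(paths["strata"], sep="\t", index=False)

    paths["weights"] = out / "feature_weights.tsv"
    pd.DataFrame(
        sorted(result.weights.items()), columns=["feature_id", "weight"]
    ).to_csv(paths["weights"], sep="\t", index=False)

    paths["candidates"] = out / "candidates.tsv"
    pd.DataFrame({"feature_id": result.candidate_ids}).to_csv(
        paths["candidates"], sep="\t", index=False
    )

    paths["discard_log"] = out / "discarded_features.tsv"
    pd.DataFrame({"feature_id": result.discarded}).to_csv(
        paths["discard_log"], sep="\t", index=False
    )

    paths["skips"] = out / "skipped_candidates.tsv"
    pd.DataFrame(
        sorted(result.report.skips.items()), columns=["feature_id", "reason"]
    ).to_csv(paths["skips"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    return paths
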