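"""Phase 1: split the feature set into pathway-based groups.

Features that belong to no pathway are discarded from all downstream
phases (they are reported so the discard is auditable).  When no pathway
knowledge is available the problem either stays in a single group, or is
split randomly into balanced groups.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import OmicsDataset, PathwayCollection

logger = logging.getLogger(__name__)


def group_features(
    dataset: OmicsDataset,
    pathways: PathwayCollection | None,
) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Map pathways onto dataset feature indices.

    Returns ``(groups, group_names, discarded)`` where each group is an
    array of feature indices (dataset order) restricted to features the
    dataset actually contains.  Pathways matching zero dataset features are
    dropped with a warning.  Without pathways, a single group holds all
    features and nothing is discarded.
    """
    if pathways is None:
        logger.info("no pathway collection supplied; using one group of all features")
        return [np.arange(dataset.n_features)], ["all_features"], []

    index_of = {fid: i for i, fid in enumerate(dataset.feature_ids)}
    groups: list[np.ndarray] = []
    names: list[str] = []
    covered: set[str] = set()
    for name, members in pathways:
        idx = sorted(index_of[f] for f in members if f in index_of)
        if not idx:
            logger.warning("pathway %r matches no dataset feature; dropped", name)
            continue
        groups.append(np.asarray(idx, dtype=np.int64))
        names.append(name)
        covered.update(dataset.feature_ids[i] for i in idx)
    discarded = [f for f in dataset.feature_ids if f not in covered]
    if discarded:
        logger.info("%d features belong to no pathway and are discarded", len(discarded))
    return groups, names, discarded


def random_grouping(
    n_features: int, n_groups: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Balanced, uniformly random disjoint partition of the features."""
    if n_groups < 1:
        raise ValueError("n_groups must be positive")
    perm = rng.permutation(n_features)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_groups)]
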