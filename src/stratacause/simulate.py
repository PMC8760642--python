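"""Synthetic binary omics data with planted strata and causal feature clusters.

The generator emulates haplotype-block structure: features come in clusters
whose members share one presence pattern across samples; cluster sizes are
binomially distributed around ``n_features / n_feature_clusters``.  A few
clusters are *causal*: each is present exactly on one hidden stratum of
positive-outcome samples (one-to-one cluster/stratum correspondence), so a
causal feature predicts the outcome only within its stratum.  The remaining
clusters are present on random sample subsets.  Pathways form a second
grouping layer built by preferential attachment, so each pathway is
dominated by few clusters (low cluster-label entropy).  Finally a fixed
fraction of matrix and outcome entries is flipped as noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import OmicsDataset, PathwayCollection


@dataclass
class SimulationParams:
    """Generation parameters; defaults are the reference study conditions."""

    n_features: int = 100_000
    n_feature_clusters: int = 2_500
    n_pathways: int = 100
    feature_noise: float = 0.05
    positive_fraction: float = 0.2
    n_causal_clusters: int = 3
    outcome_noise: float = 0.05
    n_positive_samples: int = 100
    pathway_alpha: float = 0.001
    m_confounders: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("feature_noise", "outcome_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if not 0.0 < self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in (0, 1]")
        if self.n_feature_clusters > self.n_features:
            raise ValueError("more feature clusters than features")
        if self.n_causal_clusters > self.n_feature_clusters:
            raise ValueError("more causal clusters than feature clusters")
        if self.n_positive_samples < self.n_causal_clusters:
            raise ValueError("need at least one positive sample per stratum")
        if self.n_pathways < 1 or self.n_pathways > self.n_features:
            raise ValueError("n_pathways must be in [1, n_features]")
        if self.pathway_alpha < 0:
            raise ValueError("pathway_alpha must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.n_positive_samples / self.positive_fraction))

    def scaled(self, factor: int) -> "SimulationParams":
        """Shrink the feature dimension uniformly, keeping sample counts.

        Features, feature clusters and pathways are all divided by
        ``factor`` so cluster and pathway sizes stay at reference scale.
        """
        return replace(
            self,
            n_features=self.n_features // factor,
            n_feature_clusters=self.n_feature_clusters // factor,
            n_pathways=max(1, self.n_pathways // factor),
        )


@dataclass
class SyntheticTruth:
    """Ground truth retained for evaluating a pipeline run."""

    cluster_of_feature: np.ndarray           # (p,) cluster index per feature
    causal_clusters: list[int]               # stratum k <-> causal_clusters[k]
    stratum_of_sample: dict[str, int]        # positive sample id -> stratum
    causal_features: set[str]
    pre_noise_G: np.ndarray
    pre_noise_R: np.ndarray
    params: SimulationParams = field(repr=False, default=None)

    def strata_labels(self, sample_ids: list[str]) -> np.ndarray:
        """True stratum per sample (-1 for samples outside any stratum)."""
        return np.array([self.stratum_of_sample.get(s, -1) for s in sample_ids])


def sample_cluster_sizes(n_features: int, n_clusters: int, rng: np.random.Generator) -> np.ndarray:
    """Integer partition of ``n_features`` with binomial spread.

    Sizes are drawn Binomial(2*floor(n_features/n_clusters), 0.5), clamped
    to at least one, then rescaled to sum exactly to ``n_features`` by the
    largest-remainder rule.
    """
    if n_clusters > n_features:
        raise ValueError("n_clusters may not exceed n_features")
    if n_clusters < 1:
        raise ValueError("n_clusters must be positive")
    mean = n_features // n_clusters
    draws = rng.binomial(2 * mean, 0.5, size=n_clusters).astype(float)
    draws = np.maximum(draws, 1.0)
    scaled = draws * (n_features / draws.sum())
    sizes = np.maximum(np.floor(scaled).astype(np.int64), 1)
    diff = n_features - sizes.sum()
    if diff > 0:
        order = np.argsort(-(scaled - np.floor(scaled)), kind="stable")
        i = 0
        while diff > 0:
            sizes[order[i % n_clusters]] += 1
            diff -= 1
            i += 1
    elif diff < 0:
        order = np.argsort(-sizes, kind="stable")
        i = 0
        while diff < 0:
            j = order[i % n_clusters]
            if sizes[j] > 1:
                sizes[j] -= 1
                diff += 1
            i += 1
    return sizes


def assign_pathways(
    cluster_of_feature: np.ndarray,
    n_pathways: int,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign each feature to one pathway by preferential attachment.

    Each pathway is seeded with one random feature; the remaining features
    are visited in random order and feature ``j`` joins pathway ``X`` with
    probability proportional to
    ``(members of X from cluster(j) + alpha) / (|X| + alpha * n_clusters)``.
    Small ``alpha`` concentrates each pathway on few clusters; as
    ``alpha`` grows the assignment approaches uniform.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be positive")
    cluster_of_feature = np.asarray(cluster_of_feature)
    p = cluster_of_feature.shape[0]
    if n_pathways > p:
        raise ValueError("more pathways than features")
    n_clusters = int(cluster_of_feature.max()) + 1
    pathway_of_feature = np.full(p, -1, dtype=np.int64)
    counts = np.zeros((n_pathways, n_clusters))   # pathway x cluster membership
    sizes = np.zeros(n_pathways)

    order = rng.permutation(p)
    seeds, rest = order[:n_pathways], order[n_pathways:]
    for x, j in enumerate(seeds):
        pathway_of_feature[j] = x
        counts[x, cluster_of_feature[j]] += 1
        sizes[x] += 1
    denom_alpha = alpha * n_clusters
    for j in rest:
        c = cluster_of_feature[j]
        w = (counts[:, c] + alpha) / (sizes + denom_alpha)
        total = w.sum()
        if total <= 0:     # alpha == 0 and no pathway holds cluster c yet
            w = 1.0 / sizes
            total = w.sum()
        x = rng.choice(n_pathways, p=w / total)
        pathway_of_feature[j] = x
        counts[x, c] += 1
        sizes[x] += 1
    return pathway_of_feature


def _flip_entries(a: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Flip round(fraction * a.size) entries, chosen uniformly without replacement."""
    n_flip = int(round(fraction * a.size))
    out = a.copy()
    if n_flip == 0:
        return out
    idx = rng.choice(a.size, size=n_flip, replace=False)
    flat = out.reshape(-1)
    flat[idx] = 1 - flat[idx] if np.isin(a, (0, 1)).all() else -flat[idx]
    return out


def generate_dataset(
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[OmicsDataset, PathwayCollection, SyntheticTruth]:
    """Generate one dataset plus pathway collection and ground truth.

    Fully deterministic given ``params.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p, n = params.n_features, params.n_samples
    n_pos, K = params.n_positive_samples, params.n_causal_clusters

    sizes = sample_cluster_sizes(p, params.n_feature_clusters, rng)
    cluster_of_feature = rng.permutation(np.repeat(np.arange(params.n_feature_clusters), sizes))

    positive_idx = rng.choice(n, size=n_pos, replace=False)
    R_clean = np.full(n, -1, dtype=np.int8)
    R_clean[positive_idx] = 1

    # near-equal partition of the positives into K strata
    shuffled = rng.permutation(positive_idx)
    strata = np.array_split(shuffled, K)
    stratum_of_idx = {int(i): k for k, members in enumerate(strata) for i in members}

    causal_clusters = [int(c) for c in rng.choice(params.n_feature_clusters, size=K, replace=False)]
    G_clean = np.zeros((p, n), dtype=np.int8)
    presence = np.zeros((params.n_feature_clusters, n), dtype=bool)
    for k, c in enumerate(causal_clusters):
        presence[c, strata[k]] = True
    noncausal = np.setdiff1d(np.arange(params.n_feature_clusters), causal_clusters)
    prevalence = rng.uniform(0.05, 0.5, size=noncausal.shape[0])
    for c, u in zip(noncausal, prevalence):
        presence[c] = rng.random(n) < u
    G_clean[:] = presence[cluster_of_feature]

    pathway_of_feature = assign_pathways(
        cluster_of_feature, params.n_pathways, params.pathway_alpha, rng
    )

    G = _flip_entries(G_clean, params.feature_noise, rng)
    R = _flip_entries(R_clean, params.outcome_noise, rng)

    if params.m_confounders:
        Z = (rng.random((params.m_confounders, n)) < 0.5).astype(np.int8)
        confounder_ids = [f"z{i}" for i in range(params.m_confounders)]
    else:
        Z = np.zeros((0, n), dtype=np.int8)
        confounder_ids = []

    width_f, width_s = len(str(p - 1)), len(str(n - 1))
    feature_ids = [f"f{i:0{width_f}d}" for i in range(p)]
    sample_ids = [f"s{i:0{width_s}d}" for i in range(n)]

    dataset = OmicsDataset(
        G=G, R=R, Z=Z,
        feature_ids=feature_ids, sample_ids=sample_ids, confounder_ids=confounder_ids,
    )
    names = [f"pw{x}" for x in range(params.n_pathways)]
    groups = [set() for _ in range(params.n_pathways)]
    for j, x in enumerate(pathway_of_feature):
        groups[x].add(feature_ids[j])
    keep = [i for i, g in enumerate(groups) if g]
    pathways = PathwayCollection(names=[names[i] for i in keep], groups=[groups[i] for i in keep])

    causal_mask = np.isin(cluster_of_feature, causal_clusters)
    truth = SyntheticTruth(
        cluster_of_feature=cluster_of_feature,
        causal_clusters=causal_clusters,
        stratum_of_sample={sample_ids[i]: k for i, k in stratum_of_idx.items()},
        causal_features={feature_ids[j] for j in np.flatnonzero(causal_mask)},
        pre_noise_G=G_clean,
        pre_noise_R=R_clean,
        params=params,
    )
    return dataset, pathways, truth
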