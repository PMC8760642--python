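"""Supervised biclustering: sample strata, feature clusters, feature weights.

The model is a Bernoulli block model with an outcome term.  Features carry
cluster labels, samples carry stratum labels, and every (feature cluster,
stratum) block has its own Bernoulli presence probability with a
symmetric Beta prior.  Each stratum additionally has a Beta-Bernoulli
outcome probability, scaled by an outcome-sharpness factor so strata are
outcome-homogeneous whenever the data allow it.  Per-feature weights in
[0, 1] temper each feature's likelihood contribution, so features that
carry no information about the outcome barely influence the strata.

Weights are the square root of the feature/outcome uncertainty
coefficient, i.e. of the feature's share of the outcome entropy explained:
``w_j = sqrt(I(g_j; R) / H(R))``.  This is the (normalised) gain in
outcome predictive log-likelihood contributed by observing feature j
alone, which makes causal features rise above the indifferent bulk while
leaving constant features at (near) zero weight.

Fitting is iterated conditional modes: closed-form MAP updates of the
block and outcome probabilities alternate with argmax reassignment of
feature clusters and sample strata, so the penalised complete-data
log-likelihood is non-decreasing sweep over sweep.  To make the fit
equivariant under input permutations, samples and features are reordered
internally into a canonical (id-sorted) order before any random choice is
made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


class NoPositiveStratumError(RuntimeError):
    """Raised when stratification yields no positive-majority stratum."""


@dataclass
class BiclusterHyper:
    """Tunable knobs of the block model.

    ``n_feature_clusters`` defaults to ``round(sqrt(p))``.  ``theta_prior``
    and ``phi_prior`` are the symmetric Beta parameters of block presence
    and stratum outcome probabilities (both > 1 so MAP estimates stay
    interior).  ``outcome_weight`` scales the outcome log-likelihood
    against the feature term; ``None`` picks ``1 + 0.5 * sum(weights)`` so
    the outcome counts as much as half the effective feature mass.
    """

    n_feature_clusters: int | None = None
    theta_prior: float = 1.5
    phi_prior: float = 2.0
    outcome_weight: float | None = None
    weight_floor: float = 0.01
    max_sweeps: int = 200
    tol: float = 1e-6


@dataclass
class BiclusterFit:
    stratum_of_sample: np.ndarray          # (n,) in {0..K-1}
    cluster_of_feature: np.ndarray         # (p,)
    weights: np.ndarray                    # (p,) in [0, 1]
    K: int
    loglik_trace: list[float]
    stratum_outcome: np.ndarray            # (K,) majority outcome in {-1, +1}
    sample_ids: list[str] | None = None
    feature_ids: list[str] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def positive_strata(self) -> list[int]:
        return [int(k) for k in np.flatnonzero(self.stratum_outcome == 1)]


def outcome_relevance_weights(G: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Per-feature outcome relevance, signed and mapped to [0, 1].

    The magnitude is the square root of the uncertainty coefficient
    ``I(g_j; R) / H(R)`` (the feature's share of the outcome entropy, i.e.
    its normalised contribution to the outcome predictive log-likelihood);
    the sign is the direction of the feature/outcome association.  Mapping
    ``(1 + s_j * sqrt(U_j)) / 2`` centres outcome-indifferent features at
    0.5 with an approximately normal spread under independence — the
    regime in which a median + L*MAD outlier boundary has its nominal
    normal-tail pass rate — while features predictive of the positive
    outcome stand out towards 1.  Constant features carry no information
    about the outcome and are pinned to weight 0.  Returns zeros when the
    outcome itself is constant.
    """
    G = np.asarray(G)
    R = np.asarray(R)
    n = R.shape[0]
    n_pos = int((R == 1).sum())
    if n_pos in (0, n):
        return np.zeros(G.shape[0])
    # 2x2 joint counts per feature
    a = (G[:, R == 1] == 1).sum(axis=1).astype(float)    # g=1, r=+
    b = (G[:, R != 1] == 1).sum(axis=1).astype(float)    # g=1, r=-
    c = n_pos - a
    d = (n - n_pos) - b
    counts = np.stack([a, b, c, d], axis=1)
    p_joint = counts / n
    p_g1 = (a + b) / n
    p_g = np.stack([p_g1, p_g1, 1 - p_g1, 1 - p_g1], axis=1)
    p_r = np.array([n_pos, n - n_pos, n_pos, n - n_pos], dtype=float)[None, :] / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p_joint * np.log(p_joint / (p_g * p_r))
    terms[~np.isfinite(terms)] = 0.0
    mi = np.clip(terms.sum(axis=1), 0.0, None)
    h_r = -(n_pos / n) * np.log(n_pos / n) - ((n - n_pos) / n) * np.log((n - n_pos) / n)
    mag = np.sqrt(np.clip(mi / h_r, 0.0, 1.0))
    sign = np.sign(a * d - b * c)                        # direction of association
    w = 0.5 * (1.0 + sign * mag)
    w[(p_g1 == 0) | (p_g1 == 1)] = 0.0                   # constant features
    return w


def tempering_exponents(weights: np.ndarray, floor: float = 0.01) -> np.ndarray:
    """Likelihood-tempering exponents derived from the relevance weights.

    The positive excess over the null centre, ``clip(2w - 1, floor, 1)``:
    outcome-indifferent and protective features contribute only a floor's
    worth of likelihood, positively predictive features up to full
    strength.
    """
    return np.clip(2.0 * np.asarray(weights) - 1.0, floor, 1.0)


def _init_strata(
    Gw: np.ndarray, R: np.ndarray, K: int, seed: int
) -> np.ndarray:
    """Outcome-stratified initial strata: negatives and positives are split
    separately with k-means on weighted profiles, positives receiving the
    larger share of strata."""
    n = R.shape[0]
    pos = np.flatnonzero(R == 1)
    neg = np.flatnonzero(R != 1)
    s = np.zeros(n, dtype=np.int64)
    if len(pos) == 0 or len(neg) == 0:
        X = Gw.T
        k = min(K, n)
        s[:] = KMeans(n_clusters=k, n_init=2, random_state=seed).fit_predict(X)
        return s
    k_pos = min(K - 1, len(pos))
    k_neg = min(K - k_pos, len(neg))
    if k_pos == 1:
        s[pos] = 0
    else:
        s[pos] = KMeans(n_clusters=k_pos, n_init=2, random_state=seed).fit_predict(Gw[:, pos].T)
    if k_neg == 1:
        s[neg] = k_pos
    else:
        s[neg] = k_pos + KMeans(
            n_clusters=k_neg, n_init=2, random_state=seed + 1
        ).fit_predict(Gw[:, neg].T)
    return s


def _map_theta(N1, Wc, n_k, a):
    denom = Wc[:, None] * n_k[None, :] + 2.0 * (a - 1.0)
    theta = np.full(N1.shape, 0.5)
    ok = denom > 0
    theta[ok] = (N1[ok] + (a - 1.0)) / denom[ok]
    return np.clip(theta, 1e-12, 1 - 1e-12)


def fit_bicluster(
    G_sub: np.ndarray,
    R: np.ndarray,
    K: int,
    hyper: BiclusterHyper | None = None,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> BiclusterFit:
    """Fit the tempered block model; deterministic under a fixed seed.

    Raises ``ValueError`` when ``K`` exceeds the sample count or is < 2.
    """
    hyper = hyper or BiclusterHyper()
    G_sub = np.asarray(G_sub, dtype=np.int8)
    R = np.asarray(R)
    p, n = G_sub.shape
    if p == 0 or n == 0:
        raise ValueError("empty matrix")
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")

    # canonical internal order -> equivariance under input permutations
    s_order = np.argsort(np.asarray(sample_ids)) if sample_ids is not None else np.arange(n)
    f_order = np.argsort(np.asarray(feature_ids)) if feature_ids is not None else np.arange(p)
    G = np.asarray(G_sub, dtype=np.float64)[np.ix_(f_order, s_order)]
    Rc = R[s_order]

    w_rel = outcome_relevance_weights(G, Rc)
    w = tempering_exponents(w_rel, floor=hyper.weight_floor)
    lam = hyper.outcome_weight if hyper.outcome_weight is not None else 1.0 + 0.5 * w.sum()
    F = hyper.n_feature_clusters or max(2, int(round(np.sqrt(p))))
    F = min(F, p)

    rpos = (Rc == 1).astype(np.float64)
    Gw = w[:, None] * G

    if F == 1:
        c = np.zeros(p, dtype=np.int64)
    else:
        c = KMeans(n_clusters=F, n_init=2, random_state=seed).fit_predict(G)
    s = _init_strata(Gw, Rc, K, seed)

    a_th, a_ph = hyper.theta_prior, hyper.phi_prior
    trace: list[float] = []
    prev = -np.inf
    for sweep in range(hyper.max_sweeps):
        # ---- MAP parameters given assignments
        S = np.zeros((n, K))
        S[np.arange(n), s] = 1.0
        n_k = S.sum(axis=0)
        C1 = G @ S                                   # (p, K) per-feature counts
        N1 = np.zeros((F, K))
        np.add.at(N1, c, w[:, None] * C1)
        Wc = np.bincount(c, weights=w, minlength=F)
        theta = _map_theta(N1, Wc, n_k, a_th)
        pos_k = rpos @ S
        phi = np.clip((pos_k + (a_ph - 1.0)) / (n_k + 2.0 * (a_ph - 1.0)), 1e-12, 1 - 1e-12)

        logt, log1mt = np.log(theta), np.log1p(-theta)

        # ---- reassign feature clusters (weights cancel in the argmax)
        score_f = C1 @ logt.T + (n_k[None, :] - C1) @ log1mt.T
        c = np.argmax(score_f, axis=1)
        N1 = np.zeros((F, K))
        np.add.at(N1, c, w[:, None] * C1)
        Wc = np.bincount(c, weights=w, minlength=F)
        theta = _map_theta(N1, Wc, n_k, a_th)
        logt, log1mt = np.log(theta), np.log1p(-theta)

        # ---- reassign sample strata
        M1 = np.zeros((F, n))
        np.add.at(M1, c, Gw)
        score_s = M1.T @ (logt - log1mt) + (Wc @ log1mt)[None, :]
        score_s = score_s + lam * (
            rpos[:, None] * np.log(phi)[None, :]
            + (1.0 - rpos)[:, None] * np.log1p(-phi)[None, :]
        )
        s = np.argmax(score_s, axis=1)

        # ---- penalised complete-data log-likelihood
        S = np.zeros((n, K))
        S[np.arange(n), s] = 1.0
        n_k = S.sum(axis=0)
        C1 = G @ S
        N1 = np.zeros((F, K))
        np.add.at(N1, c, w[:, None] * C1)
        theta = _map_theta(N1, Wc, n_k, a_th)
        pos_k = rpos @ S
        phi = np.clip((pos_k + (a_ph - 1.0)) / (n_k + 2.0 * (a_ph - 1.0)), 1e-12, 1 - 1e-12)
        logt, log1mt = np.log(theta), np.log1p(-theta)
        obj = float(
            (N1 * logt).sum()
            + ((Wc[:, None] * n_k[None, :] - N1) * log1mt).sum()
            + (a_th - 1.0) * (logt + log1mt).sum()
            + lam * (pos_k @ np.log(phi) + (n_k - pos_k) @ np.log1p(-phi))
            + (a_ph - 1.0) * (np.log(phi) + np.log1p(-phi)).sum()
        )
        trace.append(obj)
        if obj - prev < hyper.tol * max(1.0, abs(obj)):
            break
        prev = obj

    majority = np.where(pos_k * 2 > n_k, 1, -1).astype(np.int8)
    majority[n_k == 0] = -1

    # undo the canonical reordering
    s_out = np.empty(n, dtype=np.int64)
    s_out[s_order] = s
    c_out = np.empty(p, dtype=np.int64)
    c_out[f_order] = c
    w_out = np.empty(p)
    w_out[f_order] = w_rel
    return BiclusterFit(
        stratum_of_sample=s_out,
        cluster_of_feature=c_out,
        weights=w_out,
        K=K,
        loglik_trace=trace,
        stratum_outcome=majority,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
        extras={"n_sweeps": len(trace), "lambda": lam, "n_feature_clusters": F},
    )


def select_k(
    G_sub: np.ndarray,
    R: np.ndarray,
    k_grid=(2, 3, 4, 5, 6),
    hyper: BiclusterHyper | None = None,
    seed: int = 0,
) -> int:
    """Choose K by held-out outcome log-likelihood.

    Samples are split in half (outcome-stratified); for each K the model
    is fitted on the training half, held-out samples are assigned to their
    best stratum by the feature term alone, and the outcome log-likelihood
    of those assignments is scored.
    """
    G_sub = np.asarray(G_sub)
    R = np.asarray(R)
    n = R.shape[0]
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(R == 1), np.flatnonzero(R != 1)
    train = np.sort(np.concatenate([
        rng.permutation(pos)[: max(1, len(pos) // 2)],
        rng.permutation(neg)[: max(1, len(neg) // 2)],
    ]))
    test = np.setdiff1d(np.arange(n), train)
    best_k, best_ll = None, -np.inf
    for k in k_grid:
        if k > len(train):
            continue
        fit = fit_bicluster(G_sub[:, train], R[train], K=k, hyper=hyper, seed=seed)
        w = tempering_exponents(fit.weights)
        S = np.zeros((len(train), k))
        S[np.arange(len(train)), fit.stratum_of_sample] = 1.0
        n_k = S.sum(axis=0)
        C1 = np.asarray(G_sub[:, train], dtype=float) @ S
        F = int(fit.cluster_of_feature.max()) + 1
        N1 = np.zeros((F, k))
        np.add.at(N1, fit.cluster_of_feature, w[:, None] * C1)
        Wc = np.bincount(fit.cluster_of_feature, weights=w, minlength=F)
        theta = _map_theta(N1, Wc, n_k, 1.5)
        pos_k = (R[train] == 1).astype(float) @ S
        phi = np.clip((pos_k + 1.0) / (n_k + 2.0), 1e-9, 1 - 1e-9)
        logt, log1mt = np.log(theta), np.log1p(-theta)
        M1 = np.zeros((F, len(test)))
        np.add.at(M1, fit.cluster_of_feature, w[:, None] * np.asarray(G_sub[:, test], dtype=float))
        score = M1.T @ (logt - log1mt) + (Wc @ log1mt)[None, :]
        assign = np.argmax(score, axis=1)
        r_test = (R[test] == 1).astype(float)
        ll = float(np.sum(r_test * np.log(phi[assign]) + (1 - r_test) * np.log1p(-phi[assign])))
        if ll > best_ll:
            best_k, best_ll = k, ll
    if best_k is None:
        raise ValueError("no feasible K in the grid")
    return best_k


def stratify(
    candidates_matrix: np.ndarray,
    R: np.ndarray,
    K: int,
    hyper: BiclusterHyper | None = None,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> BiclusterFit:
    """Stratify all samples from the candidate-feature matrix.

    Wraps :func:`fit_bicluster` and verifies that at least one stratum has
    a positive majority outcome; otherwise raises
    :class:`NoPositiveStratumError` with diagnostics.
    """
    fit = fit_bicluster(
        candidates_matrix, R, K,
        hyper=hyper, seed=seed, sample_ids=sample_ids, feature_ids=feature_ids,
    )
    if not fit.positive_strata:
        sizes = np.bincount(fit.stratum_of_sample, minlength=K).tolist()
        raise NoPositiveStratumError(
            f"no stratum has a positive majority outcome "
            f"(stratum sizes {sizes}, positives {int((np.asarray(R) == 1).sum())})"
        )
    return fit
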