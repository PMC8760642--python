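"""Phase 5: matched-pairs quasi-experimental design per (candidate, stratum).

For every candidate feature, samples carrying the feature ("treated") are
paired with non-carriers ("controls").  Pairs must agree exactly on the
confounder profile Z (exact blocking); within each block a minimum-cost
assignment under the Manhattan distance over the *other* candidate
features picks maximally similar pairs.  The association between
treatment and each positive stratum's outcome is then tested on the
discordant pair counts with McNemar's test (Yates-corrected), and all
(candidate, stratum) p-values are pooled into one adaptive
Benjamini-Hochberg correction whose null count m0 is estimated from the
slope of the sorted p-value sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import chi2

from .core import CausalReport, CausalTuple

logger = logging.getLogger(__name__)


@dataclass
class MatchedPairSet:
    """Pairs of (treated, control) sample indices for one candidate."""

    pairs: list[tuple[int, int]]
    treatment_feature: str
    total_distance: float
    n_treated: int = 0
    n_controls: int = 0

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DiscordantCounts:
    b: int      # treated positive / control negative on the stratum outcome
    c: int      # treated negative / control positive
    concordant_pos: int = 0
    concordant_neg: int = 0

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise ValueError("discordant counts must be non-negative")


def stratum_outcome(strata: np.ndarray, R: np.ndarray, k: int) -> np.ndarray:
    """Outcome vector of stratum ``k``: +1 for members, -1 for everyone else.

    Samples of *other* positive strata are labelled -1 as well: the
    stratum outcome is a full-length vector marking only the stratum under
    test.  ``k`` must index a positive-majority stratum.
    """
    strata = np.asarray(strata)
    R = np.asarray(R)
    members = strata == k
    if not members.any():
        raise ValueError(f"stratum {k} is empty")
    if 2 * int((R[members] == 1).sum()) <= members.sum():
        raise ValueError(f"stratum {k} does not have a positive majority outcome")
    return np.where(members, 1, -1).astype(np.int8)


def build_pairs(
    treatment: np.ndarray,
    Z: np.ndarray,
    other_candidates: np.ndarray,
    feature_id: str = "",
    sample_ids: list[str] | None = None,
) -> MatchedPairSet:
    """Exact-Z-blocked minimum-cost matching of treated vs untreated samples.

    ``treatment`` is the candidate's binary sample vector, ``Z`` the
    (m x n) confounder matrix (m may be 0: a single block), and
    ``other_candidates`` the (q x n) matrix of the remaining candidate
    features entering the Manhattan distance.  Within each block the
    smaller side is fully matched (rectangular assignment).  Samples are
    processed in sample-id order so equal-cost matchings resolve
    deterministically.
    """
    treatment = np.asarray(treatment)
    n = treatment.shape[0]
    Z = np.asarray(Z).reshape(-1, n)
    other = np.asarray(other_candidates, dtype=np.float64).reshape(-1, n)
    order = np.argsort(np.asarray(sample_ids)) if sample_ids is not None else np.arange(n)

    treated = order[treatment[order] == 1]
    controls = order[treatment[order] != 1]
    pairs: list[tuple[int, int]] = []
    total = 0.0
    if Z.shape[0]:
        keys = [tuple(col) for col in Z.T]
        blocks: dict[tuple, tuple[list[int], list[int]]] = {}
        for i in treated:
            blocks.setdefault(keys[i], ([], []))[0].append(int(i))
        for i in controls:
            blocks.setdefault(keys[i], ([], []))[1].append(int(i))
        block_list = list(blocks.values())
    else:
        block_list = [(list(map(int, treated)), list(map(int, controls)))]

    for t_idx, u_idx in block_list:
        if not t_idx or not u_idx:
            continue
        cost = cdist(other[:, t_idx].T, other[:, u_idx].T, metric="cityblock")
        rows, cols = linear_sum_assignment(cost)
        for r, cidx in zip(rows, cols):
            pairs.append((t_idx[r], u_idx[cidx]))
            total += float(cost[r, cidx])
    return MatchedPairSet(
        pairs=pairs,
        treatment_feature=feature_id,
        total_distance=total,
        n_treated=len(treated),
        n_controls=len(controls),
    )


def count_discordant(pairs: MatchedPairSet, outcome: np.ndarray) -> DiscordantCounts:
    """Tabulate pair outcomes for McNemar's test."""
    outcome = np.asarray(outcome)
    b = c = cp = cn = 0
    for t, u in pairs.pairs:
        yt, yu = outcome[t], outcome[u]
        if yt == 1 and yu != 1:
            b += 1
        elif yt != 1 and yu == 1:
            c += 1
        elif yt == 1:
            cp += 1
        else:
            cn += 1
    return DiscordantCounts(b=b, c=c, concordant_pos=cp, concordant_neg=cn)


def mcnemar_yates(counts: DiscordantCounts) -> tuple[float, float]:
    """Yates-corrected McNemar statistic and chi-square(1) upper-tail p.

    The continuity correction is clamped at zero (|b - c| <= 1 gives a
    zero statistic); b + c = 0 returns (0, 1).
    """
    b, c = counts.b, counts.c
    if b + c == 0:
        return 0.0, 1.0
    stat = max(abs(b - c) - 1.0, 0.0) ** 2 / (b + c)
    return float(stat), float(chi2.sf(stat, df=1))


def adaptive_bh(p_values, q: float = 0.05) -> tuple[int, np.ndarray]:
    """Adaptive Benjamini-Hochberg step-up with stepwise m0 estimation.

    The number of true null hypotheses is read off the q-q plot of the
    sorted p-values: walking up the sorted sequence, slopes
    ``S_i = (1 - p_(i)) / (m + 1 - i)`` are computed and the walk stops at
    the first decrease; ``m0 = min(m, ceil(1/S_i) + 1)`` at the stopping
    point (``m0 = m`` when the slopes never decrease).  Standard step-up
    BH at level ``q`` then uses m0 in place of m.

    Returns ``(m0, rejected)`` with ``rejected`` aligned to the input.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]

    slopes = (1.0 - ps) / (m + 1.0 - np.arange(1, m + 1))
    m0 = m
    for i in range(1, m):
        if slopes[i] < slopes[i - 1]:
            if slopes[i] > 0:
                m0 = min(m, int(math.ceil(1.0 / slopes[i])) + 1)
            break
    m0 = max(m0, 1)

    thresholds = np.arange(1, m + 1) * q / m0
    passing = np.flatnonzero(ps <= thresholds)
    rejected = np.zeros(m, dtype=bool)
    if passing.size:
        rejected[order[: passing[-1] + 1]] = True
    return m0, rejected


def run_qed(
    G: np.ndarray,
    candidates: np.ndarray,
    feature_ids: list[str],
    strata: np.ndarray,
    positive_strata: list[int],
    R: np.ndarray,
    Z: np.ndarray,
    sample_ids: list[str] | None = None,
    q: float = 0.05,
    min_prevalence: int = 5,
    stratified: bool = True,
    exclude_other_positive: bool = False,
) -> CausalReport:
    """Test every (candidate, positive stratum) pair; pool into one FDR step.

    Pairing depends only on the candidate (treatment) and Z, so each
    candidate is matched once and reused across strata.  ``stratified=False``
    tests each candidate once against the global outcome instead
    (hypothesis stratum index -1).  ``exclude_other_positive`` drops pairs
    touching members of other positive strata instead of counting them as
    negatives.

    Candidates with fewer treated samples than ``min_prevalence``, or with
    no matchable pair, are skipped and recorded in the report.
    """
    G = np.asarray(G)
    R = np.asarray(R)
    strata = np.asarray(strata)
    candidates = np.asarray(candidates, dtype=np.int64)
    n = R.shape[0]
    Z = np.asarray(Z).reshape(-1, n)
    if candidates.size == 0:
        raise ValueError("no candidate features to test")
    if stratified and not positive_strata:
        raise ValueError("no positive stratum to test against")

    order = np.argsort(np.asarray(sample_ids)) if sample_ids is not None else np.arange(n)
    G_cand = G[candidates].astype(np.float64)
    # pairwise Manhattan distances over the full candidate profile; the
    # treatment feature contributes a constant +1 to every treated/control
    # pair, so a flat -1 shift yields the other-candidates distance
    D_all = cdist(G_cand.T, G_cand.T, metric="cityblock")

    if stratified:
        outcomes = [(k, stratum_outcome(strata, R, k)) for k in positive_strata]
    else:
        outcomes = [(-1, R.astype(np.int8))]
    if exclude_other_positive:
        pos_strata_of = np.full(n, -1)
        for k in positive_strata:
            pos_strata_of[strata == k] = k

    keys = [tuple(col) for col in Z.T] if Z.shape[0] else None

    tuples: list[CausalTuple] = []
    skips: dict[str, str] = {}
    p_pool: list[float] = []
    meta: list[tuple[str, int, float, int, int, int]] = []
    for ci, j in enumerate(candidates):
        fid = feature_ids[j]
        treatment = G[j]
        treated = order[treatment[order] == 1]
        controls = order[treatment[order] != 1]
        if len(treated) < min_prevalence:
            skips[fid] = f"prevalence {len(treated)} below threshold {min_prevalence}"
            continue
        if keys is not None:
            blocks: dict[tuple, tuple[list[int], list[int]]] = {}
            for i in treated:
                blocks.setdefault(keys[i], ([], []))[0].append(int(i))
            for i in controls:
                blocks.setdefault(keys[i], ([], []))[1].append(int(i))
            block_list = [v for v in blocks.values() if v[0] and v[1]]
        else:
            block_list = [(list(map(int, treated)), list(map(int, controls)))]
        pairs: list[tuple[int, int]] = []
        for t_idx, u_idx in block_list:
            cost = D_all[np.ix_(t_idx, u_idx)] - 1.0
            rows, cols = linear_sum_assignment(cost)
            pairs.extend((t_idx[r], u_idx[c]) for r, c in zip(rows, cols))
        if not pairs:
            skips[fid] = "no matchable treated/control pair under exact confounder blocking"
            continue
        for k, y in outcomes:
            use = pairs
            if exclude_other_positive and k != -1:
                use = [
                    (t, u) for t, u in pairs
                    if pos_strata_of[t] in (-1, k) and pos_strata_of[u] in (-1, k)
                ]
            counts = DiscordantCounts(
                b=sum(1 for t, u in use if y[t] == 1 and y[u] != 1),
                c=sum(1 for t, u in use if y[t] != 1 and y[u] == 1),
            )
            stat, p = mcnemar_yates(counts)
            p_pool.append(p)
            meta.append((fid, k, stat, counts.b, counts.c, len(use)))

    if not p_pool:
        return CausalReport(tuples=[], m0_estimate=0, q_level=q, skips=skips)

    m0, rejected = adaptive_bh(np.asarray(p_pool), q=q)
    for (fid, k, stat, b, c, n_pairs), p, rej in zip(meta, p_pool, rejected):
        tuples.append(CausalTuple(
            feature_id=fid, stratum=k, raw_p=float(p), significant=bool(rej),
            b=b, c=c, statistic=stat, n_pairs=n_pairs,
        ))
    return CausalReport(tuples=tuples, m0_estimate=int(m0), q_level=q, skips=skips)
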