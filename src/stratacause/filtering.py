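"""Phase 3: per-group outlier selection on feature weights.

Within each feature group, features whose weight lies far above the
group's weight distribution are promoted to causal candidates.  The scale
of "far" is the median absolute deviation about the median, rescaled by
1/(sqrt(2) * erfinv(1/2)) ~ 1.4826 so that it estimates the standard
deviation consistently under normality; a weight is selected when it
exceeds the group median by more than ``L`` scaled MADs (one-sided,
upper tail).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import erfinv

logger = logging.getLogger(__name__)

#: 1 / (sqrt(2) * erfinv(1/2)); the normal-consistency factor ~1.482602
MAD_SCALE = 1.0 / (np.sqrt(2.0) * erfinv(0.5))


def scaled_mad(weights) -> float:
    """Median absolute deviation about the median, normal-consistent scaling."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("scaled_mad of an empty vector is undefined")
    return float(np.median(np.abs(w - np.median(w))) * MAD_SCALE)


def select_outlier_features(weights, L: float = 3.0) -> np.ndarray:
    """Indices whose weight exceeds the median by more than ``L`` scaled MADs.

    ``L`` plays the role of a number of standard deviations (typically an
    integer between 2 and 5).  Degenerate groups: if the MAD is zero but
    the weights are not constant, the strict maxima above the median are
    selected (logged); a constant group selects nothing.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    w = np.asarray(weights, dtype=float)
    med = np.median(w)
    mad = scaled_mad(w)
    if mad == 0.0:
        if np.ptp(w) == 0.0:
            return np.array([], dtype=np.int64)
        logger.info("zero MAD in non-constant group; selecting strict maxima")
        top = w.max()
        if top <= med:
            return np.array([], dtype=np.int64)
        return np.flatnonzero(w == top)
    return np.flatnonzero(w - med > L * mad)


def merge_candidates(selections: list[np.ndarray]) -> np.ndarray:
    """De-duplicated union of per-group selections, first-seen order.

    ``selections`` hold dataset-level feature indices.  An empty union is
    an error: the pipeline has nothing to test.
    """
    seen: set[int] = set()
    merged: list[int] = []
    for sel in selections:
        for idx in np.asarray(sel, dtype=np.int64):
            if int(idx) not in seen:
                seen.add(int(idx))
                merged.append(int(idx))
    if not merged:
        raise ValueError("no candidate features survived filtering in any group")
    return np.asarray(merged, dtype=np.int64)
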