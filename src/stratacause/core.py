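"""Core domain types shared across the pipeline.

The pipeline operates on a binary omics profile matrix ``G`` (features x
samples), a case/control outcome vector ``R`` over ``{-1, +1}``, an optional
binary confounder matrix ``Z`` (confounders x samples), and a collection of
possibly overlapping feature groups (pathways).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_binary(a: np.ndarray, name: str) -> None:
    if not np.isin(a, (0, 1)).all():
        bad = np.argwhere(~np.isin(a, (0, 1)))[0]
        raise ValueError(f"{name} contains a non-binary value at {tuple(bad)}")


@dataclass
class OmicsDataset:
    """Binary omics profiles with outcome and confounders.

    Parameters
    ----------
    G : ndarray of shape (p, n)
        Feature presence indicators; rows are features, columns samples.
    R : ndarray of shape (n,)
        Outcome vector over {-1, +1}; +1 marks a positive (case) sample.
    Z : ndarray of shape (m, n)
        Binary confounder profiles; ``m`` may be zero.
    feature_ids, sample_ids, confounder_ids : lists of unique strings.
    """

    G: np.ndarray
    R: np.ndarray
    Z: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    confounder_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        self.R = np.asarray(self.R, dtype=np.int8)
        n = self.R.shape[0]
        self.Z = np.asarray(self.Z, dtype=np.int8).reshape(len(self.confounder_ids), n)
        if self.G.ndim != 2 or self.G.shape[1] != n:
            raise ValueError(f"G has shape {self.G.shape}, expected (*, {n})")
        if self.Z.size and self.Z.shape[1] != n:
            raise ValueError(f"Z has shape {self.Z.shape}, expected (*, {n})")
        _check_binary(self.G, "G")
        if self.Z.size:
            _check_binary(self.Z, "Z")
        if not np.isin(self.R, (-1, 1)).all():
            raise ValueError("R must take values in {-1, +1}")
        if len(self.feature_ids) != self.G.shape[0]:
            raise ValueError("feature_ids length does not match G rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match R")
        for ids, what in ((self.feature_ids, "feature_ids"), (self.sample_ids, "sample_ids")):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate entries in {what}")

    @property
    def n_features(self) -> int:
        return self.G.shape[0]

    @property
    def n_samples(self) -> int:
        return self.G.shape[1]

    @property
    def positive_mask(self) -> np.ndarray:
        return self.R == 1


@dataclass
class PathwayCollection:
    """An ordered list of named, possibly overlapping feature groups."""

    names: list[str]
    groups: list[set[str]]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.groups):
            raise ValueError("names and groups must have equal length")
        for name, members in zip(self.names, self.groups):
            if not members:
                raise ValueError(f"pathway {name!r} has no members")

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(zip(self.names, self.groups))


@dataclass
class CausalTuple:
    feature_id: str
    stratum: int                 # -1 denotes the unstratified (global) outcome
    raw_p: float
    significant: bool
    b: int = 0                   # discordant pairs, treated positive
    c: int = 0                   # discordant pairs, control positive
    statistic: float = 0.0
    n_pairs: int = 0


@dataclass
class CausalReport:
    """Outcome of the matched-pairs causal testing phase.

    ``tuples`` holds one entry per (candidate feature, positive stratum)
    hypothesis; a feature may recur with several strata and vice versa.
    ``m0_estimate`` is the estimated number of true null hypotheses used by
    the adaptive FDR step; ``skips`` records candidates that could not be
    tested, with the reason.
    """

    tuples: list[CausalTuple]
    m0_estimate: int
    q_level: float
    skips: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.tuples:
            if not 0.0 <= t.raw_p <= 1.0:
                raise ValueError(f"p-value out of [0,1] for {t.feature_id}")

    @property
    def significant_features(self) -> set[str]:
        return {t.feature_id for t in self.tuples if t.significant}

    def significant_pairs(self) -> list[tuple[str, int]]:
        return [(t.feature_id, t.stratum) for t in self.tuples if t.significant]
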