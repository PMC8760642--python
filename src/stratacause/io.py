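"""Readers and writers for the external text formats.

Matrices travel as TSV with a header row of sample ids and a first column of
feature (or confounder) ids.  Outcome vectors are one-row matrices.  Gene
sets use the standard GMT format (name, description, member ids, tab
separated, one set per line).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import OmicsDataset, PathwayCollection


def read_matrix(path, allowed=(0, 1), sep: str = "\t"):
    """Read a labeled matrix of small integers.

    Returns ``(values, row_ids, col_ids)`` preserving file order.  Raises
    ``ValueError`` naming the offending cell when a value is outside
    ``allowed``, and on duplicate row/column ids.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column id {dup!r} in {path}")
    values = df.to_numpy()
    mask = ~np.isin(values, allowed)
    if mask.any():
        i, j = np.argwhere(mask)[0]
        raise ValueError(
            f"non-binary value {values[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    return values.astype(np.int8), [str(x) for x in df.index], [str(x) for x in df.columns]


def write_matrix(path, values, row_ids, col_ids, sep: str = "\t") -> None:
    df = pd.DataFrame(np.asarray(values), index=row_ids, columns=col_ids)
    df.to_csv(path, sep=sep)


def read_outcome(path, sep: str = "\t") -> tuple[np.ndarray, list[str]]:
    """Read a one-row outcome matrix over {-1, +1}; returns (R, sample_ids)."""
    values, _, sample_ids = read_matrix(path, allowed=(-1, 1), sep=sep)
    if values.shape[0] != 1:
        raise ValueError(f"outcome file {path} must have exactly one row")
    return values[0], sample_ids


def write_outcome(path, R, sample_ids, sep: str = "\t") -> None:
    write_matrix(path, np.asarray(R).reshape(1, -1), ["outcome"], sample_ids, sep=sep)


def read_gmt(path) -> PathwayCollection:
    """Read a GMT gene-set file into a :class:`PathwayCollection`."""
    names: list[str] = []
    groups: list[set[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            members = {f for f in fields[2:] if f}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {fields[0]!r} is empty")
            names.append(fields[0])
            groups.append(members)
    return PathwayCollection(names=names, groups=groups)


def write_gmt(path, pathways: PathwayCollection) -> None:
    with open(path, "w") as fh:
        for name, members in pathways:
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_dataset(g_path, r_path, z_path=None) -> OmicsDataset:
    """Assemble an :class:`OmicsDataset` from G/R(/Z) TSV files.

    Sample ids must agree across files (same order).
    """
    G, feature_ids, sample_ids = read_matrix(g_path)
    R, r_samples = read_outcome(r_path)
    if r_samples != sample_ids:
        raise ValueError("sample ids of outcome file do not match profile matrix")
    if z_path is not None:
        Z, confounder_ids, z_samples = read_matrix(z_path)
        if z_samples != sample_ids:
            raise ValueError("sample ids of confounder file do not match profile matrix")
    else:
        Z, confounder_ids = np.zeros((0, len(sample_ids)), dtype=np.int8), []
    return OmicsDataset(
        G=G, R=R, Z=Z,
        feature_ids=feature_ids, sample_ids=sample_ids, confounder_ids=confounder_ids,
    )


def write_dataset(dataset: OmicsDataset, out_dir, prefix: str = "") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "G": out_dir / f"{prefix}G.tsv",
        "R": out_dir / f"{prefix}R.tsv",
    }
    write_matrix(paths["G"], dataset.G, dataset.feature_ids, dataset.sample_ids)
    write_outcome(paths["R"], dataset.R, dataset.sample_ids)
    if dataset.Z.size:
        paths["Z"] = out_dir / f"{prefix}Z.tsv"
        write_matrix(paths["Z"], dataset.Z, dataset.confounder_ids, dataset.sample_ids)
    return paths
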