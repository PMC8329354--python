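"""Data model and text readers/writers for thickness tables, matrices, networks.

All on-disk formats are delimiter-separated text (TSV or CSV, chosen by file
extension) so that every artefact of a run is diffable and inspectable at the
68x68 scale this package works at. Lines starting with ``#`` are comments
(used to stamp outputs with the config hash that produced them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RoiAtlas

__all__ = [
    "MorphometryError",
    "ThicknessTable",
    "CovarianceMatrix",
    "BinaryNetwork",
    "read_thickness_table",
    "write_thickness_table",
    "read_network",
    "write_network",
    "read_matrix",
    "write_matrix",
]

META_COLUMNS = ("subject_id", "condition", "group")


class MorphometryError(ValueError):
    """A table or matrix violates the data-model invariants."""


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


class ThicknessTable:
    """Per-subject, per-condition ROI mean cortical thickness (mm).

    One row per (subject, condition); metadata columns ``subject_id``,
    ``condition``, ``group`` followed by one column per atlas ROI. Column
    order is canonicalized to atlas order on construction, so the order in
    an input file never changes results.

    Invariants enforced here: all thickness values finite and strictly
    positive; (subject_id, condition) pairs unique; ROI columns exactly
    match the atlas.
    """

    def __init__(self, data: pd.DataFrame, atlas: RoiAtlas):
        data = data.reset_index(drop=True)
        missing_meta = [c for c in META_COLUMNS if c not in data.columns]
        if missing_meta:
            raise MorphometryError(f"missing metadata columns: {missing_meta}")
        roi_cols = [c for c in data.columns if c not in META_COLUMNS]
        missing = sorted(set(atlas.names) - set(roi_cols))
        if missing:
            raise MorphometryError(f"missing ROI columns: {missing[:5]}")
        unknown = sorted(set(roi_cols) - set(atlas.names))
        if unknown:
            raise MorphometryError(f"unknown columns: {unknown[:5]}")
        data = data.loc[:, list(META_COLUMNS) + list(atlas.names)].copy()
        values = data.loc[:, list(atlas.names)].to_numpy(dtype=float)
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MorphometryError(
                f"non-positive or non-finite thickness at row {int(r) + 1}, "
                f"ROI {atlas.names[int(c)]!r}: {values[r, c]!r}"
            )
        dup = data.duplicated(subset=["subject_id", "condition"])
        if dup.any():
            r = int(np.argmax(dup.to_numpy()))
            raise MorphometryError(
                f"duplicate (subject_id, condition) pair at row {r + 1}: "
                f"({data.at[r, 'subject_id']!r}, {data.at[r, 'condition']!r})"
            )
        self.data = data
        self.atlas = atlas

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["condition"]))

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["group"]))

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["subject_id"]))

    def __len__(self) -> int:
        return len(self.data)

    def restrict_group(self, group: str) -> "ThicknessTable":
        sub = self.data[self.data["group"] == group]
        if sub.empty:
            raise MorphometryError(f"no rows with group {group!r}")
        return ThicknessTable(sub, self.atlas)

    def condition_values(self, condition: str, group: str | None = None):
        """(subject_ids, n_subjects x n_roi array) for one condition.

        Rows are sorted by subject_id so results do not depend on file
        row order.
        """
        sel = self.data[self.data["condition"] == condition]
        if group is not None:
            sel = sel[sel["group"] == group]
        if sel.empty:
            raise MorphometryError(
                f"no rows for condition {condition!r}"
                + (f", group {group!r}" if group else "")
            )
        sel = sel.sort_values("subject_id", kind="stable")
        return (
            tuple(sel["subject_id"]),
            sel.loc[:, list(self.atlas.names)].to_numpy(dtype=float),
        )

    def paired_values(self, cond_a: str, cond_b: str, group: str | None = None):
        """Aligned (subjects, X_a, X_b) arrays for a paired two-condition design.

        Raises if any subject lacks one of the two conditions.
        """
        subj_a, xa = self.condition_values(cond_a, group)
        subj_b, xb = self.condition_values(cond_b, group)
        if subj_a != subj_b:
            odd = sorted(set(subj_a) ^ set(subj_b))
            raise MorphometryError(
                f"subjects not paired across conditions {cond_a!r}/{cond_b!r}: "
                f"{odd[:5]}"
            )
        return subj_a, xa, xb


def read_thickness_table(path, atlas: RoiAtlas) -> ThicknessTable:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    try:
        return ThicknessTable(df, atlas)
    except MorphometryError as e:
        raise MorphometryError(f"{path}: {e}") from None


def write_thickness_table(table: ThicknessTable, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.data.to_csv(fh, sep=_sep_for(path), index=False)


@dataclass
class CovarianceMatrix:
    """Across-subject Pearson correlation of ROI thickness, with p-values.

    ``r`` is the symmetric ROI x ROI correlation matrix (unit diagonal);
    ``p`` holds two-sided p-values from the exact t transform
    ``t = r*sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom (diagonal
    ignored); ``n`` is the number of subjects entering the correlation.
    """

    r: np.ndarray
    p: np.ndarray
    n: int
    atlas: RoiAtlas

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        k = self.atlas.n
        if self.r.shape != (k, k) or self.p.shape != (k, k):
            raise MorphometryError("correlation/p matrices must be ROI x ROI")
        if self.n < 4:
            raise MorphometryError("correlation requires n >= 4 subjects")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise MorphometryError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise MorphometryError("correlation diagonal must be 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
            raise MorphometryError("correlations must lie in [-1, 1]")


class BinaryNetwork:
    """Undirected, unweighted ROI network: symmetric 0/1 adjacency, zero diagonal."""

    def __init__(self, adjacency, atlas: RoiAtlas):
        a = np.asarray(adjacency)
        if a.shape != (atlas.n, atlas.n):
            raise MorphometryError("adjacency must be ROI x ROI")
        if not np.isin(a, (0, 1)).all():
            raise MorphometryError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        if (a != a.T).any():
            raise MorphometryError("adjacency must be symmetric")
        if np.diag(a).any():
            raise MorphometryError("adjacency diagonal must be zero")
        self.adjacency = a
        self.atlas = atlas

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)


def write_matrix(m: np.ndarray, atlas: RoiAtlas, path, header_comment: str | None = None) -> None:
    """Write a labelled square ROI x ROI matrix as delimited text."""
    df = pd.DataFrame(m, index=atlas.names, columns=atlas.names)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=_sep_for(path), index_label="roi")


def read_matrix(path, atlas: RoiAtlas) -> np.ndarray:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", index_col=0)
    if list(df.columns) != list(atlas.names) or list(df.index) != list(atlas.names):
        # order-insensitive: reindex if the label sets match
        if set(df.columns) != set(atlas.names) or set(df.index) != set(atlas.names):
            raise MorphometryError(f"{path}: matrix labels do not match atlas")
        df = df.loc[list(atlas.names), list(atlas.names)]
    return df.to_numpy(dtype=float)


def write_network(net: BinaryNetwork, path, header_comment: str | None = None) -> None:
    write_matrix(net.adjacency, net.atlas, path, header_comment)


def read_network(path, atlas: RoiAtlas) -> BinaryNetwork:
    m = read_matrix(path, atlas)
    if not np.isin(m, (0.0, 1.0)).all():
        raise MorphometryError(f"{path}: network entries must be 0/1")
    try:
        return BinaryNetwork(m.astype(np.int8), atlas)
    except MorphometryError as e:
        raise MorphometryError(f"{path}: {e}") from None
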