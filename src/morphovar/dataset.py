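"""Grouped specimen-by-variable data and the study's table format.

The unit of analysis is a table of shape variables (by default the 14
size-standardized radial Fourier coefficients of a closed outline) with one
group label per specimen.  The on-disk format is the one used for the mouse
molar study data: a whitespace/tab-delimited text table with a ``Loc``
column holding the locality label and columns ``UM1A1``..``UM1A7``,
``UM1B1``..``UM1B7`` holding the cosine and sine coefficients of the first
seven harmonics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._warnings import ExtraColumnWarning

#: Canonical column order of the study table: 7 cosine then 7 sine terms.
FC_COLUMNS = [f"UM1A{h}" for h in range(1, 8)] + [f"UM1B{h}" for h in range(1, 8)]
GROUP_COLUMN = "Loc"


@dataclass
class GroupedDataset:
    """n specimens x p shape variables plus a group label per specimen.

    Parameters
    ----------
    values:
        Float matrix of shape ``(n, p)``.
    group_labels:
        Sequence of ``n`` hashable group identifiers (stored as strings).
    var_names:
        Optional variable names; defaults to the study's 14 coefficient
        columns when ``p == 14``, else ``V1..Vp``.
    """

    values: np.ndarray
    group_labels: np.ndarray
    var_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 specimens")
        if p < 1:
            raise ValueError("need at least 1 variable")
        self.group_labels = np.asarray([str(g) for g in np.asarray(self.group_labels)])
        if self.group_labels.shape != (n,):
            raise ValueError("group_labels must have one entry per specimen")
        if self.var_names is None:
            self.var_names = list(FC_COLUMNS) if p == 14 else [f"V{i+1}" for i in range(p)]
        if len(self.var_names) != p:
            raise ValueError("var_names length must equal the number of variables")

    # -- derived structure -------------------------------------------------
    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        """Group names in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_sizes(self) -> dict[str, int]:
        return {g: int(np.sum(self.group_labels == g)) for g in self.groups}

    def group_values(self, group: str) -> np.ndarray:
        mask = self.group_labels == group
        if not mask.any():
            raise KeyError(f"unknown group {group!r}")
        return self.values[mask]

    def group_means(self) -> np.ndarray:
        """g x p matrix of group mean vectors, rows in ``self.groups`` order."""
        return np.vstack([self.group_values(g).mean(axis=0) for g in self.groups])

    def subset(self, groups: list[str]) -> "GroupedDataset":
        """Restrict to the given groups (order of first appearance kept)."""
        missing = [g for g in groups if g not in self.groups]
        if missing:
            raise KeyError(f"unknown groups: {missing}")
        mask = np.isin(self.group_labels, groups)
        return GroupedDataset(self.values[mask], self.group_labels[mask], list(self.var_names))

    def merge_groups(self, mapping: dict[str, str]) -> "GroupedDataset":
        """Relabel groups; labels absent from ``mapping`` are kept as is."""
        labels = np.asarray([mapping.get(g, g) for g in self.group_labels])
        return GroupedDataset(self.values.copy(), labels, list(self.var_names))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.var_names)
        df.insert(0, GROUP_COLUMN, self.group_labels)
        return df


def read_fc_table(path) -> GroupedDataset:
    """Read a study-format coefficient table.

    The reader is tolerant: columns may appear in any order, lines starting
    with ``#`` are ignored, and extra columns are dropped with a warning.
    Decimal points only (no comma locale).
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", dtype=str)
    if GROUP_COLUMN not in df.columns:
        raise ValueError(f"missing required column {GROUP_COLUMN!r}")
    dup = df.columns[df.columns.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate column(s): {dup}")
    missing = [c for c in FC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing coefficient column(s): {missing}")
    extra = [c for c in df.columns if c not in FC_COLUMNS and c != GROUP_COLUMN]
    if extra:
        warnings.warn(f"ignoring extra column(s): {extra}", ExtraColumnWarning)
    # numpy's string parser is correctly rounded, so a written table reads
    # back bit-identically; pandas' fast path can be one ulp off
    raw = df[FC_COLUMNS].to_numpy()
    try:
        values = raw.astype(np.float64)
    except ValueError as exc:
        for (r, c), cell in np.ndenumerate(raw):
            try:
                float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at row {r}, column {FC_COLUMNS[c]}"
                ) from exc
        raise
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-numeric cell at row {r}, column {FC_COLUMNS[c]}")
    return GroupedDataset(values, df[GROUP_COLUMN].to_numpy(), list(FC_COLUMNS))


def write_fc_table(data: GroupedDataset, path) -> None:
    """Write a dataset in the study's tab-delimited table format.

    Group labels containing whitespace are rejected (the format is
    whitespace-delimited and unquoted).  Datasets with ``p != 14`` are
    written with their own variable names and a warning.
    """
    for g in data.groups:
        if any(ch.isspace() for ch in g):
            raise ValueError(f"group label {g!r} contains whitespace; not representable")
    if data.n_variables != 14:
        warnings.warn(
            f"writing {data.n_variables} variables under names {data.var_names[:2]}...",
            ExtraColumnWarning,
        )
    df = data.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
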