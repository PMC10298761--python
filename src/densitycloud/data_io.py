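"""Grouped tabular data: loading, validation, and summaries.

The package compares exactly two groups of complete multivariate
observations: a *reference* group B (the denominator of every density
ratio) and a *comparison* group A (the numerator). This module enforces
that data model at the boundary so downstream code can assume a clean
N x d numeric matrix with a two-level label vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GroupedDataset", "load_table", "write_table", "summarize"]


@dataclass(frozen=True)
class GroupedDataset:
    """Two-group multivariate dataset.

    Parameters
    ----------
    values : ndarray, shape (N, d)
        Numeric data matrix, complete cases only.
    group_labels : ndarray, shape (N,)
        Group label for each row; exactly the two values in ``group_names``.
    var_names : tuple of str
        Names of the d variables (columns of ``values``).
    group_names : (str, str)
        ``(reference, comparison)`` — group B then group A.
    """

    values: np.ndarray
    group_labels: np.ndarray
    var_names: tuple[str, ...]
    group_names: tuple[str, str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.group_labels)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "group_labels", labels)
        object.__setattr__(self, "var_names", tuple(self.var_names))
        object.__setattr__(self, "group_names", tuple(self.group_names))
        if values.ndim != 2 or values.shape[1] < 2:
            raise ValueError("data must be an N x d matrix with d >= 2")
        if not np.isfinite(values).all():
            raise ValueError("data contain missing or non-finite values; "
                             "only complete cases are supported")
        if values.shape[1] != len(self.var_names):
            raise ValueError("var_names length does not match column count")
        if labels.shape != (values.shape[0],):
            raise ValueError("group_labels length does not match row count")
        present = set(np.unique(labels).tolist())
        expected = set(self.group_names)
        if len(expected) != 2:
            raise ValueError("group_names must name two distinct groups")
        if present != expected:
            raise ValueError(
                f"group labels {sorted(map(str, present))} do not match "
                f"declared groups {sorted(map(str, expected))}")
        for name in self.group_names:
            if int((labels == name).sum()) < 3:
                raise ValueError(f"group {name!r} has fewer than 3 cases")

    # -- convenience accessors -------------------------------------------

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def reference_name(self) -> str:
        return self.group_names[0]

    @property
    def comparison_name(self) -> str:
        return self.group_names[1]

    def group_matrix(self, name: str) -> np.ndarray:
        """Rows belonging to one group, as an (n_g, d) copy."""
        if name not in self.group_names:
            raise KeyError(f"unknown group {name!r}")
        return self.values[self.group_labels == name].copy()

    @property
    def reference_matrix(self) -> np.ndarray:
        return self.group_matrix(self.reference_name)

    @property
    def comparison_matrix(self) -> np.ndarray:
        return self.group_matrix(self.comparison_name)

    def with_values(self, values: np.ndarray) -> "GroupedDataset":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self, group_col: str = "group") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.var_names))
        df.insert(0, group_col, self.group_labels)
        return df


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_table(path: str | Path,
               group_col: str,
               reference: str | None = None,
               comparison: str | None = None,
               var_cols: Sequence[str] | None = None,
               delimiter: str | None = None) -> GroupedDataset:
    """Read a delimited table and build a validated :class:`GroupedDataset`.

    Rows with a missing value in any *selected* variable column (or in the
    group column) are dropped as incomplete cases and the drop count is
    logged. If ``reference``/``comparison`` are omitted the table must
    contain exactly two group labels, taken in order of first appearance;
    with three or more labels the two groups must be named explicitly and
    rows with other labels are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_infer_delimiter(path, delimiter))
    if group_col not in df.columns:
        raise ValueError(f"group column {group_col!r} not found in {path.name}")

    if var_cols is None:
        numeric = df.drop(columns=[group_col]).select_dtypes(include=[np.number])
        var_cols = list(numeric.columns)
    else:
        var_cols = list(var_cols)
        missing = [c for c in var_cols if c not in df.columns]
        if missing:
            raise ValueError(f"variable columns not found: {missing}")
    for col in var_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"variable column {col!r} is not numeric")

    labels_present = [str(v) for v in pd.unique(df[group_col].dropna().astype(str))]
    if reference is None or comparison is None:
        if len(labels_present) != 2:
            raise ValueError(
                f"group column {group_col!r} has {len(labels_present)} labels "
                f"{labels_present}; name reference and comparison explicitly")
        reference = reference or labels_present[0]
        comparison = comparison or (
            labels_present[1] if labels_present[1] != reference else labels_present[0])
    for name in (reference, comparison):
        if name not in labels_present:
            raise ValueError(f"group value {name!r} does not occur in {group_col!r}")

    n_input = len(df)
    keep_label = df[group_col].astype(str).isin([reference, comparison])
    n_other = int((~keep_label).sum())
    if n_other:
        logger.warning("dropped %d rows with group labels other than %r/%r",
                       n_other, reference, comparison)
    sub = df.loc[keep_label, [group_col, *var_cols]]
    complete = sub.dropna()
    n_incomplete = len(sub) - len(complete)
    if n_incomplete:
        logger.info("dropped %d incomplete cases (missing values in %s)",
                    n_incomplete, var_cols)
    logger.info("retained %d of %d rows", len(complete), n_input)

    return GroupedDataset(
        values=complete[var_cols].to_numpy(dtype=float),
        group_labels=complete[group_col].astype(str).to_numpy(),
        var_names=tuple(var_cols),
        group_names=(reference, comparison),
    )


def write_table(ds: GroupedDataset, path: str | Path,
                group_col: str = "group") -> Path:
    """Write the dataset back to CSV/TSV (delimiter from the extension)."""
    path = Path(path)
    ds.to_frame(group_col).to_csv(path, sep=_infer_delimiter(path, None),
                                  index=False)
    return path


def summarize(ds: GroupedDataset) -> pd.DataFrame:
    """Per-group sample size, centroid, and SD (n-1 denominator).

    Returns a tidy frame with one row per (group, variable).
    """
    rows = []
    for name in ds.group_names:
        X = ds.group_matrix(name)
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        for j, var in enumerate(ds.var_names):
            rows.append({"group": name, "variable": var, "n": X.shape[0],
                         "mean": means[j], "sd": sds[j]})
    return pd.DataFrame(rows)
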