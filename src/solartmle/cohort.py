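"""The wide-format longitudinal cohort table.

One row per subject, one column per node (see :mod:`solartmle.nodes`).
Missing values are ``NaN``; binary nodes otherwise take values in {0, 1}.
The table wraps a :class:`pandas.DataFrame` and carries its ordered node
specs, so downstream stages never have to guess which column is a
treatment, a confounder, or an outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nodes import NodeSpec, validate_ordering

logger = logging.getLogger(__name__)


@dataclass
class CohortTable:
    df: pd.DataFrame
    node_specs: list[NodeSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_specs = validate_ordering(self.node_specs)
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    def spec(self, name: str) -> NodeSpec:
        for s in self.node_specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def values(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(dtype=float)

    def has_missing(self) -> bool:
        return bool(self.df.isna().to_numpy().any())

    def missingness(self) -> dict[str, float]:
        """Per-node fraction of missing values."""
        return {s.name: float(self.df[s.name].isna().mean()) for s in self.node_specs}

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = [s.name for s in self.node_specs]
        if list(self.df.columns) != names:
            extra = set(self.df.columns) - set(names)
            missing = set(names) - set(self.df.columns)
            raise ValueError(
                f"cohort columns do not match node specs (extra={sorted(extra)}, missing={sorted(missing)})"
            )
        if self.n < 1:
            raise ValueError("cohort table has zero rows")
        for s in self.node_specs:
            col = self.df[s.name]
            vals = col.dropna().to_numpy(dtype=float)
            if s.value_kind == "binary":
                bad = ~np.isin(vals, (0.0, 1.0))
                if bad.any():
                    raise ValueError(
                        f"non-binary value(s) {sorted(set(vals[bad]))} in binary node {s.name!r}"
                    )
            else:
                if not np.all(np.isfinite(vals)):
                    raise ValueError(f"non-finite value in continuous node {s.name!r}")

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), list(self.node_specs))


def read_cohort(path: str | Path, specs: list[NodeSpec]) -> CohortTable:
    """Read a wide cohort CSV; empty cells and "NA" are missing.

    Columns must exactly match the node-spec names (order taken from the
    specs).  Row count and per-node missingness are logged.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    names = [s.name for s in specs]
    unknown = set(df.columns) - set(names)
    if unknown:
        raise ValueError(f"unknown column(s) in cohort file: {sorted(unknown)}")
    absent = set(names) - set(df.columns)
    if absent:
        raise ValueError(f"cohort file lacks column(s): {sorted(absent)}")
    table = CohortTable(df[names].astype(float), list(specs))
    logger.info("read cohort %s: n=%d", path, table.n)
    for name, frac in table.missingness().items():
        if frac > 0:
            logger.info("  node %s: %.1f%% missing", name, 100 * frac)
    return table


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the cohort as CSV with empty cells for missing values.

    Binary columns are written as integers so a round trip is lossless.
    """
    out = table.df.copy()
    for s in table.node_specs:
        if s.value_kind == "binary":
            out[s.name] = out[s.name].astype("Int64")
    out.to_csv(path, index=False, na_rep="")


def regime_pattern_counts(table: CohortTable) -> dict[tuple[int, ...], int]:
    """Counts of observed treatment patterns (A1, A2, ...) among complete cases.

    Subjects with any missing treatment are not counted; every possible
    pattern appears as a key (zero-filled).
    """
    tnames = [s.name for s in table.node_specs if s.role == "treatment"]
    if not tnames:
        raise ValueError("cohort has no treatment nodes")
    k = len(tnames)
    arr = table.df[tnames].to_numpy(dtype=float)
    complete = ~np.isnan(arr).any(axis=1)
    counts: dict[tuple[int, ...], int] = {}
    for i in range(2**k):
        pattern = tuple((i >> j) & 1 for j in range(k - 1, -1, -1))
        counts[pattern] = 0
    for row in arr[complete]:
        counts[tuple(int(v) for v in row)] += 1
    return counts
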