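"""Tabular and config I/O.

Interchange formats are plain TSV with optional ``#``-prefixed comment
header lines, JSON for structured results, and JSON/YAML for configs.
Readers validate ranges and report the offending row and column.

Schemas
-------
trajectory        generation, p
observed          replicate, generation, freq, effective_n
zygotes           hom1, het, hom2, p_initial
census            V, Z, A, S
progeny           m1, m2[, m3]   (values 1/2 for parental origin)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cost_fit import ObservedTrajectory
from .estimators import CellCensus, ProgenyTable, ZygoteCounts

__all__ = [
    "read_config",
    "read_trajectories",
    "write_trajectories",
    "read_zygote_counts",
    "write_zygote_counts",
    "read_census",
    "read_progeny_table",
    "write_progeny_table",
    "write_json",
]


class TableError(ValueError):
    """A table failed schema or range validation."""


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def _check_range(df: pd.DataFrame, path, column: str, lo: float, hi: float) -> None:
    bad = df.index[(df[column] < lo) | (df[column] > hi) | df[column].isna()]
    if len(bad):
        row = int(bad[0])
        raise TableError(
            f"{path}: value {df.loc[row, column]!r} in column {column!r}, row {row} "
            f"outside [{lo}, {hi}]"
        )


def read_config(path) -> dict:
    """Load a JSON or YAML parameter block."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_trajectories(path) -> list[ObservedTrajectory]:
    """Read observed trajectories (`replicate generation freq effective_n`)."""
    df = _read_tsv(path, ["replicate", "generation", "freq", "effective_n"])
    _check_range(df, path, "freq", 0.0, 1.0)
    _check_range(df, path, "generation", 0, np.inf)
    _check_range(df, path, "effective_n", 1, np.inf)
    out = []
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("generation")
        out.append(
            ObservedTrajectory(
                replicate=str(rep),
                generations=grp["generation"].to_numpy(),
                observed_freq=grp["freq"].to_numpy(),
                effective_n=grp["effective_n"].to_numpy(),
            )
        )
    return out


def write_trajectories(trajectories: list[ObservedTrajectory], path, comment: str = "") -> None:
    rows = [
        (t.replicate, int(g), float(f), float(n))
        for t in trajectories
        for g, f, n in zip(t.generations, t.observed_freq, t.effective_n)
    ]
    df = pd.DataFrame(rows, columns=["replicate", "generation", "freq", "effective_n"])
    _write_with_comment(df, path, comment)


def _write_with_comment(df: pd.DataFrame, path, comment: str) -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_zygote_counts(path) -> ZygoteCounts:
    df = _read_tsv(path, ["hom1", "het", "hom2", "p_initial"])
    _check_range(df, path, "p_initial", 0.0, 1.0)
    for col in ("hom1", "het", "hom2"):
        _check_range(df, path, col, 0, np.inf)
    row = df.iloc[0]
    return ZygoteCounts(int(row.hom1), int(row.het), int(row.hom2), float(row.p_initial))


def write_zygote_counts(counts: ZygoteCounts, path, comment: str = "") -> None:
    df = pd.DataFrame(
        [[counts.n_hom1, counts.n_het, counts.n_hom2, counts.p_initial]],
        columns=["hom1", "het", "hom2", "p_initial"],
    )
    _write_with_comment(df, path, comment)


def read_census(path) -> CellCensus:
    df = _read_tsv(path, ["V", "Z", "A", "S"])
    for col in ("V", "Z", "A", "S"):
        _check_range(df, path, col, 0, np.inf)
    row = df.iloc[0]
    return CellCensus(int(row.V), int(row.Z), int(row.A), int(row.S))


def read_progeny_table(path) -> ProgenyTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    marker_cols = [c for c in df.columns if c.startswith("m")]
    if len(marker_cols) not in (2, 3):
        raise TableError(f"{path}: expected 2 or 3 marker columns m1..m3, found {marker_cols}")
    values = df[marker_cols].to_numpy()
    if not np.isin(values, (1, 2)).all():
        bad = np.argwhere(~np.isin(values, (1, 2)))[0]
        raise TableError(
            f"{path}: marker state {values[tuple(bad)]!r} in column "
            f"{marker_cols[bad[1]]!r}, row {bad[0]} is not 1 or 2"
        )
    return ProgenyTable(values)


def write_progeny_table(table: ProgenyTable, path, comment: str = "") -> None:
    cols = [f"m{i + 1}" for i in range(table.n_markers)]
    _write_with_comment(pd.DataFrame(table.genotypes, columns=cols), path, comment)


def write_json(obj, path) -> None:
    """Write a JSON result file (numpy scalars/arrays coerced to Python types)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
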