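"""Delimited-text readers/writers and config handling.

Feature matrices are TSV/CSV with a header row of feature names and one row
per sample; missing values are rejected with the offending cell named.
Phenotypes are single-column plain text. Samples are rows and features are
columns, everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix, standardize

__all__ = ["read_matrix", "write_matrix", "read_phenotype", "load_sim_config"]


def _delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path, delimiter: str | None = None) -> FeatureMatrix:
    """Read a delimited feature matrix (header row) and standardize it.

    Rejects missing values, non-numeric cells, ragged rows and duplicate
    feature names, naming the offending coordinates.
    """
    sep = _delimiter(path, delimiter)
    # pandas silently mangles duplicate header names, so check them first
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    names = [h.strip() for h in header]
    dupes = {x for x in names if names.count(x) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate feature names: {sorted(dupes)}")
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    names = [str(c) for c in df.columns]
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, line {row}"
            )
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df.index[df[col].isna()][0]) + 2  # +header +1-based
        raise ValueError(f"{path}: missing value in column {col!r}, line {row}")
    return standardize(df.to_numpy(dtype=float), names)


def write_matrix(
    path: str | Path,
    values: np.ndarray | FeatureMatrix,
    names: list[str] | None = None,
    delimiter: str | None = None,
) -> None:
    """Write a matrix as delimited text with a header row (17 sig. digits)."""
    if isinstance(values, FeatureMatrix):
        names = values.feature_names
        values = values.values
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"f{j + 1}" for j in range(values.shape[1])]
    sep = _delimiter(path, delimiter)
    pd.DataFrame(values, columns=names).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def read_phenotype(path: str | Path) -> np.ndarray:
    """Read a single-column numeric phenotype file (no header)."""
    vals = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                vals.append(float(s))
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value on line {i}: {s!r}") from exc
    if not vals:
        raise ValueError(f"{path}: empty phenotype file")
    return np.array(vals)


def load_sim_config(path: str | Path):
    """Load a YAML simulation config into a :class:`SimulationConfig`."""
    import yaml

    from .simdata import SimulationConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("q_grid", "methods"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def write_json(path: str | Path, obj: dict) -> None:
    """Write a JSON document, converting numpy scalars/arrays."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
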