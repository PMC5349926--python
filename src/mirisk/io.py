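"""Readers and writers for the tabular interchange formats.

Plain CSV is the canonical format: the expression matrix has probes as rows
(first column ``probe_id``) and samples as columns; probe and sample
annotations are one-row-per-entity CSV tables. Reading cross-validates
identifiers across the three files and rejects negative or non-numeric
cells with row/column context.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ExpressionMatrix,
    cross_validate,
    validate_probe_annotation,
    validate_sample_table,
)
from .exceptions import ParseError
from .simulate import SyntheticCohort


def read_expression_matrix(
    path: str | Path,
    probe_annot_path: str | Path,
    sample_path: str | Path,
    state: str = "raw",
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Read matrix + probe annotation + sample table, cross-validated."""
    for p in (path, probe_annot_path, sample_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    raw = pd.read_csv(path)
    if raw.columns[0] != "probe_id":
        raise ParseError(f"{path}: first column must be 'probe_id', got {raw.columns[0]!r}")
    raw = raw.set_index("probe_id")
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value at probe {bad[0]!r}, sample {col!r}"
            )
        raw[col] = coerced
    if raw.isna().any().any():
        probe = raw.index[raw.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row {probe!r}")
    if (raw.to_numpy() < 0).any():
        i, j = np.argwhere(raw.to_numpy() < 0)[0]
        raise ParseError(
            f"{path}: negative value at probe {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    matrix = ExpressionMatrix(raw, state=state)
    annot = validate_probe_annotation(pd.read_csv(probe_annot_path))
    samples = validate_sample_table(pd.read_csv(sample_path))
    cross_validate(matrix, annot, samples)
    return matrix, annot, samples


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.rename_axis("probe_id").to_csv(path)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.csv, probes.csv, samples.csv, truth.txt to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.csv",
        "probes": out / "probes.csv",
        "samples": out / "samples.csv",
        "truth": out / "truth.txt",
    }
    write_expression_matrix(cohort.matrix, paths["matrix"])
    cohort.probes.to_csv(paths["probes"], index=False)
    cohort.samples.to_csv(paths["samples"], index=False)
    paths["truth"].write_text("\n".join(cohort.truth) + "\n")
    return paths


def read_config(path: str | Path) -> dict:
    """Read a declarative key-value (YAML) config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a key-value mapping")
    return cfg
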