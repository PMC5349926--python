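"""Core data containers: expression matrix, probe annotation, sample table.

The expression matrix is a probes x samples pandas DataFrame wrapped with a
normalization-state flag; probe and sample annotations are plain DataFrames
validated against a small schema. Raw matrices must hold nonnegative integer
counts (digital barcode counting yields integers); normalized matrices are
real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

PROBE_CLASSES = ("endogenous", "negative_control", "positive_control")
MATRIX_STATES = ("raw", "normalized", "filtered+normalized")

#: Required columns of a probe annotation table.
PROBE_COLUMNS = ("probe_id", "probe_class", "sequence", "platform")

#: Required columns of a sample table. ``covariate_*`` columns and
#: ``duplicate_of`` are optional.
SAMPLE_COLUMNS = ("sample_id", "group")


def _check_unique(names: Iterable[str], what: str) -> None:
    names = list(names)
    seen = pd.Index(names)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values with a normalization-state flag.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns.
    state
        One of ``raw``, ``normalized``, ``filtered+normalized``.
    filtered
        Whether the background filter has been applied.
    """

    values: pd.DataFrame
    state: str = "raw"
    filtered: bool = False

    def __post_init__(self) -> None:
        if self.state not in MATRIX_STATES:
            raise ValidationError(
                f"unknown matrix state {self.state!r}; expected one of {MATRIX_STATES}"
            )
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("expression matrix must be numeric")
        if np.isnan(vals).any():
            raise ValidationError("expression matrix contains missing values")
        if (vals < 0).any():
            raise ValidationError("expression values must be nonnegative")
        if self.state == "raw" and not np.allclose(vals, np.round(vals)):
            raise ValidationError("raw counts must be integer-valued")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise ValidationError(f"unknown probes: {missing[:5]}")
        return replace(self, values=self.values.loc[list(probes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown samples: {missing[:5]}")
        return replace(self, values=self.values[list(samples)])


def validate_probe_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe annotation table and return it unchanged.

    Endogenous probes must carry a nonempty sequence over {A,C,G,U,T};
    probe classes must come from :data:`PROBE_CLASSES`.
    """
    for col in PROBE_COLUMNS[:2]:
        if col not in annot.columns:
            raise ValidationError(f"probe annotation missing column {col!r}")
    _check_unique(annot["probe_id"], "probe ids in annotation")
    bad_class = set(annot["probe_class"]) - set(PROBE_CLASSES)
    if bad_class:
        raise ValidationError(f"unknown probe classes: {sorted(bad_class)}")
    if "sequence" in annot.columns:
        endo = annot[annot["probe_class"] == "endogenous"]
        seqs = endo["sequence"].fillna("")
        empty = endo.loc[seqs.str.len() == 0, "probe_id"].tolist()
        if empty:
            raise ValidationError(
                f"endogenous probes without sequence: {empty[:5]}"
            )
        alphabet = set("ACGUT")
        bad = endo.loc[
            [not set(s.upper()) <= alphabet for s in seqs], "probe_id"
        ].tolist()
        if bad:
            raise ValidationError(f"non-RNA sequences for probes: {bad[:5]}")
    return annot


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample table: two group labels, resolvable duplicate links."""
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise ValidationError(f"sample table missing column {col!r}")
    _check_unique(samples["sample_id"], "sample ids")
    groups = set(samples["group"].unique())
    if len(groups) > 2:
        raise ValidationError(f"more than two group labels: {sorted(groups)}")
    if "duplicate_of" in samples.columns:
        links = samples["duplicate_of"].dropna()
        known = set(samples["sample_id"])
        orphan = sorted(set(links) - known)
        if orphan:
            raise ValidationError(f"duplicate_of references unknown samples: {orphan[:5]}")
    return samples


def analysis_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Samples entering the analysis: technical duplicates are QC-only."""
    if "duplicate_of" in samples.columns:
        return samples[samples["duplicate_of"].isna()]
    return samples


def duplicate_pairs(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """(original, duplicate) sample-id pairs recorded in the sample table."""
    if "duplicate_of" not in samples.columns:
        return []
    dup = samples[samples["duplicate_of"].notna()]
    return list(zip(dup["duplicate_of"], dup["sample_id"]))


def cross_validate(
    matrix: ExpressionMatrix, annot: pd.DataFrame, samples: pd.DataFrame
) -> None:
    """Check that matrix probe/sample ids are all annotated."""
    validate_probe_annotation(annot)
    validate_sample_table(samples)
    missing_probes = sorted(set(matrix.probe_ids) - set(annot["probe_id"]))
    if missing_probes:
        raise ValidationError(
            f"probes absent from annotation: {missing_probes[:10]}"
        )
    missing_samples = sorted(set(matrix.sample_ids) - set(samples["sample_id"]))
    if missing_samples:
        raise ValidationError(
            f"samples absent from sample table: {missing_samples[:10]}"
        )
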