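"""Classification metrics, permutation significance, univariate screening.

The permutation test answers "is the classifier better than a random
signature?": labels are reshuffled in the training cohort, the identical
model-building-and-evaluation procedure is rerun for each replicate, and the
observed accuracy is ranked against the null accuracies with the add-one
estimator p = (1 + #{null >= observed}) / (B + 1), which can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .exceptions import MiriskError, ParameterError, ValidationError


@dataclass
class ClassificationMetrics:
    """Confusion counts and the five derived proportions.

    Ratios with a zero denominator are ``None`` (reported as absent), never
    coerced to 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return self.tn / d if d else None

    def as_dict(self, digits: int | None = 3) -> dict:
        vals = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
        }
        if digits is not None:
            for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
                if vals[k] is not None:
                    vals[k] = round(vals[k], digits)
        return vals


def confusion_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], positive_label: str
) -> ClassificationMetrics:
    """Confusion matrix and accuracy/sensitivity/specificity/PPV/NPV."""
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    if len(y_true) == 0:
        raise ParameterError("empty input")
    if len(y_true) != len(y_pred):
        raise ParameterError("y_true and y_pred must have equal length")
    labels = set(y_true) | set(y_pred)
    if len(labels) > 2:
        raise ParameterError(f"more than two labels present: {sorted(labels)}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ClassificationMetrics(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


@dataclass
class PermutationResult:
    """Observed accuracy against the label-reshuffled null distribution."""

    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    B: int
    seed: int


def permutation_test(
    X: pd.DataFrame,
    y: Sequence[str],
    score_fn: Callable[[pd.DataFrame, np.ndarray], float],
    B: int = 10_000,
    seed: int = 0,
    check_reproducible: bool = True,
) -> PermutationResult:
    """Permutation significance of a frozen fit-and-evaluate procedure.

    ``score_fn(X, y)`` must run the complete model-building procedure on the
    training cohort (tuning included, if part of the procedure) and return
    the accuracy being tested — on whichever cohort the analysis scores. It
    must be deterministic: any internal randomness has to be seeded inside
    the closure, which is verified by scoring the observed labels twice.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    y = np.asarray(list(y))
    observed = float(score_fn(X, y))
    if check_reproducible and float(score_fn(X, y)) != observed:
        raise MiriskError(
            "score_fn is not reproducible; seed its internal randomness"
        )
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        null[b] = score_fn(X, rng.permutation(y))
    p = (1.0 + float(np.sum(null >= observed))) / (B + 1.0)
    return PermutationResult(
        observed_accuracy=observed, null_accuracies=null, p_value=p, B=B, seed=seed
    )


def univariate_wilcoxon(
    matrix: ExpressionMatrix | pd.DataFrame, groups: Sequence[str]
) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p-value per probe between the two groups.

    Exact for small untied samples, normal approximation with tie and
    continuity corrections otherwise.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    groups = np.asarray(list(groups))
    if len(groups) != values.shape[1]:
        raise ParameterError("one group label per sample is required")
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ParameterError(f"exactly two groups required, got {list(uniq)}")
    a, b = (groups == uniq[0]), (groups == uniq[1])
    if a.sum() < 2 or b.sum() < 2:
        raise ParameterError("both groups need at least two samples")
    out = {}
    arr = values.to_numpy(dtype=float)
    for i, probe in enumerate(values.index):
        x, z = arr[i, a], arr[i, b]
        if np.all(x == x[0]) and np.all(z == z[0]) and x[0] == z[0]:
            out[probe] = 1.0  # identical constant groups carry no evidence
            continue
        res = stats.mannwhitneyu(x, z, alternative="two-sided", method="auto",
                                 use_continuity=True)
        out[probe] = float(res.pvalue)
    return pd.Series(out, name="p_value")


def bh_adjust(pvalues: Sequence[float], q: float = 0.10) -> tuple[pd.Series, pd.Series]:
    """Benjamini-Hochberg step-up adjusted p-values and the significant set.

    Returns (adjusted p-values, boolean mask of adjusted < q), preserving
    the input index when given a Series.
    """
    p = pd.Series(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p.to_numpy(), method="fdr_bh")
    adjusted = pd.Series(adj, index=p.index, name="p_adjusted")
    return adjusted, adjusted < q


def compare_cohorts_chisq(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared on a 2 x k contingency table.

    Yates continuity correction applies to 2 x 2 tables. Returns
    (statistic, p-value).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ParameterError("a 2 x k contingency table is required")
    if (arr < 0).any():
        raise ParameterError("counts must be nonnegative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero marginal")
    correction = arr.shape == (2, 2)
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)
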