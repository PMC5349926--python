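"""Background filtering, top-quartile-mean normalization, duplicate QC, PCA screen.

The processing order mirrors a standard nCounter workflow: derive a
per-sample background threshold from the negative-control probes, drop
endogenous probes that fail to clear it in at least half the samples, then
rescale each sample so the mean of its top quartile of probe values equals a
common reference (the geometric mean of the per-sample top-quartile means).
A PCA screen on the log2-transformed normalized matrix flags covariates
(batch, technical artifacts) associated with the leading components.

Conventions fixed here: sample standard deviation uses the n-1 denominator
throughout; "top quartile" is the highest ceil(p/4) probes of a sample, ties
broken by probe order; downstream modeling uses log2(normalized + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .exceptions import (
    ConfigurationError,
    DegenerateSampleError,
    EmptyPanelError,
    ParameterError,
    ValidationError,
)

BACKGROUND_METHODS = ("mean_neg", "max_neg", "mean_plus_2sd")


@dataclass
class BackgroundThresholds:
    """Per-sample background thresholds derived from negative controls."""

    values: pd.Series  # indexed by sample id
    method: str


@dataclass
class NormalizationFactors:
    """Per-sample scale factors and the common top-quartile-mean reference."""

    factors: pd.Series
    reference: float


def compute_background_threshold(
    matrix: ExpressionMatrix, annot: pd.DataFrame, method: str = "mean_neg"
) -> BackgroundThresholds:
    """Per-sample background from the negative-control probes.

    ``mean_neg``: mean negative-control count per sample (default);
    ``max_neg``: maximum; ``mean_plus_2sd``: mean + 2 sample SDs.
    """
    if method not in BACKGROUND_METHODS:
        raise ConfigurationError(f"unknown background method {method!r}")
    neg_ids = annot.loc[annot["probe_class"] == "negative_control", "probe_id"]
    neg_ids = [p for p in neg_ids if p in matrix.values.index]
    if not neg_ids:
        raise ConfigurationError("no negative-control probes present in the matrix")
    neg = matrix.values.loc[neg_ids]
    if method == "mean_neg":
        thr = neg.mean(axis=0)
    elif method == "max_neg":
        thr = neg.max(axis=0)
    else:
        thr = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    return BackgroundThresholds(values=thr.astype(float), method=method)


def filter_low_expression(
    matrix: ExpressionMatrix,
    annot: pd.DataFrame,
    thresholds: BackgroundThresholds,
    min_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Drop endogenous probes below background in >= ``min_fraction`` of samples.

    "Below" is strict; a probe under the threshold in exactly half the
    samples is dropped at the default ``min_fraction=0.5``. Control probes
    never enter the retained set. Probe order is preserved.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ParameterError("min_fraction must lie in (0, 1]")
    thr = thresholds.values.reindex(matrix.sample_ids)
    if thr.isna().any():
        raise ValidationError("thresholds missing for some samples")
    classes = annot.set_index("probe_id")["probe_class"]
    endo = [p for p in matrix.probe_ids if classes.get(p) == "endogenous"]
    if not endo:
        raise EmptyPanelError("matrix contains no endogenous probes")
    sub = matrix.values.loc[endo]
    below = sub.lt(thr, axis=1)
    frac_below = below.mean(axis=1)
    keep = frac_below[frac_below < min_fraction].index.tolist()
    if not keep:
        raise EmptyPanelError(
            "all endogenous probes fall below background; nothing to analyze"
        )
    return replace(matrix, values=matrix.values.loc[keep], filtered=True)


def _top_quartile_mean(col: np.ndarray) -> float:
    """Mean of the highest ceil(p/4) values; ties broken by probe order."""
    p = len(col)
    k = max(1, int(np.ceil(p / 4)))
    # stable sort on (-value) keeps earlier probes first among ties
    order = np.argsort(-col, kind="stable")
    return float(col[order[:k]].mean())


def normalize_top_quartile(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, NormalizationFactors]:
    """Top-quartile-mean normalization.

    Each sample is scaled so the mean of its top quartile of probe values
    equals the reference, taken as the geometric mean of the per-sample
    top-quartile means (a single sample is its own reference, factor 1).
    Normalizing an already-normalized matrix is a no-op up to float error.
    """
    vals = matrix.values.to_numpy(dtype=float)
    tq = np.array([_top_quartile_mean(vals[:, j]) for j in range(vals.shape[1])])
    if (tq <= 0).any():
        bad = [matrix.sample_ids[j] for j in np.flatnonzero(tq <= 0)]
        raise DegenerateSampleError(
            f"samples with nonpositive top-quartile mean cannot be normalized: {bad[:5]}"
        )
    reference = float(np.exp(np.mean(np.log(tq))))
    factors = reference / tq
    out = pd.DataFrame(
        vals * factors[None, :], index=matrix.values.index, columns=matrix.values.columns
    )
    state = "filtered+normalized" if matrix.filtered else "normalized"
    return (
        ExpressionMatrix(out, state=state, filtered=matrix.filtered),
        NormalizationFactors(
            factors=pd.Series(factors, index=matrix.sample_ids), reference=reference
        ),
    )


@dataclass
class DuplicateQC:
    """Assay-reliability summary from technical duplicate pairs."""

    per_pair_cv_pct: pd.Series  # indexed by (original, duplicate)
    mean_cv_pct: float
    n_pairs: int
    n_probes: int


def duplicate_cv(
    matrix: ExpressionMatrix, pairs: Sequence[tuple[str, str]]
) -> DuplicateQC:
    """Mean coefficient of variation across duplicate pairs and probes.

    Per pair and probe, CV = SD / mean over the two measurements (sample SD,
    n-1); probes with zero pair mean are excluded. The summary is the mean CV
    over all probes and pairs, as a percentage.
    """
    if not pairs:
        raise ParameterError("at least one duplicate pair is required")
    known = set(matrix.sample_ids)
    per_pair = {}
    all_cvs = []
    for a, b in pairs:
        missing = [s for s in (a, b) if s not in known]
        if missing:
            raise ValidationError(f"duplicate pair references unknown samples: {missing}")
        x = matrix.values[a].to_numpy(dtype=float)
        y = matrix.values[b].to_numpy(dtype=float)
        mean = (x + y) / 2.0
        sd = np.abs(x - y) / np.sqrt(2.0)  # two-point sample SD (ddof=1)
        ok = mean > 0
        cv = sd[ok] / mean[ok]
        per_pair[(a, b)] = float(cv.mean() * 100.0)
        all_cvs.append(cv)
    pooled = np.concatenate(all_cvs)
    return DuplicateQC(
        per_pair_cv_pct=pd.Series(per_pair),
        mean_cv_pct=float(pooled.mean() * 100.0),
        n_pairs=len(pairs),
        n_probes=matrix.n_probes,
    )


@dataclass
class PcaScreen:
    """Confounder screen: PC scores vs. categorical covariates."""

    variance_explained: pd.Series  # fraction per PC
    pvalues: pd.DataFrame  # PCs x covariates
    flagged: pd.Series  # covariate -> bool (any PC association below alpha)
    alpha: float


def pca_screen(
    matrix: ExpressionMatrix,
    covariates: pd.DataFrame,
    n_components: int = 5,
    alpha: float = 0.01,
) -> PcaScreen:
    """Screen for confounding structure in the leading principal components.

    PCA runs on log2(x+1)-transformed, column-centered data (samples as
    observations). Each categorical covariate is tested against each PC with
    a Wilcoxon rank-sum (2 levels) or Kruskal-Wallis (>2 levels) test; a
    covariate is flagged when any PC association falls below ``alpha``.

    ``covariates`` must be indexed by sample id (or carry a ``sample_id``
    column); every column is treated as categorical.
    """
    if "sample_id" in covariates.columns:
        covariates = covariates.set_index("sample_id")
    covariates = covariates.loc[matrix.sample_ids]
    n, p = matrix.n_samples, matrix.n_probes
    if n_components > min(n, p):
        raise ParameterError(
            f"n_components={n_components} exceeds min(n_samples, n_probes)={min(n, p)}"
        )
    X = np.log2(matrix.values.to_numpy(dtype=float).T + 1.0)
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2 / max(n - 1, 1)
    var_frac = var / var.sum() if var.sum() > 0 else var
    scores = U[:, :n_components] * s[:n_components]

    pcs = [f"PC{i+1}" for i in range(n_components)]
    pvals = pd.DataFrame(index=pcs, columns=covariates.columns, dtype=float)
    for cov in covariates.columns:
        levels = covariates[cov].astype(str)
        uniq = levels.unique()
        for i, pc in enumerate(pcs):
            groups = [scores[levels.to_numpy() == lv, i] for lv in uniq]
            if len(uniq) < 2 or min(len(g) for g in groups) == 0:
                pvals.loc[pc, cov] = np.nan
            elif len(uniq) == 2:
                pvals.loc[pc, cov] = stats.ranksums(groups[0], groups[1]).pvalue
            else:
                pvals.loc[pc, cov] = stats.kruskal(*groups).pvalue
    flagged = (pvals < alpha).any(axis=0)
    return PcaScreen(
        variance_explained=pd.Series(var_frac[:n_components], index=pcs),
        pvalues=pvals,
        flagged=flagged,
        alpha=alpha,
    )


def log_transform(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Modeling matrix: log2(normalized + 1), transposed to samples x features."""
    return np.log2(matrix.values.T + 1.0)
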