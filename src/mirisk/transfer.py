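"""Tissue-to-serum panel transfer.

Probes on the two platforms are matched by identical mature sequence (after
U/T harmonization and case folding); panel probes that stay detectable above
the serum background in more than a minimum number of subjects are kept; the
tissue model is refit on the surviving panel and locked; serum subjects are
scored, binned into risk-score quartiles, and per-quartile breast-cancer
odds ratios are estimated against the lowest quartile.

Because digital tissue counts and serum array intensities are not
commensurable, prediction on the second platform applies a per-feature
z-standardization using the serum cohort's own statistics before mapping
onto the tissue model's scale — a deliberate modeling choice, flagged in the
docs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .exceptions import EmptyPanelError, ParameterError, ValidationError
from .preprocess import BackgroundThresholds
from .splsda import SplsdaModel, fit_splsda, tune_splsda


def _normalize_sequence(seq: str) -> str:
    return str(seq).upper().replace("T", "U")


@dataclass
class TransferMap:
    """One-to-one cross-platform probe pairs matched by mature sequence."""

    pairs: pd.DataFrame  # columns probe_a, probe_b, sequence
    unmatched_a: list[str]
    unmatched_b: list[str]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def to_serum(self, tissue_probes: Sequence[str]) -> dict[str, str]:
        """tissue probe id -> serum probe id for the matched subset."""
        m = dict(zip(self.pairs["probe_a"], self.pairs["probe_b"]))
        return {p: m[p] for p in tissue_probes if p in m}


def _sequence_index(annot: pd.DataFrame, side: str) -> dict[str, str]:
    """sequence -> probe id; within-platform duplicates resolved by name order."""
    endo = annot[annot["probe_class"] == "endogenous"] \
        if "probe_class" in annot.columns else annot
    missing = endo.loc[endo["sequence"].fillna("").str.len() == 0, "probe_id"]
    if len(missing):
        raise ValidationError(
            f"endogenous probes without sequence on panel {side}: {list(missing[:5])}"
        )
    index: dict[str, str] = {}
    dropped = []
    for _, row in endo.sort_values("probe_id").iterrows():
        seq = _normalize_sequence(row["sequence"])
        if seq in index:
            dropped.append(row["probe_id"])
        else:
            index[seq] = row["probe_id"]
    if dropped:
        warnings.warn(
            f"panel {side}: {len(dropped)} duplicate-sequence probe(s) resolved "
            f"by name tie-break: {dropped[:5]}"
        )
    return index


def match_probes_by_sequence(
    panel_a: pd.DataFrame, panel_b: pd.DataFrame
) -> TransferMap:
    """Exact-sequence matching between two probe annotations.

    Sequences are case-folded and U/T-harmonized first; duplicates within a
    platform collapse to the lexicographically first probe name (logged as a
    warning). Matching is symmetric.
    """
    ia = _sequence_index(panel_a, "a")
    ib = _sequence_index(panel_b, "b")
    shared = sorted(set(ia) & set(ib), key=lambda s: ia[s])
    pairs = pd.DataFrame(
        {"probe_a": [ia[s] for s in shared],
         "probe_b": [ib[s] for s in shared],
         "sequence": shared}
    )
    return TransferMap(
        pairs=pairs,
        unmatched_a=sorted(v for s, v in ia.items() if s not in ib),
        unmatched_b=sorted(v for s, v in ib.items() if s not in ia),
    )


def detectable_in_serum(
    serum_matrix: ExpressionMatrix,
    thresholds: BackgroundThresholds,
    min_subjects: int = 50,
    probes: Sequence[str] | None = None,
) -> list[str]:
    """Probes above the serum background in strictly more than ``min_subjects``.

    Restrict to ``probes`` (e.g. the transferred panel) when given; order is
    preserved.
    """
    n = serum_matrix.n_samples
    if min_subjects >= n:
        raise ParameterError(
            f"min_subjects={min_subjects} must be below the cohort size {n}"
        )
    thr = thresholds.values.reindex(serum_matrix.sample_ids)
    if thr.isna().any():
        raise ValidationError("thresholds missing for some serum samples")
    candidates = list(probes) if probes is not None else serum_matrix.probe_ids
    missing = [p for p in candidates if p not in serum_matrix.values.index]
    if missing:
        raise ValidationError(f"probes absent from serum matrix: {missing[:5]}")
    sub = serum_matrix.values.loc[candidates]
    above = sub.gt(thr, axis=1).sum(axis=1)
    return [p for p in candidates if above[p] > min_subjects]


def subset_and_refit(
    discovery_X: pd.DataFrame,
    discovery_y: Sequence[str],
    retained_panel: Sequence[str],
    retune: bool = True,
    keepX_grid: Sequence[int] = (5, 10, 15, 20, 25),
    ncomp: int = 3,
    keepX: int | None = None,
    folds: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> SplsdaModel:
    """Refit the discovery model on the panel surviving serum transfer.

    The discovery matrix is restricted to ``retained_panel``; with
    ``retune=True`` keepX is re-chosen by CV on the restricted panel,
    otherwise the supplied (or previous) ``keepX`` is frozen. keepX values
    are clamped to the panel size. The returned model is locked: apply it to
    serum data without further fitting.
    """
    panel = list(retained_panel)
    if not panel:
        raise EmptyPanelError("retained panel is empty")
    missing = [p for p in panel if p not in discovery_X.columns]
    if missing:
        raise ParameterError(f"panel probes absent from discovery data: {missing[:5]}")
    Xp = discovery_X[panel]
    if retune and len(panel) > 1:
        grid = sorted({min(k, len(panel)) for k in keepX_grid})
        tuned = tune_splsda(Xp, discovery_y, keepX_grid=grid,
                            ncomp_grid=(ncomp,), folds=folds, seed=seed, **fit_kwargs)
        keepX = tuned.best_keepX
        ncomp = tuned.best_ncomp
    elif keepX is not None:
        keepX = min(keepX, len(panel))
    return fit_splsda(Xp, discovery_y, ncomp=ncomp, keepX=keepX, **fit_kwargs)


def zstandardize_to_model(
    model: SplsdaModel, serum_X: pd.DataFrame, target: str = "balanced"
) -> pd.DataFrame:
    """Map serum intensities onto the tissue model's feature scale.

    Per feature: z-score using the serum cohort's own mean/SD, then rescale
    into the model's feature SD around a target center. Digital tissue
    counts and serum array intensities are not commensurable, so this is a
    deliberate modeling choice: it assumes comparable within-cohort
    orderings across platforms.

    ``target="balanced"`` (default) centers the serum population on the
    average of the tissue model's per-class feature means — appropriate for
    a matched case-control serum cohort, whose population is balanced by
    design while the tissue training set need not be. ``target="training"``
    centers on the pooled training mean instead.
    """
    if target not in ("balanced", "training"):
        raise ParameterError(f"unknown standardization target {target!r}")
    missing = [f for f in model.feature_names if f not in serum_X.columns]
    if missing:
        raise ParameterError(f"serum data missing model features: {missing[:5]}")
    sub = serum_X[model.feature_names].astype(float)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1).replace(0.0, 1.0)
    z = (sub - mu) / sd
    center = model.x_mean
    if target == "balanced" and model.x_mean_balanced is not None:
        center = model.x_mean_balanced
    return z * model.x_scale + center


def assign_quartiles(scores: pd.Series) -> pd.Series:
    """Quartile (1-4) from the score distribution of all subjects.

    Rank-based: subjects are ordered by score (ties broken by input order)
    and split into four nearly equal groups, any remainder spread from the
    lowest quartile up.
    """
    n = len(scores)
    if n < 4:
        raise ParameterError("at least four subjects are required for quartiles")
    order = np.argsort(scores.to_numpy(), kind="stable")
    q = np.empty(n, dtype=int)
    q[order] = np.floor(np.arange(n) * 4 / n).astype(int) + 1
    return pd.Series(q, index=scores.index, name="quartile")


def risk_score_table(
    model: SplsdaModel, serum_X: pd.DataFrame, outcomes: Sequence[str],
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-subject continuous risk score, quartile, and outcome."""
    from .splsda import risk_score  # local import to avoid cycle at module load

    X = zstandardize_to_model(model, serum_X) if standardize else serum_X
    score = risk_score(model, X)
    return pd.DataFrame(
        {
            "score": score,
            "quartile": assign_quartiles(score),
            "outcome": list(outcomes),
        },
        index=serum_X.index,
    )


def quartile_or(
    scores: pd.DataFrame, positive_outcome: str = "case"
) -> pd.DataFrame:
    """Breast-cancer odds ratios for quartiles 2-4 of the risk score vs. 1.

    OR_q is the 2 x 2 cross-product (cases_q * controls_Q1) / (controls_q *
    cases_Q1) — identical to the indicator-coded unadjusted logistic fit —
    with Wald 95% CI exp(ln OR +/- 1.96 * sqrt(sum of reciprocal cells)).
    Zero cells yield unbounded CIs with a warning; no continuity correction
    is applied.
    """
    for col in ("quartile", "outcome"):
        if col not in scores.columns:
            raise ParameterError(f"scores table missing column {col!r}")
    tab = (
        scores.assign(case=(scores["outcome"] == positive_outcome))
        .groupby("quartile")["case"]
        .agg(cases="sum", total="count")
    )
    tab["controls"] = tab["total"] - tab["cases"]
    if 1 not in tab.index or tab.loc[1, "cases"] == 0 or tab.loc[1, "controls"] == 0:
        raise ParameterError("the first quartile needs at least one case and one control")
    a1, b1 = float(tab.loc[1, "cases"]), float(tab.loc[1, "controls"])
    rows = []
    for q in sorted(tab.index):
        aq, bq = float(tab.loc[q, "cases"]), float(tab.loc[q, "controls"])
        if q == 1:
            rows.append({"quartile": q, "cases": int(aq), "controls": int(bq),
                         "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan})
            continue
        if min(aq, bq) == 0:
            warnings.warn(f"quartile {q} has a zero cell; CI is unbounded")
            or_q = np.inf if bq == 0 else 0.0
            rows.append({"quartile": q, "cases": int(aq), "controls": int(bq),
                         "odds_ratio": or_q, "ci_low": 0.0, "ci_high": np.inf})
            continue
        or_q = (aq * b1) / (bq * a1)
        se = math.sqrt(1 / aq + 1 / bq + 1 / a1 + 1 / b1)
        rows.append(
            {
                "quartile": q, "cases": int(aq), "controls": int(bq),
                "odds_ratio": or_q,
                "ci_low": math.exp(math.log(or_q) - 1.96 * se),
                "ci_high": math.exp(math.log(or_q) + 1.96 * se),
            }
        )
    return pd.DataFrame(rows).set_index("quartile")
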