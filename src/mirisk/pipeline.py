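"""End-to-end pipeline driver.

Runs the full workflow on a discovery cohort (train), an optional
replication cohort (independent evaluation of the locked model), and an
optional serum cohort (panel transfer, rescoring, quartile odds ratios):

    filter -> normalize -> duplicate QC -> [univariate screen] ->
    tune/fit sPLS-DA -> evaluate -> [permutation test] -> [serum transfer]

The discovery filter defines the feature space; held-out cohorts are
normalized on that same probe set so the locked model applies to
commensurately scaled data. Every stage records its parameters in the
report, all randomness descends from one root seed split per stage, and
identical config + seed reproduces the report bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .containers import analysis_samples, cross_validate, duplicate_pairs
from .evaluate import bh_adjust, confusion_metrics, permutation_test, univariate_wilcoxon
from .exceptions import StageError
from .preprocess import (
    compute_background_threshold,
    duplicate_cv,
    filter_low_expression,
    log_transform,
    normalize_top_quartile,
)
from .simulate import SyntheticCohort
from .splsda import fit_splsda, predict_splsda, tune_splsda
from .transfer import (
    detectable_in_serum,
    match_probes_by_sequence,
    quartile_or,
    risk_score_table,
    subset_and_refit,
    zstandardize_to_model,
)

log = logging.getLogger("mirisk")


@dataclass
class PipelineConfig:
    """Every stage parameter, with defaults mirroring the standard workflow."""

    background_method: str = "mean_neg"
    filter_min_fraction: float = 0.5
    run_screen: bool = True
    screen_fdr_q: float = 0.10
    ncomp: int = 3
    keepX_grid: tuple[int, ...] = (5, 10, 15, 20, 25)
    tune: bool = True
    keepX: int | None = None
    folds: int = 10
    prediction_distance: str = "max_dist"
    permutation_B: int = 99
    permutation_scope: str = "refit"  # "refit" (frozen keepX) or "retune"
    serum_min_subjects: int = 50
    serum_background_method: str = "mean_plus_2sd"
    serum_retune: bool = True
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the root seed."""
        offsets = {"tune": 1, "permutation": 2, "serum": 3}
        return (self.seed * 7919 + offsets.get(stage, 0)) % (2**31 - 1)


def _qc_entry(cohort: SyntheticCohort, probes: list[str] | None = None) -> float | None:
    """Duplicate CV on the above-background probes (counts near the noise
    floor are rounding-dominated and would understate assay reliability)."""
    pairs = duplicate_pairs(cohort.samples)
    if not pairs:
        return None
    matrix = cohort.matrix.subset_probes(probes) if probes else cohort.matrix
    return duplicate_cv(matrix, pairs).mean_cv_pct


def _labels(cohort: SyntheticCohort) -> pd.Series:
    keep = analysis_samples(cohort.samples)
    return keep.set_index("sample_id")["group"]


def _modeling_matrix(cohort: SyntheticCohort, probes: list[str]) -> pd.DataFrame:
    """Normalize a cohort on a fixed probe set and return log2 samples x features."""
    sub = cohort.matrix.subset_probes(probes)
    normalized, _ = normalize_top_quartile(sub)
    y = _labels(cohort)
    return log_transform(normalized).loc[y.index]


def run_pipeline(
    config: PipelineConfig,
    discovery: SyntheticCohort,
    replication: SyntheticCohort | None = None,
    serum: SyntheticCohort | None = None,
    serum_positive: str = "case",
) -> dict:
    """Execute the full workflow and return a JSON-serializable report."""
    report: dict = {"config": asdict(config)}

    # ---- preprocess discovery: background filter defines the feature space
    try:
        cross_validate(discovery.matrix, discovery.probes, discovery.samples)
        thresholds = compute_background_threshold(
            discovery.matrix, discovery.probes, method=config.background_method
        )
        filtered = filter_low_expression(
            discovery.matrix, discovery.probes, thresholds,
            min_fraction=config.filter_min_fraction,
        )
        panel_probes = filtered.probe_ids
        X_disc = _modeling_matrix(discovery, panel_probes)
        y_disc = _labels(discovery)
        report["discovery"] = {
            "n_samples": int(len(y_disc)),
            "n_probes_raw": discovery.matrix.n_probes,
            "n_probes_retained": len(panel_probes),
            "background_method": config.background_method,
            "duplicate_cv_pct": _qc_entry(discovery, panel_probes),
        }
    except Exception as exc:
        raise StageError(f"[preprocess/discovery] {exc}") from exc

    # ---- univariate screen (descriptive, does not gate the model)
    if config.run_screen:
        try:
            pvals = univariate_wilcoxon(X_disc.T, y_disc.to_numpy())
            adj, sig = bh_adjust(pvals, q=config.screen_fdr_q)
            report["screen"] = {
                "n_tested": int(len(pvals)),
                "n_nominal_p05": int((pvals < 0.05).sum()),
                "n_fdr_significant": int(sig.sum()),
                "fdr_q": config.screen_fdr_q,
            }
        except Exception as exc:
            raise StageError(f"[screen] {exc}") from exc

    # ---- tune and fit the sparse PLS-DA model
    try:
        if config.tune:
            tuned = tune_splsda(
                X_disc, y_disc, keepX_grid=config.keepX_grid,
                ncomp_grid=(config.ncomp,), folds=config.folds,
                seed=config.stage_seed("tune"),
                prediction_distance=config.prediction_distance,
            )
            keepX, ncomp = tuned.best_keepX, tuned.best_ncomp
            report["tuning"] = {
                "best_keepX": keepX, "best_ncomp": ncomp,
                "cv_error": tuned.best_error, "folds": tuned.folds,
            }
        else:
            keepX, ncomp = config.keepX, config.ncomp
        model = fit_splsda(
            X_disc, y_disc, ncomp=ncomp, keepX=keepX,
            prediction_distance=config.prediction_distance,
        )
        report["model"] = {
            "ncomp": model.ncomp, "keepX": model.keepX,
            "n_selected": len(model.selected_features),
            "selected_features": model.selected_features,
            "positive_class": model.positive_class,
        }
    except Exception as exc:
        raise StageError(f"[train] {exc}") from exc

    def evaluate(X, y, tag):
        _, pred = predict_splsda(model, X)
        m = confusion_metrics(y, pred.to_numpy(), positive_label=model.positive_class)
        report[f"metrics_{tag}"] = m.as_dict()
        return m

    evaluate(X_disc, y_disc.to_numpy(), "discovery")

    # ---- independent replication of the locked model
    X_rep = y_rep = None
    if replication is not None:
        try:
            cross_validate(replication.matrix, replication.probes, replication.samples)
            X_rep = _modeling_matrix(replication, panel_probes)
            y_rep = _labels(replication)
            report["replication"] = {
                "n_samples": int(len(y_rep)),
                "duplicate_cv_pct": _qc_entry(replication, panel_probes),
            }
            evaluate(X_rep, y_rep.to_numpy(), "replication")
        except Exception as exc:
            raise StageError(f"[replication] {exc}") from exc

    # ---- permutation significance of the frozen procedure
    if config.permutation_B > 0:
        try:
            fixed_keepX, fixed_ncomp = model.keepX, model.ncomp

            def score_fn(X, y_perm):
                if config.permutation_scope == "retune":
                    t = tune_splsda(
                        X, y_perm, keepX_grid=config.keepX_grid,
                        ncomp_grid=(config.ncomp,), folds=config.folds,
                        seed=config.stage_seed("tune"),
                    )
                    m = fit_splsda(X, y_perm, ncomp=t.best_ncomp, keepX=t.best_keepX)
                else:
                    m = fit_splsda(X, y_perm, ncomp=fixed_ncomp, keepX=fixed_keepX)
                if X_rep is not None:
                    _, pred = predict_splsda(m, X_rep)
                    return float(np.mean(pred.to_numpy() == y_rep.to_numpy()))
                _, pred = predict_splsda(m, X)
                return float(np.mean(pred.to_numpy() == np.asarray(y_perm)))

            perm = permutation_test(
                X_disc, y_disc.to_numpy(), score_fn,
                B=config.permutation_B, seed=config.stage_seed("permutation"),
            )
            report["permutation"] = {
                "observed_accuracy": perm.observed_accuracy,
                "p_value": perm.p_value,
                "B": perm.B,
                "scope": config.permutation_scope,
                "scored_on": "replication" if X_rep is not None else "discovery",
            }
        except Exception as exc:
            raise StageError(f"[permtest] {exc}") from exc

    # ---- tissue -> serum transfer
    if serum is not None:
        try:
            report["serum"] = _serum_stage(
                config, model, X_disc, y_disc, discovery.probes, serum, serum_positive
            )
        except Exception as exc:
            raise StageError(f"[transfer] {exc}") from exc
    return report


def _serum_stage(
    config: PipelineConfig,
    model,
    X_disc: pd.DataFrame,
    y_disc: pd.Series,
    tissue_annot: pd.DataFrame,
    serum: SyntheticCohort,
    serum_positive: str,
) -> dict:
    """Sequence matching, detectability filter, locked refit, scoring, quartile ORs."""
    selected = model.selected_features
    panel_annot = tissue_annot[tissue_annot["probe_id"].isin(selected)]
    tmap = match_probes_by_sequence(panel_annot, serum.probes)
    mapping = tmap.to_serum(selected)
    matched_tissue = [p for p in selected if p in mapping]

    thresholds = compute_background_threshold(
        serum.matrix, serum.probes, method=config.serum_background_method
    )
    serum_ids = [mapping[p] for p in matched_tissue]
    detect = set(
        detectable_in_serum(
            serum.matrix, thresholds,
            min_subjects=config.serum_min_subjects, probes=serum_ids,
        )
    )
    retained_tissue = [p for p, s in zip(matched_tissue, serum_ids) if s in detect]

    refit = subset_and_refit(
        X_disc, y_disc, retained_tissue, retune=config.serum_retune,
        keepX_grid=config.keepX_grid,
        ncomp=min(config.ncomp, max(1, len(retained_tissue) - 1)),
        keepX=None if config.serum_retune else config.keepX,
        folds=config.folds, seed=config.stage_seed("serum"),
    )
    _, pred_disc = predict_splsda(refit, X_disc)
    metrics_disc = confusion_metrics(
        y_disc.to_numpy(), pred_disc.to_numpy(), positive_label=refit.positive_class
    )

    # serum side: renormalize within platform, log, map ids back to tissue names
    serum_sub = serum.matrix.subset_probes(
        [mapping[p] for p in retained_tissue]
    )
    normalized, _ = normalize_top_quartile(serum_sub)
    y_serum = _labels(serum)
    X_serum = log_transform(normalized).loc[y_serum.index]
    X_serum = X_serum.rename(columns={mapping[p]: p for p in retained_tissue})

    table = risk_score_table(refit, X_serum, y_serum.to_numpy())
    _, pred = predict_splsda(refit, zstandardize_to_model(refit, X_serum))
    # the refit model speaks tissue labels (high/low); translate to the
    # serum vocabulary (case/control) before scoring
    serum_classes = sorted(set(y_serum))
    serum_negative = next(c for c in serum_classes if c != serum_positive)
    pred = pred.map({refit.classes[1]: serum_positive, refit.classes[0]: serum_negative})
    metrics = confusion_metrics(
        y_serum.to_numpy(), pred.to_numpy(), positive_label=serum_positive
    )
    ors = quartile_or(table, positive_outcome=serum_positive)
    return {
        "n_panel": len(selected),
        "n_matched": len(matched_tissue),
        "n_detectable": len(retained_tissue),
        "refit_keepX": refit.keepX,
        "metrics_discovery_refit": metrics_disc.as_dict(),
        "metrics": metrics.as_dict(),
        "quartile_or": ors.reset_index().to_dict(orient="records"),
    }
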