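"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: an
nCounter-style count matrix (~800 probes, a handful of negative/positive
controls), a planted subset of risk-associated miRNAs shifted between the
high- and low-risk groups, a lognormal spread of per-sample library sizes,
technical duplicates re-assayed for QC, and a second, serum-like platform on
which only part of a tissue panel remains detectable and the group signal is
attenuated.

Counts follow a negative-binomial model: for probe *p* in sample *s* with
latent log2 expression mu and library factor f, counts are NB with mean
f * 2^mu and variance mean + dispersion * mean^2 (dispersion 0 = Poisson).
Probes split into an "expressed" minority (latent log2 means drawn uniformly
well above background) and a majority fluctuating at the negative-control
background floor, so the background filter has real work to do. Informative
probes are always expressed and shifted by ``effect_size`` log2 units in the
positive (high-risk / case) group.

Technical duplicates are multiplicative lognormal jitters of the original
counts, calibrated so the expected duplicate coefficient of variation matches
``duplicate_cv`` (pair CV of (x, x*e^eps), eps ~ N(0, s): E[CV] ~ s/sqrt(pi),
hence s = duplicate_cv * sqrt(pi)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_probe_annotation, validate_sample_table
from .exceptions import ParameterError

_DEFAULT_GROUPS = {"low": 75, "high": 15}
_POSITIVE_LABELS = ("high", "case")

#: Marginal category frequencies used by :func:`simulate_gail_covariates`,
#: matching the discovery reduction-mammoplasty cohort (n=90).
DEFAULT_GAIL_MARGINS: dict[str, dict[str, float]] = {
    "age_band": {"<50": 62 / 90, ">=50": 28 / 90},
    "age_at_menarche": {
        "<12": 15 / 90, "12-13": 43 / 90, ">=14": 16 / 90, "unknown": 16 / 90,
    },
    "age_at_first_live_birth": {
        "nulliparous": 22 / 90, "<20": 9 / 90, "20-24": 12 / 90,
        "25-29": 16 / 90, ">=30": 11 / 90, "unknown": 20 / 90,
    },
    "n_first_degree_relatives": {"0": 57 / 90, "1": 8 / 90, "unknown": 25 / 90},
    "n_biopsies": {"0": 40 / 90, "1": 6 / 90, ">=2": 2 / 90, "unknown": 42 / 90},
}


@dataclass
class SimulationParams:
    """Knobs of the cohort generator.

    ``n_probes`` counts every probe on the panel, controls included; the
    endogenous panel is ``n_probes - n_negative_controls - n_positive_controls``.
    ``effect_size`` is the planted log2 fold change between groups,
    ``dispersion`` the NB overdispersion (var = mu + dispersion * mu^2),
    ``library_size_spread`` the multiplicative range of per-sample scale
    factors (log-uniform on [1/spread, spread]).

    ``seed`` fixes the probe landscape (sequences, which probes are
    expressed, which are informative, latent baselines) *and*, by default,
    the subject draw. Set ``subject_seed`` to redraw subjects over the same
    probe landscape — that is how a replication cohort of the same assay is
    simulated.
    """

    n_probes: int = 800
    n_negative_controls: int = 6
    n_positive_controls: int = 6
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_GROUPS))
    n_informative: int = 10
    effect_size: float = 2.0
    dispersion: float = 0.05
    background_mean: float = 5.0
    expressed_fraction: float = 0.25
    expressed_log2_range: tuple[float, float] = (5.0, 12.0)
    library_size_spread: float = 1.5
    duplicate_fraction: float = 0.10
    duplicate_cv: float = 0.04
    seed: int = 0
    subject_seed: int | None = None

    @property
    def n_endogenous(self) -> int:
        return self.n_probes - self.n_negative_controls - self.n_positive_controls

    def validate(self) -> None:
        if self.n_endogenous <= 0:
            raise ParameterError("n_probes must exceed the number of control probes")
        if self.n_informative < 0 or self.n_informative > self.n_endogenous:
            raise ParameterError(
                "n_informative must lie in [0, n_probes - controls]"
            )
        if not self.group_sizes or len(self.group_sizes) != 2:
            raise ParameterError("group_sizes must define exactly two groups")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ParameterError("group sizes must be positive")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ParameterError("duplicate_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.library_size_spread < 1.0:
            raise ParameterError("library_size_spread must be >= 1")
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ParameterError("expressed_fraction must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """A simulated cohort: raw counts, annotations, and the planted truth."""

    matrix: ExpressionMatrix
    probes: pd.DataFrame
    samples: pd.DataFrame
    truth: list[str]

    def __post_init__(self) -> None:
        validate_probe_annotation(self.probes)
        validate_sample_table(self.samples)
        unknown = set(self.truth) - set(self.probes["probe_id"])
        if unknown:
            raise ParameterError(f"truth probes not on the panel: {sorted(unknown)[:5]}")


def _positive_label(group_sizes: Mapping[str, int]) -> str:
    for label in _POSITIVE_LABELS:
        if label in group_sizes:
            return label
    # fall back to the smaller group (ties: last in sorted order)
    return sorted(group_sizes, key=lambda g: (group_sizes[g], g))[-1]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mean + dispersion*mean^2."""
    mean = np.clip(mean, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _random_sequences(rng: np.random.Generator, n: int, length: int = 22) -> list[str]:
    letters = np.array(list("ACGU"))
    draws = rng.integers(0, 4, size=(n, length))
    return ["".join(letters[row]) for row in draws]


def _probe_annotation(
    rng: np.random.Generator, params: SimulationParams, platform: str,
    prefix: str, sequences: Sequence[str] | None = None,
) -> pd.DataFrame:
    n_endo = params.n_endogenous
    endo_ids = [f"{prefix}-mir-{i:04d}" for i in range(n_endo)]
    neg_ids = [f"{prefix}-neg-{i}" for i in range(params.n_negative_controls)]
    pos_ids = [f"{prefix}-pos-{i}" for i in range(params.n_positive_controls)]
    if sequences is None:
        sequences = _random_sequences(rng, n_endo)
    return pd.DataFrame(
        {
            "probe_id": endo_ids + neg_ids + pos_ids,
            "probe_class": (["endogenous"] * n_endo
                            + ["negative_control"] * params.n_negative_controls
                            + ["positive_control"] * params.n_positive_controls),
            "sequence": list(sequences) + [""] * (len(neg_ids) + len(pos_ids)),
            "platform": platform,
        }
    )


def _simulate_counts(
    rng: np.random.Generator,
    params: SimulationParams,
    annot: pd.DataFrame,
    mu_log2: np.ndarray,
    informative: np.ndarray,
    effect_size: float,
    sample_prefix: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw raw counts and the sample table (duplicates included)."""
    groups = list(params.group_sizes)
    pos = _positive_label(params.group_sizes)
    sample_ids, sample_groups = [], []
    for g in groups:
        for i in range(params.group_sizes[g]):
            sample_ids.append(f"{sample_prefix}-{g}-{i:03d}")
            sample_groups.append(g)
    n_samples = len(sample_ids)

    spread = params.library_size_spread
    lib = np.exp(rng.uniform(-math.log(spread), math.log(spread), size=n_samples))

    endo = annot["probe_class"].to_numpy() == "endogenous"
    neg = annot["probe_class"].to_numpy() == "negative_control"
    n_probes = len(annot)
    mu = np.zeros((n_probes, n_samples))
    mu[endo] = mu_log2[:, None]
    shift = np.zeros(n_probes)
    shift[np.flatnonzero(endo)[informative]] = effect_size
    in_pos = np.array([g == pos for g in sample_groups])
    mu[:, in_pos] += shift[:, None]
    mean = lib[None, :] * np.exp2(mu)
    # controls sit at fixed means, independent of group
    mean[neg] = lib[None, :] * params.background_mean
    posctl = annot["probe_class"].to_numpy() == "positive_control"
    if posctl.any():
        ladder = params.background_mean * 2.0 ** np.arange(4, 4 + posctl.sum())
        mean[posctl] = lib[None, :] * ladder[:, None]

    counts = _nb_counts(rng, mean, params.dispersion)
    values = pd.DataFrame(counts, index=annot["probe_id"].tolist(), columns=sample_ids)

    samples = pd.DataFrame(
        {"sample_id": sample_ids, "group": sample_groups, "duplicate_of": pd.NA}
    )

    n_dup = int(round(params.duplicate_fraction * n_samples))
    if n_dup > 0:
        dup_idx = rng.choice(n_samples, size=n_dup, replace=False)
        sigma = params.duplicate_cv * math.sqrt(math.pi)
        dup_cols, dup_rows = {}, []
        for j in sorted(dup_idx):
            sid = sample_ids[j]
            jitter = np.exp(rng.normal(0.0, sigma, size=n_probes))
            dup_cols[f"{sid}-dup"] = np.round(values[sid].to_numpy() * jitter).astype(int)
            dup_rows.append(
                {"sample_id": f"{sid}-dup", "group": sample_groups[j], "duplicate_of": sid}
            )
        values = pd.concat([values, pd.DataFrame(dup_cols, index=values.index)], axis=1)
        samples = pd.concat([samples, pd.DataFrame(dup_rows)], ignore_index=True)

    return values, samples


def simulate_tissue_cohort(params: SimulationParams) -> SyntheticCohort:
    """Generate an nCounter-style tissue cohort with planted risk signal.

    Returns a :class:`SyntheticCohort` whose ``truth`` lists the informative
    probes (shifted by ``params.effect_size`` log2 units in the positive
    group). Fully reproducible from ``params.seed``.
    """
    params.validate()
    rng_land = np.random.default_rng(params.seed)
    annot = _probe_annotation(rng_land, params, platform="nanostring", prefix="nsp")
    n_endo = params.n_endogenous

    expressed = rng_land.random(n_endo) < params.expressed_fraction
    informative = rng_land.choice(n_endo, size=params.n_informative, replace=False)
    expressed[informative] = True  # planted probes must clear background
    lo, hi = params.expressed_log2_range
    mu_log2 = np.full(n_endo, math.log2(params.background_mean))
    mu_log2[expressed] = rng_land.uniform(lo, hi, size=int(expressed.sum()))
    # informative probes live in the lower half of the expressed range so the
    # planted shift does not distort the top-quartile normalization reference
    mu_log2[informative] = rng_land.uniform(lo, (lo + hi) / 2,
                                            size=params.n_informative)

    subject_seed = params.seed if params.subject_seed is None else params.subject_seed
    rng_sub = np.random.default_rng([subject_seed, params.seed])
    values, samples = _simulate_counts(
        rng_sub, params, annot, mu_log2, informative, params.effect_size, "rm"
    )
    endo_ids = annot.loc[annot["probe_class"] == "endogenous", "probe_id"].to_numpy()
    truth = sorted(endo_ids[informative])
    return SyntheticCohort(
        matrix=ExpressionMatrix(values, state="raw"),
        probes=annot,
        samples=samples,
        truth=truth,
    )


def simulate_serum_cohort(
    params: SimulationParams,
    tissue_panel: pd.DataFrame,
    detectable_fraction: float,
    attenuation: float = 4.0,
    tissue_truth: Sequence[str] = (),
) -> SyntheticCohort:
    """Generate a serum cohort on a second platform carrying a tissue panel.

    ``tissue_panel`` is the probe annotation of the transferred tissue probes
    (sequences are preserved so cross-platform matching works). Exactly
    ``ceil(detectable_fraction * len(panel))`` panel probes are expressed
    above background; the rest sit at the background floor and fail the serum
    detectability rule. The planted group effect is ``effect_size /
    attenuation`` (``attenuation=inf`` zeroes the signal). Group labels come
    from ``params.group_sizes`` (typically case/control).
    """
    params.validate()
    panel = tissue_panel[tissue_panel.get("probe_class", "endogenous") == "endogenous"] \
        if "probe_class" in tissue_panel.columns else tissue_panel
    if len(panel) == 0:
        raise ParameterError("tissue_panel must contain at least one endogenous probe")
    if not 0.0 < detectable_fraction <= 1.0:
        raise ParameterError("detectable_fraction must lie in (0, 1]")
    if attenuation < 1.0:
        raise ParameterError("attenuation must be >= 1 (inf zeroes the signal)")

    k_panel = len(panel)
    n_extra = max(params.n_endogenous - k_panel, 0)
    serum_params = replace(params, n_probes=k_panel + n_extra
                           + params.n_negative_controls + params.n_positive_controls)

    rng_land = np.random.default_rng(params.seed + 1)
    extra_seq = _random_sequences(rng_land, n_extra)
    sequences = list(panel["sequence"]) + extra_seq
    annot = _probe_annotation(rng_land, serum_params, platform="affymetrix",
                              prefix="afx", sequences=sequences)

    n_endo = serum_params.n_endogenous
    n_detectable = math.ceil(detectable_fraction * k_panel)
    detectable = rng_land.permutation(k_panel)[:n_detectable]

    lo, hi = params.expressed_log2_range
    mu_log2 = np.full(n_endo, math.log2(params.background_mean))
    mu_log2[detectable] = rng_land.uniform(lo, (lo + hi) / 2, size=n_detectable)
    # extra serum-only probes: background-level noise
    effect = 0.0 if math.isinf(attenuation) else params.effect_size / attenuation
    truth_pos = [i for i, pid in enumerate(panel["probe_id"]) if pid in set(tissue_truth)]
    informative = np.array([i for i in truth_pos if i in set(detectable)], dtype=int)

    subject_seed = params.seed if params.subject_seed is None else params.subject_seed
    rng_sub = np.random.default_rng([subject_seed, params.seed + 1])
    values, samples = _simulate_counts(
        rng_sub, serum_params, annot, mu_log2, informative, effect, "ss"
    )
    endo_ids = annot.loc[annot["probe_class"] == "endogenous", "probe_id"].to_numpy()
    truth = sorted(endo_ids[informative]) if len(informative) else []
    return SyntheticCohort(
        matrix=ExpressionMatrix(values, state="raw"),
        probes=annot,
        samples=samples,
        truth=truth,
    )


def simulate_gail_covariates(
    n: int,
    seed: int,
    margins: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Draw Gail-model covariates from categorical margins.

    Default margins reproduce the discovery cohort's characteristics table
    (age band, age at menarche, age at first live birth, first-degree
    relatives with breast cancer, number of biopsies, "unknown" included).
    Ages are drawn uniformly within the sampled band (35-49 / 50-76).
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    margins = {k: dict(v) for k, v in (margins or DEFAULT_GAIL_MARGINS).items()}
    rng = np.random.default_rng(seed)

    def draw(field: str) -> np.ndarray:
        cats = list(margins[field])
        probs = np.array([margins[field][c] for c in cats], dtype=float)
        probs = probs / probs.sum()
        return rng.choice(cats, size=n, p=probs)

    band = draw("age_band")
    age = np.where(band == "<50", rng.integers(35, 50, size=n), rng.integers(50, 77, size=n))
    return pd.DataFrame(
        {
            "age": age.astype(int),
            "age_at_menarche": draw("age_at_menarche"),
            "age_at_first_live_birth": draw("age_at_first_live_birth"),
            "n_first_degree_relatives": draw("n_first_degree_relatives"),
            "n_biopsies": draw("n_biopsies"),
        }
    )
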