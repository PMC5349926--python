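"""Gail-style absolute breast-cancer risk and the high/low threshold rule.

The engine is deliberately table-driven: it consumes log-relative-risk
coefficients per covariate category (with optional biopsy x age and
first-birth x relatives interaction terms) and age-specific baseline
breast-cancer and competing-mortality hazards, supplied as CSV/DataFrames.
The published BCRAT race-specific constants are not embedded; the package
ships a clearly-labeled synthetic toy table for tests and examples.

Absolute 5-year risk uses the standard competing-risk decomposition with
piecewise-constant hazards over 1-year steps: with h1(a) = (RR / mean
population RR) * average breast hazard and h2(a) = competing mortality at
age a,

    risk = sum_a  S(a) * h1(a)/(h1(a)+h2(a)) * (1 - exp(-(h1(a)+h2(a))))

where S(a) is survival from both causes up to the start of year a. With zero
competing mortality and constant hazard this collapses to 1 - exp(-5*RR*h).

A woman is labeled high risk when her 5-year risk is at least (1 + margin)
times the average risk for her age (margin defaults to 0.10: "10% or greater
increased risk"). The boundary is inclusive by default and configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError

_SIMPLE_TERMS = (
    "age_at_menarche",
    "age_at_first_live_birth",
    "n_first_degree_relatives",
    "n_biopsies",
)
_INTERACTION_TERMS = ("biopsy_x_age", "first_birth_x_relatives")


@dataclass
class RiskEngineTables:
    """Coefficient and hazard tables consumed by the risk engine.

    ``log_rr``: columns ``term``, ``category``, ``log_rr``. Terms are any of
    the simple covariates plus the optional interaction terms; each term must
    include a zero-coefficient reference category.
    ``hazards``: columns ``age``, ``breast_hazard``, ``mortality_hazard``
    (annual rates, one row per integer age). The breast hazard is read as the
    *population-average* incidence; ``average_rr`` is the mean relative risk
    in that population, so an individual's hazard is
    (RR / average_rr) * breast_hazard (the attributable-risk correction) and
    a woman with RR = average_rr sits exactly at average risk.
    """

    log_rr: pd.DataFrame
    hazards: pd.DataFrame
    average_rr: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        for col in ("term", "category", "log_rr"):
            if col not in self.log_rr.columns:
                raise ConfigurationError(f"log_rr table missing column {col!r}")
        for col in ("age", "breast_hazard", "mortality_hazard"):
            if col not in self.hazards.columns:
                raise ConfigurationError(f"hazard table missing column {col!r}")
        if (self.hazards[["breast_hazard", "mortality_hazard"]] < 0).any().any():
            raise ConfigurationError("hazards must be nonnegative")
        if self.average_rr <= 0:
            raise ConfigurationError("average_rr must be positive")
        known = set(_SIMPLE_TERMS) | set(_INTERACTION_TERMS)
        bad = set(self.log_rr["term"]) - known
        if bad:
            raise ConfigurationError(f"unknown terms in log_rr table: {sorted(bad)}")
        for term, grp in self.log_rr.groupby("term"):
            if not np.isclose(grp["log_rr"], 0.0).any():
                raise ConfigurationError(
                    f"term {term!r} has no zero-coefficient reference category"
                )

    @classmethod
    def from_csv(cls, coeff_path: str | Path, hazard_path: str | Path,
                 provenance: str = "") -> "RiskEngineTables":
        return cls(
            log_rr=pd.read_csv(coeff_path),
            hazards=pd.read_csv(hazard_path),
            provenance=provenance or f"{coeff_path};{hazard_path}",
        )

    def reference_category(self, term: str) -> str:
        grp = self.log_rr[self.log_rr["term"] == term]
        ref = grp.loc[np.isclose(grp["log_rr"], 0.0), "category"]
        return str(ref.iloc[0])


def toy_tables() -> RiskEngineTables:
    """Synthetic coefficient/hazard tables for tests and examples.

    The coefficients are invented but ordered like the real risk factors
    (earlier menarche, later first birth, family history and biopsies raise
    risk); hazards rise gently with age. Not calibrated to any population.
    """
    rows = [
        ("age_at_menarche", ">=14", 0.0), ("age_at_menarche", "12-13", 0.10),
        ("age_at_menarche", "<12", 0.21), ("age_at_menarche", "unknown", 0.0),
        ("age_at_first_live_birth", "<20", 0.0),
        ("age_at_first_live_birth", "20-24", 0.12),
        ("age_at_first_live_birth", "25-29", 0.25),
        ("age_at_first_live_birth", "nulliparous", 0.25),
        ("age_at_first_live_birth", ">=30", 0.40),
        ("age_at_first_live_birth", "unknown", 0.0),
        ("n_first_degree_relatives", "0", 0.0),
        ("n_first_degree_relatives", "1", 0.45),
        ("n_first_degree_relatives", ">=2", 0.80),
        ("n_first_degree_relatives", "unknown", 0.0),
        ("n_biopsies", "0", 0.0), ("n_biopsies", "1", 0.30),
        ("n_biopsies", ">=2", 0.55), ("n_biopsies", "unknown", 0.0),
    ]
    log_rr = pd.DataFrame(rows, columns=["term", "category", "log_rr"])
    ages = np.arange(20, 91)
    hazards = pd.DataFrame(
        {
            "age": ages,
            "breast_hazard": 1e-5 * np.exp(0.09 * (ages - 20)),
            "mortality_hazard": 2e-4 * np.exp(0.08 * (ages - 20)),
        }
    )
    # 1.43 ~ mean composite RR under the default covariate margins, so a
    # typical woman sits near average risk
    return RiskEngineTables(log_rr=log_rr, hazards=hazards, average_rr=1.43,
                            provenance="mirisk synthetic toy tables")


def _covariate_category(term: str, cov: Mapping[str, object],
                        tables: RiskEngineTables) -> str:
    """Resolve the category string a subject falls in for a model term."""

    def get(field: str) -> str:
        val = cov.get(field)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return tables.reference_category(field) if field in _SIMPLE_TERMS else ""
        return str(val)

    if term in _SIMPLE_TERMS:
        return get(term)
    if term == "biopsy_x_age":
        age = float(cov["age"])
        return f"{get('n_biopsies')}:{'<50' if age < 50 else '>=50'}"
    if term == "first_birth_x_relatives":
        return f"{get('age_at_first_live_birth')}:{get('n_first_degree_relatives')}"
    raise ConfigurationError(f"unknown term {term!r}")


def relative_risk(cov: Mapping[str, object], tables: RiskEngineTables) -> float:
    """Composite relative risk: exp of the sum of applicable log-RR terms.

    Missing or "unknown" covariates resolve to each term's reference
    category (the zero-coefficient row), mirroring the convention of
    treating unknowns as lowest-risk.
    """
    total = 0.0
    for term, grp in tables.log_rr.groupby("term"):
        category = _covariate_category(term, cov, tables)
        match = grp.loc[grp["category"].astype(str) == category, "log_rr"]
        if match.empty:
            raise ConfigurationError(
                f"category {category!r} of term {term!r} absent from the coefficient table"
            )
        total += float(match.iloc[0])
    return math.exp(total)


def absolute_risk_5yr(
    cov: Mapping[str, object], tables: RiskEngineTables, years: int = 5,
    rr: float | None = None,
) -> float:
    """Absolute breast-cancer risk over [age, age+years) with competing mortality.

    Integrates the RR-scaled baseline breast hazard against survival from
    both breast cancer and competing mortality in 1-year piecewise-constant
    steps. Pass ``rr`` to override the covariate-derived relative risk
    (``rr=1`` gives the average-risk woman of the same age).
    """
    age = int(math.floor(float(cov["age"])))
    haz = tables.hazards.set_index("age")
    needed = range(age, age + years)
    missing = [a for a in needed if a not in haz.index]
    if missing:
        raise ParameterError(
            f"hazard table does not cover ages {missing} (table spans "
            f"{haz.index.min()}-{haz.index.max()})"
        )
    if rr is None:
        rr = relative_risk(cov, tables)
    risk, surv = 0.0, 1.0
    for a in needed:
        h1 = (rr / tables.average_rr) * float(haz.loc[a, "breast_hazard"])
        h2 = float(haz.loc[a, "mortality_hazard"])
        tot = h1 + h2
        if tot > 0:
            risk += surv * (h1 / tot) * (1.0 - math.exp(-tot))
            surv *= math.exp(-tot)
    return risk


def average_risk_5yr(age: float, tables: RiskEngineTables, years: int = 5) -> float:
    """5-year risk of an average-risk woman of the given age (RR = average_rr,
    i.e. the population-average breast hazard unadjusted)."""
    return absolute_risk_5yr({"age": age}, tables, years=years, rr=tables.average_rr)


@dataclass
class RiskLabel:
    """A subject's 5-year risk, the population average, and the high/low call."""

    five_year_risk: float
    average_risk: float
    label: str
    margin: float
    threshold: float


def classify_risk(
    subject_risk: float, average_risk: float, margin: float = 0.10,
    inclusive: bool = True,
) -> RiskLabel:
    """High/low risk call: high iff subject risk >= (1 + margin) * average.

    With the default 10% margin an average 5-year risk of 1% puts the
    high-risk threshold at 1.1%. ``inclusive=False`` switches the boundary
    to a strict inequality.
    """
    if margin < 0:
        raise ParameterError("margin must be nonnegative")
    for name, r in (("subject_risk", subject_risk), ("average_risk", average_risk)):
        if not 0.0 <= r <= 1.0:
            raise ParameterError(f"{name} must be a probability in [0, 1]")
    threshold = (1.0 + margin) * average_risk
    at_boundary = math.isclose(subject_risk, threshold, rel_tol=1e-9)
    high = (subject_risk > threshold and not at_boundary) or (inclusive and at_boundary)
    return RiskLabel(
        five_year_risk=subject_risk,
        average_risk=average_risk,
        label="high" if high else "low",
        margin=margin,
        threshold=threshold,
    )


def label_cohort(
    covariates: pd.DataFrame, tables: RiskEngineTables, margin: float = 0.10
) -> pd.DataFrame:
    """Per-subject risk, average risk and label for a covariate table."""
    out = []
    for _, row in covariates.iterrows():
        cov = row.to_dict()
        risk = absolute_risk_5yr(cov, tables)
        avg = average_risk_5yr(cov["age"], tables)
        lab = classify_risk(risk, avg, margin=margin)
        out.append(
            {
                "five_year_risk": risk,
                "average_risk": avg,
                "threshold": lab.threshold,
                "label": lab.label,
            }
        )
    res = pd.DataFrame(out, index=covariates.index)
    return pd.concat([covariates, res], axis=1)
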