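"""Label simulated women as high/low breast-cancer risk.

Draws Gail-model covariates matching the discovery cohort's margins, runs
the table-driven 5-year absolute-risk engine (synthetic toy coefficient and
hazard tables — not calibrated to any population), and applies the
threshold rule: high risk means a 5-year risk at least 10% above the
average for the same age.
"""

from mirisk import classify_risk, label_cohort, simulate_gail_covariates, toy_tables

covariates = simulate_gail_covariates(90, seed=7)
labels = label_cohort(covariates, toy_tables())

n_high = (labels["label"] == "high").sum()
print(f"{n_high} of {len(labels)} women labeled high risk")
print(labels[["age", "n_biopsies", "five_year_risk", "average_risk",
              "threshold", "label"]].head(5).to_string())

# the documented worked case: average 5-year risk 1% -> threshold 1.1%
rule = classify_risk(subject_risk=0.012, average_risk=0.01, margin=0.10)
print(f"\naverage risk 1.0% -> high-risk threshold {rule.threshold:.3%}; "
      f"a woman at 1.2% is labeled {rule.label!r}")
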