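"""Cross-platform matching, serum detectability, panel refit, quartile ORs."""

import numpy as np
import pandas as pd
import pytest

from mirisk import (
    ExpressionMatrix,
    assign_quartiles,
    detectable_in_serum,
    match_probes_by_sequence,
    quartile_or,
    subset_and_refit,
)
from mirisk.exceptions import EmptyPanelError, ParameterError, ValidationError
from mirisk.preprocess import BackgroundThresholds
from mirisk.splsda import fit_splsda


def _panel(ids_seqs, platform="nano"):
    return pd.DataFrame(
        [(pid, "endogenous", seq, platform) for pid, seq in ids_seqs],
        columns=["probe_id", "probe_class", "sequence", "platform"],
    )


def _random_seqs(n, seed=0, length=20):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGU"), size=length)) for _ in range(n)]


class TestSequenceMatching:
    def test_identical_panels_fully_matched(self):
        seqs = _random_seqs(5)
        a = _panel([(f"a{i}", s) for i, s in enumerate(seqs)])
        b = _panel([(f"b{i}", s) for i, s in enumerate(seqs)], platform="affy")
        tmap = match_probes_by_sequence(a, b)
        assert tmap.n_matched == 5
        assert not tmap.unmatched_a and not tmap.unmatched_b

    def test_single_base_substitution_breaks_match(self):
        seqs = _random_seqs(3, seed=1)
        mutated = seqs.copy()
        mutated[1] = ("A" if mutated[1][0] != "A" else "C") + mutated[1][1:]
        a = _panel([(f"a{i}", s) for i, s in enumerate(seqs)])
        b = _panel([(f"b{i}", s) for i, s in enumerate(mutated)])
        tmap = match_probes_by_sequence(a, b)
        assert tmap.n_matched == 2
        assert tmap.unmatched_a == ["a1"] and tmap.unmatched_b == ["b1"]

    def test_41_probe_panel_with_34_shared(self):
        """Constructed panel mirroring a 41-feature signature of which 34
        sequences exist on the second platform."""
        seqs = _random_seqs(41, seed=2)
        a = _panel([(f"t{i:02d}", s) for i, s in enumerate(seqs)])
        b = _panel([(f"s{i:02d}", s) for i, s in enumerate(seqs[:34])], "affy")
        tmap = match_probes_by_sequence(a, b)
        assert tmap.n_matched == 34
        assert len(tmap.unmatched_a) == 7

    def test_u_t_and_case_harmonization(self):
        a = _panel([("a0", "AACGU")])
        b = _panel([("b0", "aacgt")])
        assert match_probes_by_sequence(a, b).n_matched == 1

    def test_symmetry(self):
        seqs = _random_seqs(10, seed=3)
        a = _panel([(f"a{i}", s) for i, s in enumerate(seqs[:8])])
        b = _panel([(f"b{i}", s) for i, s in enumerate(seqs[3:])])
        ab = match_probes_by_sequence(a, b)
        ba = match_probes_by_sequence(b, a)
        assert set(zip(ab.pairs["probe_a"], ab.pairs["probe_b"])) == set(
            zip(ba.pairs["probe_b"], ba.pairs["probe_a"]))

    def test_within_platform_duplicate_resolved_by_name(self):
        seq = _random_seqs(1, seed=4)[0]
        a = _panel([("zz", seq), ("aa", seq)])
        b = _panel([("b0", seq)])
        with pytest.warns(UserWarning, match="duplicate-sequence"):
            tmap = match_probes_by_sequence(a, b)
        assert list(tmap.pairs["probe_a"]) == ["aa"]

    def test_missing_sequence_rejected(self):
        a = _panel([("a0", "")])
        with pytest.raises(ValidationError):
            match_probes_by_sequence(a, _panel([("b0", "ACGU")]))


class TestSerumDetectability:
    def _serum(self, n_above_by_probe, n_samples=410):
        rows = {}
        for probe, n_above in n_above_by_probe.items():
            rows[probe] = [10] * n_above + [1] * (n_samples - n_above)
        values = pd.DataFrame(rows).T
        values.columns = [f"s{i}" for i in range(n_samples)]
        m = ExpressionMatrix(values, state="raw")
        thr = BackgroundThresholds(
            values=pd.Series(5.0, index=m.sample_ids), method="mean_neg")
        return m, thr

    def test_boundary_exactly_min_subjects_excluded(self):
        m, thr = self._serum({"pA": 50, "pB": 51})
        kept = detectable_in_serum(m, thr, min_subjects=50)
        assert kept == ["pB"]  # "more than 50" is strict

    def test_everywhere_above_included(self):
        m, thr = self._serum({"pA": 410})
        assert detectable_in_serum(m, thr, min_subjects=50) == ["pA"]

    def test_monotone_in_min_subjects(self):
        m, thr = self._serum({"pA": 30, "pB": 100, "pC": 300})
        prev = None
        for ms in (10, 50, 150, 350):
            kept = set(detectable_in_serum(m, thr, min_subjects=ms))
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_min_subjects_must_be_below_cohort(self):
        m, thr = self._serum({"pA": 10}, n_samples=40)
        with pytest.raises(ParameterError):
            detectable_in_serum(m, thr, min_subjects=40)

    def test_generator_closure_20_of_34(self):
        """A serum simulation with detectable_fraction 20/34 on a 34-probe
        panel yields exactly 20 detectable probes under the serum rule."""
        from mirisk import (
            SimulationParams, compute_background_threshold,
            simulate_serum_cohort, simulate_tissue_cohort,
        )

        p = SimulationParams(
            n_probes=120, n_negative_controls=6, n_positive_controls=6,
            group_sizes={"control": 205, "case": 205}, n_informative=8,
            duplicate_fraction=0.0, seed=21,
        )
        tissue = simulate_tissue_cohort(p)
        panel = tissue.probes[tissue.probes["probe_class"] == "endogenous"].head(34)
        serum = simulate_serum_cohort(p, panel, detectable_fraction=20 / 34)
        thr = compute_background_threshold(serum.matrix, serum.probes,
                                           method="mean_plus_2sd")
        panel_ids = [f"afx-mir-{i:04d}" for i in range(34)]
        kept = detectable_in_serum(serum.matrix, thr, min_subjects=50,
                                   probes=panel_ids)
        assert len(kept) == 20


class TestSubsetAndRefit:
    def _data(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 12)),
                         columns=[f"f{i:02d}" for i in range(12)])
        y = np.array(["low"] * 18 + ["high"] * 12)
        X.iloc[18:, 2] += 2.5
        X.iloc[18:, 9] += 2.0
        return X, y

    def test_full_panel_refit_equals_original_fit(self):
        X, y = self._data()
        base = fit_splsda(X, y, ncomp=2, keepX=4)
        refit = subset_and_refit(X, y, list(X.columns), retune=False,
                                 keepX=4, ncomp=2)
        np.testing.assert_allclose(base.x_weights, refit.x_weights)

    def test_single_probe_panel_clamps_keepx(self):
        X, y = self._data()
        m = subset_and_refit(X, y, ["f02"], retune=False, keepX=10, ncomp=3)
        assert m.feature_names == ["f02"]
        assert all(k == 1 for k in m.keepX)

    def test_empty_panel_rejected(self):
        X, y = self._data()
        with pytest.raises(EmptyPanelError):
            subset_and_refit(X, y, [])

    def test_unknown_panel_probe_rejected(self):
        X, y = self._data()
        with pytest.raises(ParameterError):
            subset_and_refit(X, y, ["nope"], retune=False, keepX=1)


class TestQuartiles:
    def test_partition_near_equal(self):
        rng = np.random.default_rng(6)
        for n in (8, 101, 410):
            q = assign_quartiles(pd.Series(rng.normal(size=n)))
            sizes = q.value_counts()
            assert sizes.max() - sizes.min() <= 1
            assert sizes.sum() == n

    def test_cross_product_worked_example(self):
        """Q4 with 30 cases/20 controls vs Q1 with 20/30 -> OR 2.25."""
        n = 200
        scores = pd.Series(np.arange(n, dtype=float))
        outcome = np.array(["control"] * n)
        # quartiles are rank-blocks of 50; plant exact case counts per block
        for block, cases in zip(range(4), (20, 25, 25, 30)):
            idx = np.arange(block * 50, block * 50 + cases)
            outcome[idx] = "case"
        table = pd.DataFrame(
            {"score": scores, "quartile": assign_quartiles(scores),
             "outcome": outcome})
        ors = quartile_or(table)
        assert ors.loc[4, "odds_ratio"] == pytest.approx((30 * 30) / (20 * 20))
        assert ors.loc[1, "odds_ratio"] == 1.0

    def test_or_equals_indicator_logistic_fit(self):
        """Cross-product ORs equal exp(coefs) of the indicator-coded logistic
        regression (independent statsmodels route)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(size=400))
        prob = 1 / (1 + np.exp(-scores))
        outcome = np.where(rng.random(400) < prob, "case", "control")
        table = pd.DataFrame({"score": scores, "quartile": assign_quartiles(scores),
                              "outcome": outcome})
        ors = quartile_or(table)
        design = pd.get_dummies(table["quartile"], prefix="q", drop_first=True)
        fit = sm.Logit((table["outcome"] == "case").astype(float),
                       sm.add_constant(design.astype(float))).fit(disp=0)
        for q in (2, 3, 4):
            assert ors.loc[q, "odds_ratio"] == pytest.approx(
                np.exp(fit.params[f"q_{q}"]), rel=1e-6)

    def test_label_swap_inverts_or(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=120))
        outcome = rng.permutation(["case"] * 60 + ["control"] * 60)
        table = pd.DataFrame({"score": scores, "quartile": assign_quartiles(scores),
                              "outcome": outcome})
        a = quartile_or(table, positive_outcome="case")
        b = quartile_or(table, positive_outcome="control")
        for q in (2, 3, 4):
            assert a.loc[q, "odds_ratio"] == pytest.approx(
                1 / b.loc[q, "odds_ratio"])

    def test_null_scores_give_or_near_one(self):
        rng = np.random.default_rng(9)
        log_ors = []
        for _ in range(20):
            scores = pd.Series(rng.normal(size=400))
            outcome = rng.permutation(["case"] * 200 + ["control"] * 200)
            table = pd.DataFrame(
                {"score": scores, "quartile": assign_quartiles(scores),
                 "outcome": outcome})
            log_ors.append(np.log(quartile_or(table).loc[4, "odds_ratio"]))
        assert abs(np.mean(log_ors)) < 0.15

    def test_zero_cell_warns_and_unbounded_ci(self):
        scores = pd.Series(np.arange(40, dtype=float))
        outcome = np.array(["control"] * 40)
        outcome[:5] = "case"  # Q1 mixed; Q4 all controls
        table = pd.DataFrame({"score": scores, "quartile": assign_quartiles(scores),
                              "outcome": outcome})
        with pytest.warns(UserWarning, match="zero cell"):
            ors = quartile_or(table)
        assert ors.loc[4, "odds_ratio"] == 0.0
        assert np.isinf(ors.loc[4, "ci_high"])

    def test_q1_needs_both_outcomes(self):
        scores = pd.Series(np.arange(40, dtype=float))
        outcome = np.array(["case"] * 10 + ["control"] * 30)
        table = pd.DataFrame({"score": scores, "quartile": assign_quartiles(scores),
                              "outcome": outcome})
        with pytest.raises(ParameterError):
            quartile_or(table)
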