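import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rayleighsim as rs


def _table(rows):
    from rayleighsim.synthetic_data import STUDY_COLUMNS
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def _row(oid, label, inst, session, rep, lam, excluded=False):
    return (oid, label, inst, session, rep, lam, 1.0, False, excluded)


class TestSummarize:
    def test_hand_computed_mean_and_sd(self):
        t = _table([_row("A", "normal", "penn", 1, i + 1, v)
                    for i, v in enumerate([0.4, 0.5, 0.6])])
        s = rs.summarize_sessions(t)
        assert s.loc[0, "mean_lambda"] == pytest.approx(0.5)
        assert s.loc[0, "sd_lambda"] == pytest.approx(0.1)
        assert s.loc[0, "n"] == 3

    def test_duplicated_table_doubles_n(self):
        t = _table([_row("A", "normal", "penn", 1, i + 1, 0.5) for i in range(3)])
        s = rs.summarize_sessions(pd.concat([t, t], ignore_index=True))
        assert s.loc[0, "n"] == 6

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rs.summarize_sessions(_table([]))

    def test_excluded_observer_summarized_but_not_correlated(self):
        rows = []
        for oid, lam in [("A", 0.40), ("B", 0.50), ("C", 0.60), ("D", 0.45)]:
            for session in (1, 2):
                rows += [_row(oid, "normal", "penn", session, r + 1, lam)
                         for r in range(3)]
        rows += [_row("X", "protanomalous", "penn", s, r + 1, np.nan, excluded=True)
                 for s in (1, 2) for r in range(3)]
        summ = rs.summarize_sessions(_table(rows))
        assert set(summ["observer_id"]) == {"A", "B", "C", "D", "X"}
        rep = rs.reliability_report(summ, "penn", subset="all")
        assert rep.n_observers == 4


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = rs.correlation(x, 2 * x + 1, "pearson")
        assert r == pytest.approx(1.0)
        assert p < 0.001

    def test_hand_computed_pearson(self):
        r, _ = rs.correlation([1, 2, 3], [1, 3, 2], "pearson")
        assert r == pytest.approx(0.5)

    def test_spearman_is_rank_invariant(self):
        x = np.array([0.1, 0.5, 1.0, 2.0, 5.0])
        rho, _ = rs.correlation(x, np.exp(x), "spearman")
        assert rho == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            rs.correlation([1, 1, 1], [1, 2, 3], "pearson")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_pearson_invariant_to_positive_affine_maps(self, a, b):
        x = np.array([0.2, 0.9, 0.4, 1.7, 1.1])
        y = np.array([1.0, 2.2, 1.4, 3.1, 2.0])
        r0, _ = rs.correlation(x, y, "pearson")
        r1, _ = rs.correlation(a * x + b, y, "pearson")
        assert r1 == pytest.approx(r0, abs=1e-12)


@pytest.fixture(scope="module")
def reference(penn, normal_set, pre):
    return rs.make_classification_reference(penn, normal_set, pre)


class TestClassification:
    def test_reference_normal_observer_is_normal(self, reference):
        assert rs.classify_observer(reference.normal_lambda, reference) == "normal"

    def test_archetype_sides_are_opposite_and_consistent(self, reference, penn,
                                                         normal_set, pre):
        assert reference.protan_sign != reference.deutan_sign
        obs = rs.make_anomalous_observer(normal_set, "deuteranomalous", 400.0, pre)
        lam = rs.predict_match(penn, obs).lambda_star
        expected_side = np.sign(lam - reference.normal_lambda)
        assert rs.classify_observer(lam, reference) == (
            "protan-side" if expected_side == reference.protan_sign
            else "deutan-side")

    def test_boundary_mean_is_normal(self, reference):
        edge = reference.normal_lambda + reference.halfwidth
        assert rs.classify_observer(edge, reference) == "normal"

    def test_missing_mean_is_unclassifiable(self, reference):
        assert rs.classify_observer(float("nan"), reference) == "unclassifiable"


class TestReliabilityReport:
    def _noiseless_summaries(self, normal_set, pre, penn, extra_instruments=()):
        spec = rs.CohortSpec(setting_noise_sd=0.0, amber_noise_frac=0.0, seed=21)
        cohort = rs.sample_cohort(spec, normal_set, pre)
        insts = [penn, *extra_instruments]
        return rs.summarize_sessions(rs.simulate_study(cohort, insts, spec))

    def test_noiseless_simulation_has_unit_reliability(self, normal_set, pre, penn):
        summ = self._noiseless_summaries(normal_set, pre, penn)
        rep = rs.reliability_report(summ, "penn", subset="all")
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_report_is_deterministic(self, normal_set, pre, penn):
        s1 = self._noiseless_summaries(normal_set, pre, penn)
        s2 = self._noiseless_summaries(normal_set, pre, penn)
        r1 = rs.reliability_report(s1, "penn")
        r2 = rs.reliability_report(s2, "penn")
        assert (r1.pearson_r, r1.spearman_rho) == (r2.pearson_r, r2.spearman_rho)

    def test_insufficient_observers_rejected(self):
        rows = [_row(o, "normal", "penn", s, r + 1, v)
                for (o, v) in [("A", 0.4), ("B", 0.5)]
                for s in (1, 2) for r in range(3)]
        summ = rs.summarize_sessions(_table(rows))
        with pytest.raises(ValueError):
            rs.reliability_report(summ, "penn")


class TestCrossInstrument:
    def test_noiseless_cohort_has_no_contradictory_diagnoses(
            self, normal_set, pre, penn, oculus):
        spec = rs.CohortSpec(setting_noise_sd=0.0, amber_noise_frac=0.0, seed=31)
        cohort = rs.sample_cohort(spec, normal_set, pre)
        summ = rs.summarize_sessions(rs.simulate_study(cohort, [penn, oculus], spec))
        refs = [rs.make_classification_reference(i, normal_set, pre)
                for i in (penn, oculus)]
        rep = rs.cross_instrument_report(summ, "penn", "oculus", *refs)
        assert rep.contradictory_count == 0
        assert rep.agreement.to_numpy().sum() == rep.n_observers

    def test_identical_instrument_self_comparison_is_perfect(self, normal_set,
                                                             pre, penn):
        spec = rs.CohortSpec(n_normal=6, n_protan=1, n_deutan=1, seed=41)
        cohort = rs.sample_cohort(spec, normal_set, pre)
        table = rs.simulate_study(cohort, [penn], spec,
                                  plan=[(0, 1)])
        t2 = table.copy()
        t2["instrument"] = "penn-b"
        summ = rs.summarize_sessions(pd.concat([table, t2], ignore_index=True))
        rep = rs.cross_instrument_report(summ, "penn", "penn-b")
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_pearson_unchanged_by_scale_convention(self, normal_set, pre, penn):
        spec = rs.CohortSpec(n_normal=6, n_protan=1, n_deutan=1, seed=51)
        cohort = rs.sample_cohort(spec, normal_set, pre)
        table = rs.simulate_study(cohort, [penn], spec, plan=[(0, 1)])
        t2 = table.copy()
        t2["instrument"] = "scaled"
        t2["lambda"] = 73.0 * t2["lambda"]
        summ = rs.summarize_sessions(pd.concat([table, t2], ignore_index=True))
        rep = rs.cross_instrument_report(summ, "penn", "scaled")
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
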