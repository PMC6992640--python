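"""Subtype summaries, Tukey comparisons, correlation panels, quadrants, KM/log-rank."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from synergyscreen.errors import (
    DegenerateTestError,
    InsufficientDataError,
    ValidationError,
)
from synergyscreen.expression_outcomes import (
    ExpressionCohort,
    correlation_panel,
    km_estimate,
    logrank_test,
    median_split,
    median_split_quadrants,
    pairwise_logrank,
    quadrant_survival,
    subtype_summary,
    tukey_all_pairs,
)


def _cohort(values: dict, subtypes: list, clinical: pd.DataFrame | None = None):
    samples = [f"S{i}" for i in range(len(subtypes))]
    expr = pd.DataFrame(values, index=samples)
    return ExpressionCohort(
        expression=expr,
        subtype=pd.Series(subtypes, index=samples),
        clinical=clinical.set_index(pd.Index(samples)) if clinical is not None else None,
    )


class TestSubtypeSummary:
    def test_mean_and_range_per_subtype(self):
        cohort = _cohort({"G": [2.0, 4.0, 1.0, 1.0]}, ["Basal", "Basal", "LumA", "LumA"])
        out = subtype_summary(cohort, "G").set_index("subtype")
        assert out.loc["Basal"].tolist() == [3.0, 2.0, 4.0, 2]
        assert out.loc["LumA"].tolist() == [1.0, 1.0, 1.0, 2]

    def test_singleton_subtype_mean_equals_range(self):
        cohort = _cohort({"G": [5.0, 1.0]}, ["Basal", "LumA"])
        out = subtype_summary(cohort, "G").set_index("subtype")
        assert out.loc["Basal", "mean"] == out.loc["Basal", "min"] == out.loc["Basal", "max"]

    def test_unknown_gene_rejected(self):
        cohort = _cohort({"G": [1.0, 2.0]}, ["Basal", "LumA"])
        with pytest.raises(ValidationError):
            subtype_summary(cohort, "MISSING")

    def test_planted_basal_shift_recovered(self, rng):
        n = 60
        subtypes = ["Basal"] * n + ["LumA"] * n
        vals = np.concatenate([rng.normal(4.0, 1.0, n), rng.normal(2.0, 1.0, n)])
        cohort = _cohort({"G": vals}, subtypes)
        out = subtype_summary(cohort, "G").set_index("subtype")
        shift = out.loc["Basal", "mean"] - out.loc["LumA", "mean"]
        se = np.sqrt(2.0 / n)  # both groups sd ~1
        assert abs(shift - 2.0) < 3 * se


class TestTukey:
    def test_identical_groups_all_p_near_1(self, rng):
        base = rng.normal(0, 1, 30)
        out = tukey_all_pairs({"a": base, "b": base.copy(), "c": base.copy()})
        assert (out["p_adj"] > 0.95).all()

    def test_two_groups_match_studentized_range_oracle(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(0.8, 1, 25)
        out = tukey_all_pairs({"a": a, "b": b})
        # closed-form two-group Tukey: q = |diff| / sqrt(MSW/n), p from studentized range
        msw = (a.var(ddof=1) * 24 + b.var(ddof=1) * 24) / 48
        q = abs(a.mean() - b.mean()) / np.sqrt(msw / 25)
        p_oracle = stats.studentized_range.sf(q, k=2, df=48)
        assert float(out["p_adj"].iloc[0]) == pytest.approx(float(p_oracle), abs=1e-8)

    def test_planted_shift_dominates_smallest_pvalues(self, rng):
        groups = {f"g{i}": rng.normal(0, 1, 40) for i in range(5)}
        groups["shifted"] = rng.normal(2.5, 1, 40)
        out = tukey_all_pairs(groups)
        out = out.sort_values("p_adj")
        top5 = out.head(5)
        assert ((top5["group1"] == "shifted") | (top5["group2"] == "shifted")).all()

    def test_degenerate_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            tukey_all_pairs({"a": [1.0, 2.0], "b": [3.0]})


class TestCorrelationPanel:
    def test_exact_positive_and_negative(self):
        g = np.linspace(1, 10, 12)
        clinical = pd.DataFrame({"double": 2 * g, "neg": -g})
        cohort = _cohort({"G": g}, ["Basal"] * 12, clinical)
        panel = correlation_panel(cohort, ["G"], ["double", "neg"])
        assert panel.loc["G", "double"] == pytest.approx(1.0)
        assert panel.loc["G", "neg"] == pytest.approx(-1.0)

    def test_matches_numpy_corrcoef_oracle(self, rng):
        n = 855
        data = {f"g{i}": rng.normal(size=n) for i in range(3)}
        covs = pd.DataFrame({f"c{i}": rng.normal(size=n) for i in range(3)})
        cohort = _cohort(data, ["Basal"] * n, covs)
        panel = correlation_panel(cohort, list(data), list(covs.columns))
        full = pd.concat([pd.DataFrame(data, index=cohort.samples),
                          covs.set_index(cohort.samples)], axis=1)
        oracle = np.corrcoef(full.to_numpy().T)
        np.testing.assert_allclose(panel.to_numpy(), oracle, atol=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        cohort = _cohort({"a": rng.normal(size=20), "b": rng.normal(size=20)}, ["Basal"] * 20)
        panel = correlation_panel(cohort, ["a", "b"])
        np.testing.assert_allclose(panel.to_numpy(), panel.to_numpy().T)
        np.testing.assert_allclose(np.diag(panel.to_numpy()), 1.0)

    def test_constant_covariate_cell_undefined(self):
        clinical = pd.DataFrame({"const": [1.0] * 6})
        cohort = _cohort({"G": [1.0, 2, 3, 4, 5, 6]}, ["Basal"] * 6, clinical)
        panel = correlation_panel(cohort, ["G"], ["const"])
        assert np.isnan(panel.loc["G", "const"])


class TestMedianSplit:
    def test_anti_ranked_genes_give_hl_lh_only(self):
        cohort = _cohort(
            {"g1": [1.0, 2, 3, 4, 5, 6], "g2": [6.0, 5, 4, 3, 2, 1]}, ["Basal"] * 6
        )
        q = median_split_quadrants(cohort, "g1", "g2")
        counts = q.value_counts().to_dict()
        assert counts == {"hl": 3, "lh": 3}

    def test_identical_genes_give_hh_ll_only(self):
        cohort = _cohort({"g1": [1.0, 2, 3, 4], "g2": [1.0, 2, 3, 4]}, ["Basal"] * 4)
        q = median_split_quadrants(cohort, "g1", "g2")
        counts = q.value_counts().to_dict()
        assert counts == {"hh": 2, "ll": 2}

    def test_median_ties_resolve_to_low_group(self):
        s = median_split(pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd")))
        assert (s == "high").sum() == 2
        # the two tied middle samples: exactly one can be high (deterministic by label)
        assert s["a"] == "low" and s["d"] == "high"
        # repeatable
        s2 = median_split(pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd")))
        assert (s == s2).all()

    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=4, max_size=40)
        .filter(lambda v: len(v) % 2 == 0),
        st.lists(st.floats(min_value=0, max_value=100), min_size=4, max_size=40)
        .filter(lambda v: len(v) % 2 == 0),
    )
    def test_even_n_quadrant_symmetry(self, g1, g2):
        n = min(len(g1), len(g2))
        n -= n % 2
        cohort = _cohort({"g1": g1[:n], "g2": g2[:n]}, ["Basal"] * n)
        q = median_split_quadrants(cohort, "g1", "g2")
        counts = q.value_counts().reindex(["hh", "hl", "lh", "ll"], fill_value=0)
        assert counts["hh"] == counts["ll"]
        assert counts["hl"] == counts["lh"]

    def test_too_few_samples_rejected(self):
        cohort = _cohort({"g1": [1.0, 2], "g2": [1.0, 2]}, ["Basal"] * 2)
        with pytest.raises(InsufficientDataError):
            median_split_quadrants(cohort, "g1", "g2")


class TestKaplanMeier:
    def test_no_events_flat_at_1(self):
        km = km_estimate([5.0, 8.0, 12.0], [False, False, False])
        assert (km["survival"] == 1.0).all()

    def test_two_subject_closed_form(self):
        km = km_estimate([1.0, 2.0], [True, True]).set_index("time")
        assert km.loc[0.0, "survival"] == 1.0
        assert km.loc[1.0, "survival"] == pytest.approx(0.5)
        assert km.loc[2.0, "survival"] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10.0, 100)
        km = km_estimate(t, [True] * 100)
        for time, surv in zip(km["time"], km["survival"]):
            assert surv == pytest.approx(np.mean(t > time), abs=1e-12)

    def test_monotone_right_continuous_from_1(self, rng):
        t = rng.exponential(10.0, 50)
        e = rng.random(50) < 0.7
        km = km_estimate(t, e)
        assert km["survival"].iloc[0] == 1.0
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1.0], [True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        chi2, df, p = logrank_test({"a": (t, e), "b": (t, e)})
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1 and p == pytest.approx(1.0, abs=1e-10)

    def test_small_table_matches_hand_oracle(self):
        # worked two-group table, all events, no ties
        ta, tb = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        chi2, df, p = logrank_test({"a": (ta, [True] * 3), "b": (tb, [True] * 3)})
        # independent hand computation of observed-vs-expected for group a
        times = sorted(ta + tb)
        at_risk_a, at_risk_b = 3, 3
        O = E = V = 0.0
        for t in times:
            n = at_risk_a + at_risk_b
            d = 1
            in_a = t in ta
            O += 1.0 if in_a else 0.0
            E += d * at_risk_a / n
            if n > 1:
                V += d * (at_risk_a / n) * (1 - at_risk_a / n) * (n - d) / (n - 1)
            if in_a:
                at_risk_a -= 1
            else:
                at_risk_b -= 1
        oracle = (O - E) ** 2 / V
        assert chi2 == pytest.approx(oracle, abs=1e-8)
        assert df == 1

    def test_relabeling_invariant(self, rng):
        g1 = (rng.exponential(10, 30), rng.random(30) < 0.8)
        g2 = (rng.exponential(20, 30), rng.random(30) < 0.8)
        a = logrank_test({"x": g1, "y": g2})
        b = logrank_test({"y": g1, "x": g2})
        assert a[0] == pytest.approx(b[0], abs=1e-12)

    def test_zero_events_rejected(self):
        with pytest.raises(DegenerateTestError):
            logrank_test({"a": ([1.0], [False]), "b": ([2.0], [False])})

    def test_four_group_df(self, rng):
        groups = {
            q: (rng.exponential(10, 20), [True] * 20) for q in ("hh", "hl", "lh", "ll")
        }
        _, df, _ = logrank_test(groups)
        assert df == 3

    def test_pairwise_covers_all_pairs_with_optional_holm(self, rng):
        groups = {
            q: (rng.exponential(10, 15), [True] * 15) for q in ("hh", "hl", "lh", "ll")
        }
        out = pairwise_logrank(groups, adjust="holm")
        assert len(out) == 6
        assert (out["p_holm"] >= out["p_value"] - 1e-12).all()


class TestQuadrantSurvival:
    def test_groups_by_quadrant_and_endpoint(self):
        quadrants = pd.Series(
            ["hh", "hh", "ll", "ll"], index=[f"S{i}" for i in range(4)]
        )
        survival = pd.DataFrame(
            {
                "sample": [f"S{i}" for i in range(4)] * 2,
                "endpoint": ["MFS"] * 4 + ["lung"] * 4,
                "time_months": [1.0, 2, 3, 4, 5, 6, 7, 8],
                "event": [1, 0, 1, 0] * 2,
            }
        )
        groups = quadrant_survival(quadrants, survival, "MFS")
        assert set(groups) == {"hh", "ll"}
        np.testing.assert_array_equal(groups["hh"][0], [1.0, 2.0])

    def test_unknown_endpoint_rejected(self):
        quadrants = pd.Series(["hh"], index=["S0"])
        survival = pd.DataFrame(
            {"sample": ["S0"], "endpoint": ["MFS"], "time_months": [1.0], "event": [1]}
        )
        with pytest.raises(ValidationError):
            quadrant_survival(quadrants, survival, "bone")
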