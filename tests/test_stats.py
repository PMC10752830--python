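"""Statistics layer: ANOVA oracle, ROC/AUC identities, cut-off selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungmorph import (
    AirspaceDiagnostics,
    CaseSummary,
    auc,
    choose_cutoff,
    compare_groups,
    diagnostic_report,
    roc_curve,
    sample_parameter_cohort,
)
from lungmorph.reference import GROUP_REFERENCE_STATS


def anova_oracle(groups):
    """Brute-force one-way ANOVA F from sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ssb / df_b) / (ssw / df_w)


class TestCompareGroups:
    def test_f_statistic_matches_sums_of_squares_oracle(self):
        groups = {
            "a": np.array([1.0, 2.0, 3.0]),
            "b": np.array([2.0, 3.0, 4.0]),
            "c": np.array([10.0, 11.0, 12.0]),
        }
        comp = compare_groups(groups, reference_group="a")
        assert comp.anova_f == pytest.approx(
            anova_oracle(list(groups.values())), rel=1e-12
        )
        assert comp.anova_p < 0.001

    def test_constant_groups_are_degenerate(self):
        groups = {g: np.full(4, 3.0) for g in ("a", "b", "c")}
        comp = compare_groups(groups, reference_group="a")
        assert comp.degenerate
        assert math.isnan(comp.anova_f)
        assert all(c.flag == "ns" for c in comp.posthoc)

    def test_bonferroni_adjustment_identity(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0.5, 1, 8),
            "c": rng.normal(3.0, 1, 8),
        }
        comp = compare_groups(groups, reference_group="a")
        m = len(comp.posthoc)
        assert m == 2
        for c in comp.posthoc:
            assert c.p_adjusted == pytest.approx(min(1.0, m * c.p_raw), rel=1e-12)
            assert c.p_adjusted >= c.p_raw

    def test_all_pairs_scope(self):
        rng = np.random.default_rng(6)
        groups = {g: rng.normal(i, 1, 6) for i, g in enumerate("abc")}
        comp = compare_groups(groups, reference_group="a", all_pairs=True)
        assert len(comp.posthoc) == 3
        for c in comp.posthoc:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw), rel=1e-12)

    def test_flags_track_thresholds(self):
        rng = np.random.default_rng(11)
        groups = {
            "ref": rng.normal(0, 1, 10),
            "far": rng.normal(8, 1, 10),
        }
        comp = compare_groups(groups, reference_group="ref")
        assert comp.posthoc[0].flag == "**"

    @pytest.mark.parametrize(
        "groups,ref",
        [
            ({"a": [1.0, 2.0]}, "a"),
            ({"a": [1.0], "b": [1.0, 2.0]}, "a"),
            ({"a": [1.0, 2.0], "b": [1.0, 2.0]}, "missing"),
        ],
    )
    def test_invalid_inputs_rejected(self, groups, ref):
        with pytest.raises(ValueError):
            compare_groups({k: np.asarray(v) for k, v in groups.items()}, ref)

    def test_simulated_cohort_flags_barotrauma_pas_difference(self):
        """At the reported PAS group parameters, n=6/6/6 cohorts flag the
        barotrauma-vs-drowning contrast at p<0.01 in most replicates."""
        stats = GROUP_REFERENCE_STATS["mean_pas_percent"]
        hits = 0
        reps = 200
        for rep in range(reps):
            values = sample_parameter_cohort(stats, n_per_group=6, seed=9000 + rep)
            comp = compare_groups(values, reference_group="drowning")
            flag = next(c for c in comp.posthoc if c.group == "pbt").flag
            hits += flag == "**"
        assert hits > reps / 2


class TestRocCurve:
    def test_separated_singletons(self):
        curve = roc_curve([1.0], [0.0])
        j = curve.youden()
        best = j.argmax()
        assert curve.sensitivity[best] == 1.0 and curve.specificity[best] == 1.0

    def test_identical_singletons_best_point(self):
        curve = roc_curve([1.0], [1.0])
        assert (curve.sensitivity + curve.specificity).max() == pytest.approx(1.0)

    def test_enumerated_point(self):
        curve = roc_curve([3, 4, 5], [1, 2, 3])
        i = np.flatnonzero(curve.thresholds == 2.5)[0]
        assert curve.sensitivity[i] == pytest.approx(1.0)
        assert curve.specificity[i] == pytest.approx(2 / 3)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([], [1.0])


class TestAuc:
    def test_perfect_separation(self):
        value, p = auc([10, 11, 12], [1, 2, 3])
        assert value == 1.0
        assert p < 0.2  # tiny n: exact rank-sum p bounded below by 2/C(6,3)

    def test_tie_counted_half(self):
        value, _ = auc([3, 4, 5], [1, 2, 3])
        assert value == pytest.approx(8.5 / 9, rel=1e-12)

    def test_null_distribution_auc_near_half(self):
        rng = np.random.default_rng(33)
        value, p = auc(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(value - 0.5) < 0.05
        assert p > 0.001

    def test_pair_counting_equals_trapezoid(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n1, n0 = rng.integers(1, 31, size=2)
            cases = np.round(rng.normal(0.5, 1, n1), 1)  # rounding forces ties
            controls = np.round(rng.normal(0, 1, n0), 1)
            value, _ = auc(cases, controls)
            assert value == pytest.approx(
                roc_curve(cases, controls).trapezoidal_auc(), abs=1e-12
            )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(st.integers(-500, 500), min_size=2, max_size=12),
        st.lists(st.integers(-500, 500), min_size=2, max_size=12),
        st.integers(1, 5),
        st.integers(-5, 5),
    )
    def test_monotone_transform_invariance(self, cases, controls, scale, shift):
        """AUC depends only on ranks: affine and exp transforms preserve it
        (integer-valued markers keep the tie structure exact under both)."""
        cases = np.asarray(cases, dtype=float)
        controls = np.asarray(controls, dtype=float)
        base, _ = auc(cases, controls)
        affine, _ = auc(scale * cases + shift, scale * controls + shift)
        assert affine == pytest.approx(base, abs=1e-12)
        expd, _ = auc(np.exp(cases / 500), np.exp(controls / 500))
        assert expd == pytest.approx(base, abs=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(st.integers(-500, 500), min_size=1, max_size=10),
        st.lists(st.integers(-500, 500), min_size=1, max_size=10),
    )
    def test_swapping_arms_reflects_auc(self, cases, controls):
        a, _ = auc(cases, controls)
        b, _ = auc(controls, cases)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestChooseCutoff:
    def test_tie_break_prefers_sensitivity_then_lower_cutoff(self):
        cutoff, sens, spec = choose_cutoff(roc_curve([3, 4, 5], [1, 2, 3]))
        assert cutoff == pytest.approx(2.5)
        assert sens == pytest.approx(1.0)
        assert spec == pytest.approx(2 / 3)

    def test_perfect_separation_midpoint(self):
        cutoff, sens, spec = choose_cutoff(roc_curve([10, 11], [1, 2]))
        assert cutoff == pytest.approx(6.0)
        assert sens == 1.0 and spec == 1.0

    def test_confusion_matrix_consistency(self):
        rng = np.random.default_rng(3)
        cases = rng.normal(2, 1, 25)
        controls = rng.normal(0, 1, 40)
        cutoff, sens, spec = choose_cutoff(roc_curve(cases, controls))
        assert sens == pytest.approx((cases > cutoff).mean())
        assert spec == pytest.approx((controls <= cutoff).mean())

    def test_simulated_aas_cutoff_between_group_means(self):
        """Large simulation from the reported AAS parameters: the selected
        cut-off separates the drowning mean from the barotrauma mean."""
        stats = GROUP_REFERENCE_STATS["mean_aas_um2"]
        values = sample_parameter_cohort(stats, n_per_group=10_000, seed=77)
        controls = np.concatenate([values["drowning"], values["control"]])
        cutoff, _, _ = choose_cutoff(roc_curve(values["pbt"], controls))
        assert stats["drowning"][0] < cutoff < stats["pbt"][0]


def _case(case_id, group, **values):
    defaults = dict(
        n_fields=24,
        total_cas=1500,
        mean_cas_per_field=62.5,
        mean_aas_um2=500_000.0,
        mean_ratio_aas_cas_um2=8000.0,
        mean_pas_percent=40.0,
        mean_max_das_um=90.0,
        mean_min_das_um=50.0,
    )
    defaults.update(values)
    return CaseSummary(case_id=case_id, group=group, **defaults)


class TestDiagnosticModel:
    def _separated_cohort(self):
        cases = []
        for i in range(4):
            cases.append(
                _case(
                    f"p{i}",
                    "pbt",
                    mean_aas_um2=900_000.0 + i,
                    mean_ratio_aas_cas_um2=20_000.0 + i,
                    mean_pas_percent=65.0 + i,
                    mean_max_das_um=140.0 + i,
                    mean_min_das_um=75.0 + i,
                )
            )
            cases.append(_case(f"d{i}", "drowning", mean_pas_percent=38.0 + i))
            cases.append(_case(f"c{i}", "control", mean_pas_percent=41.0 + i))
        return cases

    def test_strict_separation_gives_perfect_roc(self):
        report = diagnostic_report(self._separated_cohort())
        for param in ("mean_aas_um2", "mean_pas_percent"):
            r = report.roc_results[param]
            assert r.auc == 1.0
            assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_single_control_group_pooling_note(self):
        cases = [c for c in self._separated_cohort() if c.group != "control"]
        report = diagnostic_report(cases)
        assert report.pooling_note
        assert report.roc_results["mean_pas_percent"].n_controls == 4

    def test_missing_positive_group_rejected(self):
        cases = [c for c in self._separated_cohort() if c.group != "pbt"]
        with pytest.raises(ValueError):
            diagnostic_report(cases)

    def test_summary_and_tables_shape(self):
        report = diagnostic_report(self._separated_cohort())
        table = report.table_roc()
        assert len(table) == 5
        assert set(table.columns) >= {"auc", "cutoff", "sensitivity_percent"}
        text = report.summary()
        assert "Mean PAS (%)" in text and "ROC" in text
        payload = report.to_dict()
        assert set(payload["parameters"]) == set(report.roc_results)

    def test_report_sensitivity_specificity_recomputable(self):
        report = diagnostic_report(self._separated_cohort())
        model = report.model
        for param, r in report.roc_results.items():
            values = model.data.loc[model.data.group == "pbt", param].to_numpy()
            others = model.data.loc[model.data.group != "pbt", param].to_numpy()
            assert r.sensitivity == pytest.approx((values > r.cutoff).mean())
            assert r.specificity == pytest.approx((others <= r.cutoff).mean())
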