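import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tlcausal as tl
from tlcausal.diagnostics import DoseGroupSpec, assign_dose_groups

# Published age-by-arm counts used as a worked positivity example:
# two sparse age bands have zero treated subjects, and coarser bands
# restore in-sample positivity.
AGE_LABELS = ["16-20", "21-25", "26-30", "31-35", "36-40", "41-45", "46-50"]
AGE_CONTROL = [2, 9, 37, 50, 38, 4, 3]
AGE_TREATED = [0, 7, 26, 29, 19, 1, 0]
AGE_MERGE = {
    "16-20": "16-30", "21-25": "16-30", "26-30": "16-30",
    "31-35": "31-35",
    "36-40": "36-50", "41-45": "36-50", "46-50": "36-50",
}


def _age_table():
    return tl.StratumTable(AGE_LABELS, AGE_CONTROL, AGE_TREATED)


class TestPositivityTable:
    def test_reconstructed_age_table_flags_sparse_bands(self):
        # expand the counts into a subject-level fixture and re-tabulate
        values, a = [], []
        for label, c, t in zip(AGE_LABELS, AGE_CONTROL, AGE_TREATED):
            values += [label] * (c + t)
            a += [0] * c + [1] * t
        table = tl.positivity_table(values, np.array(a), labels=AGE_LABELS)
        np.testing.assert_array_equal(table.control, AGE_CONTROL)
        np.testing.assert_array_equal(table.treated, AGE_TREATED)
        assert table.empty_cell_flags()["zero_treated"] == ["16-20", "46-50"]
        assert table.total == 225

    def test_single_category_no_flag_when_both_arms(self):
        table = tl.positivity_table(["x", "x", "x"], np.array([0, 1, 1]))
        assert not table.has_empty_cells

    def test_all_treated_flags_every_category(self):
        table = tl.positivity_table(["p", "q", "p"], np.array([1, 1, 1]))
        assert table.empty_cell_flags()["zero_control"] == ["p", "q"]


class TestCollapseCategories:
    def test_published_merges_reproduce_coarse_counts(self):
        merged = tl.collapse_categories(_age_table(), AGE_MERGE)
        df = merged.to_dataframe().set_index("category")
        assert (df.loc["16-30", "control"], df.loc["16-30", "treated"]) == (48, 33)
        assert (df.loc["36-50", "control"], df.loc["36-50", "treated"]) == (45, 20)
        assert merged.total == 225
        assert not merged.has_empty_cells

    def test_identity_mapping_unchanged(self):
        table = _age_table()
        same = tl.collapse_categories(table, {l: l for l in AGE_LABELS})
        np.testing.assert_array_equal(same.control, table.control)
        np.testing.assert_array_equal(same.treated, table.treated)

    def test_non_contiguous_merge_rejected(self):
        mapping = {l: l for l in AGE_LABELS}
        mapping["16-20"] = "ends"
        mapping["46-50"] = "ends"
        with pytest.raises(ValueError, match="non-contiguous"):
            tl.collapse_categories(_age_table(), mapping)

    @given(split=st.integers(1, 6))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_totals_preserved_under_any_contiguous_collapse(self, split):
        mapping = {
            l: ("lo" if i < split else "hi") for i, l in enumerate(AGE_LABELS)
        }
        merged = tl.collapse_categories(_age_table(), mapping)
        assert merged.total == 225
        assert merged.control.sum() == sum(AGE_CONTROL)
        assert merged.treated.sum() == sum(AGE_TREATED)


class TestPsCstat:
    def test_perfect_separation(self):
        a = np.array([0, 1, 0, 1])
        assert tl.ps_cstat(a.astype(float), a) == 1.0

    def test_constant_score_is_half(self):
        assert tl.ps_cstat(np.full(6, 0.3), np.array([0, 0, 0, 1, 1, 1])) == 0.5

    def test_enumerated_pairs(self):
        # pairs (t, c): (0.4,0.2)+, (0.4,0.6)-, (0.9,0.2)+, (0.9,0.6)+ -> 3/4
        g = np.array([0.2, 0.4, 0.6, 0.9])
        a = np.array([0, 1, 0, 1])
        assert tl.ps_cstat(g, a) == 0.75

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError):
            tl.ps_cstat(np.array([0.2, 0.4]), np.array([1, 1]))

    @given(seed=st.integers(0, 50), shift=st.floats(0.1, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_increasing_transforms(self, seed, shift):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0.05, 0.95, 40)
        a = rng.binomial(1, 0.5, 40)
        if a.sum() in (0, 40):
            a[0] = 1 - a[0]
        base = tl.ps_cstat(g, a)
        assert tl.ps_cstat(np.log(g) * shift, a) == pytest.approx(base, abs=1e-12)
        assert tl.ps_cstat(g**3, a) == pytest.approx(base, abs=1e-12)


class TestPsOverlap:
    def test_identical_arms_identical_histograms(self):
        g = np.tile(np.linspace(0.1, 0.9, 20), 2)
        a = np.repeat([0, 1], 20)
        out = tl.ps_overlap_summary(g, a, bins=8)
        assert out["treated_proportions"] == out["control_proportions"]
        assert out["overlap_mass"] == pytest.approx(1.0)

    def test_disjoint_supports_zero_overlap(self):
        g = np.concatenate([np.linspace(0.05, 0.2, 10), np.linspace(0.7, 0.9, 10)])
        a = np.repeat([0, 1], 10)
        out = tl.ps_overlap_summary(g, a, bins=10)
        assert out["overlap_mass"] == 0.0

    def test_truncation_no_impact_flag(self):
        g = np.array([0.1, 0.3, 0.5, 0.7])
        a = np.array([0, 1, 0, 1])
        out = tl.ps_overlap_summary(g, a, bound=0.06)
        assert out["truncation_no_impact"] is True
        out2 = tl.ps_overlap_summary(np.array([0.05, 0.3, 0.5, 0.7]), a, bound=0.06)
        assert out2["truncation_no_impact"] is False


class TestDoseGroups:
    def test_direct_binning(self):
        dose = np.array([0.0, 5.0, 15.0, 55.0])
        y = np.array([0, 1, 0, 1])
        table = tl.crude_dose_proportions(dose, y)
        by_group = table.set_index("group")
        assert by_group.loc[[0, 1, 2, 6], "n"].tolist() == [1, 1, 1, 1]
        assert by_group.loc[[0, 1, 2, 6], "proportion"].tolist() == [0, 1, 0, 1]

    def test_half_open_boundaries(self):
        assert assign_dose_groups(np.array([10.0]))[0] == 1
        assert assign_dose_groups(np.array([10.5]))[0] == 2
        assert assign_dose_groups(np.array([50.0]))[0] == 5
        assert assign_dose_groups(np.array([50.001]))[0] == 6

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        dose = np.concatenate([[0.0], rng.uniform(0, 100, 500)])
        groups = assign_dose_groups(dose)
        assert groups.min() >= 0 and groups.max() <= 6
        assert np.all((groups == 0) == (dose == 0.0))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            assign_dose_groups(np.array([-1.0]))

    def test_non_monotonic_flag(self):
        dose = np.array([0.0] * 10 + [5.0] * 10 + [15.0] * 10)
        y = np.array([0] * 9 + [1] + [0] * 8 + [1] * 2 + [0] * 9 + [1] * 1 + [0] * 0)
        table = tl.crude_dose_proportions(dose, y[: len(dose)])
        # proportions 0.1, 0.2, 0.1 -> rises then falls
        assert table.attrs["non_monotonic"]


class TestBaselineLogisticOr:
    def _dose_cohort(self, log_or, n, seed=0):
        from scipy.special import expit

        rng = np.random.default_rng(seed)
        a = rng.binomial(1, 0.6, n)
        dose = np.where(a == 1, rng.uniform(1, 60, n), 0.0)
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(-2 + log_or * dose + 0.3 * x))
        return tl.Cohort(y=y, a=a, w=pd.DataFrame({"x": x}), dose=dose)

    def test_null_dose_effect_covered(self):
        cohort = self._dose_cohort(0.0, 8000, 1)
        or_hat, (lo, hi) = tl.baseline_logistic_or(cohort)
        assert lo <= 1.0 <= hi

    def test_recovers_simulated_log_or(self):
        cohort = self._dose_cohort(0.02, 10_000, 2)
        or_hat, (lo, hi) = tl.baseline_logistic_or(cohort)
        assert lo <= np.exp(0.02) <= hi
        assert or_hat == pytest.approx(np.exp(0.02), abs=0.01)

    def test_missing_dose_rejected(self, discrete_toy):
        with pytest.raises(ValueError, match="dose"):
            tl.baseline_logistic_or(discrete_toy)


def test_positivity_flags_at_least_as_strict_as_gcomp():
    """Any stratum that makes gcomp_oracle fail is flagged by the table."""
    y = np.array([0, 1, 0, 1, 1, 0])
    a = np.array([0, 0, 1, 1, 0, 0])
    w = pd.DataFrame({"grp": [0, 0, 0, 0, 1, 1]})
    cohort = tl.Cohort(y=y, a=a, w=w)
    table = tl.positivity_table(w.grp.to_numpy(), a)
    flagged = set(table.empty_cell_flags()["zero_treated"])
    with pytest.raises(tl.PositivityError) as err:
        tl.gcomp_oracle(cohort)
    assert any(str(f) in str(err.value) for f in flagged)
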