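import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clampkit.errors import ValidationError
from clampkit.simulate import simulate_cohort
from clampkit.stats import (
    anova_2way_summary,
    outcome_summary,
    rm_anova_3way,
    tukey_posthoc,
    validate_cohort_table,
)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort((9, 8), seed=3)["table"]


class TestEngineCrossChecks:
    def test_reduced_design_matches_pingouin(self, cohort):
        """The hand-rolled split-plot engine reproduces pingouin.mixed_anova
        exactly on the one-within-factor design."""
        mine = rm_anova_3way(cohort, "rdt_per_insulin", within=("intervention",)).set_index("factor")
        ref = anova_2way_summary(cohort, "rdt_per_insulin").set_index("factor")
        for factor in ("group", "intervention", "group * intervention"):
            assert mine.loc[factor, "F"] == pytest.approx(ref.loc[factor, "F"], rel=1e-9)
            assert mine.loc[factor, "p"] == pytest.approx(ref.loc[factor, "p"], rel=1e-9)

    def test_group_effect_equals_t_squared(self, cohort):
        """With two groups the between-subject F is the squared independent t
        on subject means."""
        eff = rm_anova_3way(cohort, "rdt").set_index("factor")
        per = (
            cohort[cohort["outcome"] == "rdt"]
            .groupby(["subject_id", "group"], as_index=False)["value"].mean()
        )
        t, p = sps.ttest_ind(
            per.loc[per.group == "OMNI", "value"], per.loc[per.group == "VEG", "value"]
        )
        assert eff.loc["group", "F"] == pytest.approx(t**2, rel=1e-9)
        assert eff.loc["group", "p"] == pytest.approx(p, rel=1e-9)


class TestInvariances:
    def test_group_label_swap(self, cohort):
        swapped = cohort.copy()
        swapped["group"] = swapped["group"].map({"OMNI": "VEG", "VEG": "OMNI"})
        a = rm_anova_3way(cohort, "rdt")[["factor", "F", "p"]]
        b = rm_anova_3way(swapped, "rdt")[["factor", "F", "p"]]
        pd.testing.assert_frame_equal(a, b)

    def test_subject_relabelling(self, cohort):
        relabeled = cohort.copy()
        mapping = {s: f"X{i}" for i, s in enumerate(sorted(cohort["subject_id"].unique()))}
        relabeled["subject_id"] = relabeled["subject_id"].map(mapping)
        a = rm_anova_3way(cohort, "rdt").set_index("factor")["F"]
        b = rm_anova_3way(relabeled, "rdt").set_index("factor")["F"]
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_within_level_reordering(self, cohort):
        shuffled = cohort.sample(frac=1.0, random_state=0)
        a = rm_anova_3way(cohort, "rdt").set_index("factor")["F"]
        b = rm_anova_3way(shuffled, "rdt").set_index("factor")["F"]
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_gg_epsilon_bounds(self, cohort):
        eff = rm_anova_3way(cohort, "rdt").set_index("factor")
        eps_b = eff.loc["within_level", "eps_gg"]
        assert 0.5 <= eps_b <= 1.0  # 3 levels: floor 1/(b-1) = 0.5
        assert eff.loc["intervention", "eps_gg"] == 1.0  # 2 levels: no correction


class TestValidationAndMissing:
    def test_single_group_rejected(self, cohort):
        one = cohort[cohort["group"] == "OMNI"]
        with pytest.raises(ValidationError):
            anova_2way_summary(one, "rdt_per_insulin")

    def test_unknown_outcome(self, cohort):
        with pytest.raises(ValidationError):
            rm_anova_3way(cohort, "nope")

    def test_subject_in_two_groups_rejected(self, cohort):
        bad = cohort.copy()
        first = bad["subject_id"].iloc[0]
        bad.loc[bad["subject_id"] == first, "group"] = np.where(
            np.arange((bad["subject_id"] == first).sum()) % 2, "OMNI", "VEG"
        )
        with pytest.raises(ValidationError):
            validate_cohort_table(bad)

    def test_listwise_exclusion_warns(self, cohort):
        incomplete = cohort.copy()
        victim = incomplete["subject_id"].iloc[0]
        drop = (
            (incomplete["subject_id"] == victim)
            & (incomplete["outcome"] == "rdt")
            & (incomplete["within_level"] == "step2")
            & (incomplete["intervention"] == "post")
        )
        incomplete = incomplete[~drop]
        with pytest.warns(UserWarning, match="incomplete"):
            eff = rm_anova_3way(incomplete, "rdt")
        full = rm_anova_3way(cohort[cohort["subject_id"] != victim], "rdt")
        assert np.allclose(eff["F"].to_numpy(), full["F"].to_numpy())


class TestTukey:
    def test_two_groups_equals_t_test(self, cohort):
        tk = tukey_posthoc(cohort, "rdt_per_insulin", "group")
        per = (
            cohort[cohort["outcome"] == "rdt_per_insulin"]
            .groupby(["subject_id", "group"], as_index=False)["value"].mean()
        )
        _, p = sps.ttest_ind(
            per.loc[per.group == "OMNI", "value"], per.loc[per.group == "VEG", "value"]
        )
        assert float(tk["p-adj"].iloc[0]) == pytest.approx(p, abs=1e-4)

    def test_adjusted_not_below_unadjusted(self):
        rng = np.random.default_rng(5)
        rows = []
        for g in ("a", "b", "c"):
            for i in range(10):
                rows.append({"subject_id": f"{g}{i}", "group": g, "intervention": "pre",
                             "within_level": "x", "outcome": "y",
                             "value": rng.normal(0 if g != "c" else 0.8)})
        tab = pd.DataFrame(rows)
        tk = tukey_posthoc(tab, "y", "group")
        per = tab.groupby(["subject_id", "group"], as_index=False)["value"].mean()
        for _, row in tk.iterrows():
            a = per.loc[per.group == row["group1"], "value"]
            b = per.loc[per.group == row["group2"], "value"]
            _, p_unadj = sps.ttest_ind(a, b)
            assert row["p-adj"] >= p_unadj - 1e-9

    def test_null_familywise_error(self):
        """Tukey HSD controls the familywise error near the nominal level."""
        rng = np.random.default_rng(17)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            rows = []
            for g in ("a", "b", "c"):
                for i in range(8):
                    rows.append({"subject_id": f"{g}{i}", "group": g, "intervention": "pre",
                                 "within_level": "x", "outcome": "y", "value": rng.normal()})
            tk = tukey_posthoc(pd.DataFrame(rows), "y", "group")
            hits += bool((tk["p-adj"] < 0.05).any())
        assert hits / n_sim <= 0.07


def test_outcome_summary_shape(cohort):
    s = outcome_summary(cohort, "rdt")
    assert set(s["within_level"]) == {"basal", "step1", "step2"}
    assert (s["count"] > 0).all()


def test_intervention_effect_detected_when_injected():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = simulate_cohort((30, 30), {"is_multiplier": 1.37}, seed=9)
        eff = rm_anova_3way(res["table"], "rdt_per_insulin", within=("intervention",)).set_index("factor")
    assert eff.loc["intervention", "p"] < 0.01
    assert eff.loc["group", "p"] > 0.05
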