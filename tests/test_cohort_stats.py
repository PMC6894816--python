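"""Shared-strain fractions, separation binning, ANOVA + Tukey HSD (checked
against scipy's reference implementations), summary matrices and
cross-method concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wsstrack import (
    PairClassification,
    TwinCohort,
    assign_separation_group,
    build_summary_matrix,
    concordance,
    group_fractions,
    one_way_anova,
    related_fraction,
    tukey_hsd,
)
from wsstrack.classification import CALL_INDETERMINATE, CALL_RELATED, CALL_UNRELATED
from wsstrack.cohort_stats import SEPARATION_GROUPS


def make_cohort(separations: dict[str, int]) -> TwinCohort:
    rows = [
        {
            "pair_id": pid,
            "sample_a": f"{pid}_T1",
            "sample_b": f"{pid}_T2",
            "family_id": f"F_{pid}",
            "age_years": 30 + sep,
            "separation_years": sep,
        }
        for pid, sep in separations.items()
    ]
    return TwinCohort(pd.DataFrame(rows))


def make_call(species, pair, call, score=None, cutoff=90.0):
    if score is None and call != CALL_INDETERMINATE:
        score = 95.0 if call == CALL_RELATED else 40.0
    return PairClassification(
        species_id=species, pair_id=pair, sample_a=f"{pair}_T1",
        sample_b=f"{pair}_T2", wss_score=score, cutoff=cutoff, call=call,
    )


class TestRelatedFraction:
    def test_adult_dataset_multiplier(self):
        assert related_fraction(1, 250).multiplier == 0.004

    def test_pooled_dataset_multiplier_truncates(self):
        rf = related_fraction(1, 845)
        assert rf.multiplier == 0.0011  # 1/845 = 0.00118..., truncated
        assert rf.fraction == pytest.approx(1 / 845)

    def test_zero_related(self):
        assert related_fraction(0, 250).fraction == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            related_fraction(5, 4)
        with pytest.raises(ValueError):
            related_fraction(0, 0)


class TestSeparationGroups:
    @pytest.mark.parametrize(
        "years,label",
        [
            (0, "no separation"),
            (1, "1-9"),
            (9, "1-9"),
            (10, "10-19"),
            (19, "10-19"),  # a 19-year separation belongs to the 10-19 bin
            (20, "20-29"),
            (59, "50-59"),
        ],
    )
    def test_bin_edges(self, years, label):
        assert assign_separation_group(years) == label

    @pytest.mark.parametrize("years", [-1, 60, 1000])
    def test_out_of_range_rejected(self, years):
        with pytest.raises(ValueError):
            assign_separation_group(years)

    def test_groups_partition_the_cohort(self):
        cohort = make_cohort({f"P{i}": i for i in range(0, 60, 7)})
        groups = cohort.groups
        assert set(groups) == set(cohort.pair_ids)
        assert all(label in SEPARATION_GROUPS for label in groups.values())


class TestOneWayAnova:
    def test_hand_computed_two_group_fixture(self):
        # groups {1,2,3} and {2,3,4}: SSB = 1.5 (df 1), SSW = 4 (df 4)
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.F == pytest.approx(1.5, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_is_undefined(self):
        res = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert np.isnan(res.F) and np.isnan(res.p)

    def test_matches_scipy_on_random_fixtures(self, rng):
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1, size=int(rng.integers(2, 12)))
                      for _ in range(3)]
            res = one_way_anova(groups)
            ref = stats.f_oneway(*groups)
            assert res.F == pytest.approx(ref.statistic, abs=1e-10, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10, rel=1e-10)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, size=8)
            b = rng.normal(0.5, 1, size=5)
            res = one_way_anova([a, b])
            t = stats.ttest_ind(a, b, equal_var=True)
            assert res.F == pytest.approx(t.statistic**2, abs=1e-10, rel=1e-10)
            assert res.p == pytest.approx(t.pvalue, abs=1e-10, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0], []])


class TestTukeyHsd:
    def test_two_groups_reduce_to_anova_p(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, size=7)
            b = rng.normal(0.3, 1, size=9)
            anova = one_way_anova([a, b])
            (contrast,) = tukey_hsd([a, b])
            assert contrast.adjusted_p == pytest.approx(anova.p, abs=1e-7)

    def test_identical_groups_null_contrast(self):
        (contrast,) = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert contrast.mean_diff == 0.0
        assert contrast.adjusted_p == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_balanced_and_unbalanced(self, rng):
        for sizes in [(6, 6, 6), (4, 7, 10), (3, 5, 8, 6)]:
            groups = [rng.normal(rng.uniform(-1, 1), 1, size=n) for n in sizes]
            ours = tukey_hsd(groups)
            ref = stats.tukey_hsd(*groups)
            for c in ours:
                i, j = int(c.group_i[1:]), int(c.group_j[1:])
                assert c.mean_diff == pytest.approx(
                    groups[j].mean() - groups[i].mean(), abs=1e-12
                )
                assert c.adjusted_p == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_adjusted_p_at_least_unadjusted_pairwise_p(self, rng):
        for _ in range(10):
            groups = [rng.normal(0, 1, size=6) for _ in range(4)]
            n_total = sum(len(g) for g in groups)
            k = len(groups)
            dfw = n_total - k
            msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / dfw
            for c in tukey_hsd(groups):
                i, j = int(c.group_i[1:]), int(c.group_j[1:])
                se = np.sqrt(msw * (1 / len(groups[i]) + 1 / len(groups[j])))
                t_stat = abs(c.mean_diff) / se
                p_unadj = 2 * stats.t.sf(t_stat, dfw)
                assert c.adjusted_p >= p_unadj - 1e-12


class TestSummaryMatrix:
    def test_minimal_related_cell(self):
        cohort = make_cohort({"P1": 0})
        summary = build_summary_matrix([make_call("sp1", "P1", CALL_RELATED)], cohort)
        assert summary.matrix.loc["sp1", "P1"] == "R"
        assert summary.fractions["P1"].fraction == 1.0

    def test_indeterminate_without_score_has_no_number(self):
        cohort = make_cohort({"P1": 0})
        summary = build_summary_matrix(
            [make_call("sp1", "P1", CALL_INDETERMINATE)], cohort
        )
        assert summary.matrix.loc["sp1", "P1"] == "I"

    def test_indeterminate_with_score_shows_score(self):
        cohort = make_cohort({"P1": 0})
        summary = build_summary_matrix(
            [make_call("sp1", "P1", CALL_INDETERMINATE, score=42.5)], cohort
        )
        assert summary.matrix.loc["sp1", "P1"] == "I:42.5"

    def test_duplicate_species_pair_rejected(self):
        cohort = make_cohort({"P1": 0})
        calls = [make_call("sp1", "P1", CALL_RELATED)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            build_summary_matrix(calls, cohort)

    def test_related_counts_conserved(self):
        cohort = make_cohort({"P1": 0, "P2": 15})
        calls = [
            make_call("sp1", "P1", CALL_RELATED),
            make_call("sp2", "P1", CALL_UNRELATED),
            make_call("sp1", "P2", CALL_RELATED),
            make_call("sp2", "P2", CALL_RELATED),
        ]
        summary = build_summary_matrix(calls, cohort, n_total_strains=2)
        assert int(summary.n_related.sum()) == int((summary.matrix == "R").sum().sum())
        assert summary.fractions["P2"].fraction == 1.0
        assert all(0 <= rf.fraction <= 1 for rf in summary.fractions.values())

    def test_group_fractions_follow_cohort_bins(self):
        cohort = make_cohort({"P1": 0, "P2": 15, "P3": 17})
        calls = [
            make_call("sp1", "P1", CALL_RELATED),
            make_call("sp1", "P2", CALL_UNRELATED),
            make_call("sp1", "P3", CALL_RELATED),
        ]
        summary = build_summary_matrix(calls, cohort, n_total_strains=1)
        by_group = group_fractions(summary, cohort)
        assert by_group["no separation"] == [1.0]
        assert sorted(by_group["10-19"]) == [0.0, 1.0]


class TestConcordance:
    def test_identical_call_sets_agree(self):
        calls = [make_call("sp1", "P1", CALL_RELATED),
                 make_call("sp2", "P1", CALL_UNRELATED)]
        table = concordance(calls, calls)
        assert (table.agree_related, table.agree_unrelated, table.disagree) == (1, 1, 0)

    def test_single_flip_reported_with_key(self):
        a = [make_call("sp1", "P1", CALL_RELATED)]
        b = [make_call("sp1", "P1", CALL_UNRELATED)]
        table = concordance(a, b)
        assert table.disagree == 1
        assert table.disagree_keys == [("sp1", "P1")]

    def test_indeterminate_counted_separately(self):
        a = [make_call("sp1", "P1", CALL_RELATED)]
        b = [make_call("sp1", "P1", CALL_INDETERMINATE)]
        table = concordance(a, b)
        assert table.n_compared == 0
        assert table.n_indeterminate == 1

    def test_disjoint_keys_warn_and_return_empty(self):
        a = [make_call("sp1", "P1", CALL_RELATED)]
        b = [make_call("sp2", "P9", CALL_RELATED)]
        with pytest.warns(UserWarning, match="overlap"):
            table = concordance(a, b)
        assert table.n_compared == 0

    def test_matches_brute_force_tally(self, rng):
        species = [f"sp{i}" for i in range(4)]
        pairs = [f"P{i}" for i in range(5)]
        opts = [CALL_RELATED, CALL_UNRELATED, CALL_INDETERMINATE]
        for _ in range(20):
            a = [make_call(s, p, opts[rng.integers(0, 3)], score=50.0)
                 for s in species for p in pairs]
            b = [make_call(s, p, opts[rng.integers(0, 3)], score=50.0)
                 for s in species for p in pairs]
            table = concordance(a, b)
            tally = {"rr": 0, "uu": 0, "dis": 0, "ind": 0}
            for ca, cb in zip(a, b):
                if CALL_INDETERMINATE in (ca.call, cb.call):
                    tally["ind"] += 1
                elif ca.call == cb.call == CALL_RELATED:
                    tally["rr"] += 1
                elif ca.call == cb.call == CALL_UNRELATED:
                    tally["uu"] += 1
                else:
                    tally["dis"] += 1
            assert (table.agree_related, table.agree_unrelated,
                    table.disagree, table.n_indeterminate) == (
                tally["rr"], tally["uu"], tally["dis"], tally["ind"])


class TestTwinCohort:
    def test_sample_table_round_trip(self, tmp_path):
        cohort = make_cohort({"P1": 0, "P2": 25})
        samples = pd.DataFrame(
            [
                {"sample_id": r.sample_a, "pair_id": r.pair_id,
                 "family_id": r.family_id, "separation_years": r.separation_years,
                 "age_years": r.age_years}
                for r in cohort.pairs.itertuples()
            ]
            + [
                {"sample_id": r.sample_b, "pair_id": r.pair_id,
                 "family_id": r.family_id, "separation_years": r.separation_years,
                 "age_years": r.age_years}
                for r in cohort.pairs.itertuples()
            ]
        )
        rebuilt = TwinCohort.from_sample_table(samples)
        assert rebuilt.pair_ids == cohort.pair_ids
        assert rebuilt.groups == cohort.groups

    def test_duplicate_pair_rejected(self):
        df = make_cohort({"P1": 0}).pairs
        with pytest.raises(ValueError, match="duplicate"):
            TwinCohort(pd.concat([df, df], ignore_index=True))
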