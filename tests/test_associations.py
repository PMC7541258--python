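import numpy as np
import pandas as pd
import pytest

from mrsynergy.associations import (
    CohortTable,
    MutationClass,
    categorical_association,
    classify_mutation,
    combined_mutation_test,
    mutation_association,
    numerical_association,
    survival_split_logrank,
)


def make_cohort(expr_by_sample, gene="MR1", categorical=None, numerical=None,
                mutations=None, survival=None):
    samples = list(expr_by_sample)
    expression = pd.DataFrame(
        {s: [v] if np.isscalar(v) else list(v) for s, v in expr_by_sample.items()},
        index=[gene] if np.isscalar(next(iter(expr_by_sample.values())))
        else [gene, "MR2"],
    )
    return CohortTable(
        expression=expression,
        categorical=categorical if categorical is not None
        else pd.DataFrame(index=samples),
        numerical=numerical if numerical is not None else pd.DataFrame(index=samples),
        mutations=mutations if mutations is not None
        else pd.DataFrame(columns=["sample", "gene", "event"]),
        survival=survival if survival is not None else pd.DataFrame(),
    )


class TestClassifyMutation:
    @pytest.mark.parametrize(
        "events, expected",
        [
            (set(), MutationClass.NONE),
            ({"missense"}, MutationClass.MISSENSE),
            ({"missense", "frameshift"}, MutationClass.LOF),
            ({"nonsense"}, MutationClass.LOF),
            ({"splice", "missense", "nonsense"}, MutationClass.LOF),
        ],
    )
    def test_lof_dominates(self, events, expected):
        assert classify_mutation(events) is expected

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            classify_mutation({"synonymous"})

    def test_adding_events_never_lowers_class(self):
        order = {MutationClass.NONE: 0, MutationClass.MISSENSE: 1, MutationClass.LOF: 2}
        rng = np.random.default_rng(0)
        for _ in range(100):
            events = set(
                rng.choice(["missense", "nonsense", "frameshift", "splice"],
                           size=rng.integers(0, 4), replace=False)
            )
            base = classify_mutation(events)
            extra = str(rng.choice(["missense", "nonsense", "frameshift", "splice"]))
            assert order[classify_mutation(events | {extra})] >= order[base]


class TestCategoricalAssociation:
    def _cohort(self, group_sizes=(8, 8, 8), medians=(1.0, 5.0, 9.0)):
        rng = np.random.default_rng(1)
        expr, labels = {}, {}
        for gi, (n, med) in enumerate(zip(group_sizes, medians)):
            for i in range(n):
                s = f"s{gi}_{i}"
                expr[s] = med + rng.uniform(-0.3, 0.3)
                labels[s] = f"grp{gi}"
        cat = pd.DataFrame({"feature": pd.Series(labels)})
        return make_cohort(expr, categorical=cat)

    def test_extreme_median_groups_compared(self):
        res = categorical_association(self._cohort(), "MR1", "feature")
        assert (res.low_group, res.high_group) == ("grp0", "grp2")
        assert res.p is not None and res.p < 0.01

    def test_group_of_exactly_five_samples_dropped(self):
        res = categorical_association(
            self._cohort(group_sizes=(5, 8, 8)), "MR1", "feature"
        )
        assert res.low_group == "grp1"  # grp0 excluded by the strict '>' rule

    def test_fewer_than_two_retained_groups_undefined(self):
        res = categorical_association(
            self._cohort(group_sizes=(5, 5, 8)), "MR1", "feature"
        )
        assert res.p is None and res.reason is not None

    def test_identical_groups_give_p_one(self):
        expr = {f"a{i}": float(v) for i, v in enumerate(range(6))}
        expr |= {f"b{i}": float(v) for i, v in enumerate(range(6))}
        cat = pd.DataFrame(
            {"feature": ["A"] * 6 + ["B"] * 6}, index=list(expr)
        )
        res = categorical_association(make_cohort(expr, categorical=cat), "MR1", "feature")
        assert res.p == pytest.approx(1.0)


class TestMutationAssociation:
    def _cohort(self):
        expr = {"m1": 10.0, "m2": 12.0, "m3": 14.0, "n1": 1.0, "n2": 2.0, "n3": 3.0}
        muts = pd.DataFrame(
            [(s, "KRAS", "missense") for s in ("m1", "m2", "m3")],
            columns=["sample", "gene", "event"],
        )
        return make_cohort(expr, mutations=muts)

    def test_exact_p_direction_and_strict_alpha(self):
        (res,) = mutation_association(self._cohort(), "MR1", "KRAS", alpha=0.1)
        assert res.mutation_class is MutationClass.MISSENSE
        assert res.n == 3
        assert res.direction == "higher"
        assert res.delta_median == pytest.approx(10.0)
        assert res.p == pytest.approx(0.1)  # 2/C(6,3)
        assert res.selected is False  # strict '<'

    def test_absent_class_omitted(self):
        results = mutation_association(self._cohort(), "MR1", "KRAS")
        assert [r.mutation_class for r in results] == [MutationClass.MISSENSE]

    def test_empty_none_group_errors(self):
        expr = {"m1": 1.0, "m2": 2.0}
        muts = pd.DataFrame(
            [("m1", "KRAS", "missense"), ("m2", "KRAS", "nonsense")],
            columns=["sample", "gene", "event"],
        )
        with pytest.raises(ValueError):
            mutation_association(make_cohort(expr, mutations=muts), "MR1", "KRAS")


class TestCombinedMutationTest:
    def test_group_membership_logic(self):
        expr = {f"s{i}": float(i) for i in range(6)}
        muts = pd.DataFrame(
            [
                ("s0", "A", "missense"),
                ("s1", "B", "missense"),
                ("s1", "A", "nonsense"),   # missense in B still puts s1 in group A
                ("s2", "A", "frameshift"),  # LOF-only: in neither group
            ],
            columns=["sample", "gene", "event"],
        )
        n_mut, n_none, p = combined_mutation_test(
            make_cohort(expr, mutations=muts), "MR1", {"A", "B"}
        )
        assert (n_mut, n_none) == (2, 3)  # s0, s1 vs s3, s4, s5
        assert p is not None

    def test_no_mutated_samples_undefined(self):
        expr = {f"s{i}": float(i) for i in range(4)}
        n_mut, n_none, p = combined_mutation_test(make_cohort(expr), "MR1", {"A"})
        assert n_mut == 0 and p is None

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            combined_mutation_test(make_cohort({"s": 1.0}), "MR1", set())


class TestNumericalAssociation:
    def test_perfect_monotone_pairs(self):
        expr = {f"s{i}": float(i) for i in range(6)}
        up = pd.DataFrame({"f": np.arange(6.0)}, index=list(expr))
        down = pd.DataFrame({"f": -np.arange(6.0)}, index=list(expr))
        rho_up, _ = numerical_association(make_cohort(expr, numerical=up), "MR1", "f")
        rho_dn, _ = numerical_association(make_cohort(expr, numerical=down), "MR1", "f")
        assert rho_up == pytest.approx(1.0)
        assert rho_dn == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        expr = {f"s{i}": float(i) for i in range(3)}
        num = pd.DataFrame({"f": np.arange(3.0)}, index=list(expr))
        with pytest.raises(ValueError):
            numerical_association(make_cohort(expr, numerical=num), "MR1", "f")


def logrank_oracle(times, events, groups):
    """Independent O-E/V accumulation for the two-group log-rank statistic."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    o_minus_e, var = 0.0, 0.0
    for t in sorted(df.loc[df.e == 1, "t"].unique()):
        at_risk = df[df.t >= t]
        n = len(at_risk)
        n1 = int((at_risk.g == 1).sum())
        d = int(((df.t == t) & (df.e == 1)).sum())
        d1 = int(((df.t == t) & (df.e == 1) & (df.g == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestSurvival:
    def _cohort(self, expr, times, events):
        samples = list(expr)
        surv = pd.DataFrame(
            {"os_time": times, "os_event": events}, index=samples
        )
        return make_cohort(expr, survival=surv)

    def test_percentile_split_sizes(self):
        expr = {f"s{i}": float(i) for i in range(10)}
        cohort = self._cohort(expr, times=list(range(1, 11)), events=[1] * 10)
        res = survival_split_logrank(cohort, "MR1", 80)
        assert (res.n_high, res.n_low) == (2, 8)

    def test_identical_event_times_give_null_statistic(self):
        expr = {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 7.0, "b2": 8.0, "b3": 9.0}
        cohort = self._cohort(expr, times=[1, 2, 3, 1, 2, 3], events=[1] * 6)
        res = survival_split_logrank(cohort, "MR1", 50)
        assert res.chi_sq == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_accumulated_o_minus_e(self):
        expr = {f"s{i}": float(i) for i in range(8)}
        times = [2.0, 5.0, 7.0, 9.0, 3.0, 4.0, 8.0, 10.0]
        events = [1, 0, 1, 1, 1, 1, 0, 1]
        cohort = self._cohort(expr, times, events)
        res = survival_split_logrank(cohort, "MR1", 50)
        groups = [int(expr[f"s{i}"] > np.percentile(list(expr.values()), 50))
                  for i in range(8)]
        expected = logrank_oracle(times, events, groups)
        assert res.chi_sq == pytest.approx(expected, rel=1e-6)

    def test_no_events_undefined(self):
        expr = {f"s{i}": float(i) for i in range(10)}
        cohort = self._cohort(expr, times=[5.0] * 10, events=[0] * 10)
        res = survival_split_logrank(cohort, "MR1", 50)
        assert res.p is None and res.reason == "no events"
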