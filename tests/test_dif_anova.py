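"""Residuals, class intervals, and the two-way ANOVA DIF tests."""

import numpy as np
import pytest

import raschdif as rd
from raschdif.dif_anova import count_dif_tests, dif_anova_item

from test_rasch_core import make_item


def make_persons(locations, groups=None, ids=None):
    locations = np.asarray(locations, dtype=float)
    n = len(locations)
    return rd.PersonEstimates(
        person_ids=np.array(ids if ids is not None else [f"p{i}" for i in range(n)], dtype=object),
        group=np.array(groups if groups is not None else ["a"] * n, dtype=object),
        total=np.zeros(n, dtype=int),
        n_answered=np.full(n, 1),
        location=locations,
        se=np.full(n, 0.5),
        extreme=np.zeros(n, dtype=bool),
    )


def make_assignment(intervals):
    intervals = np.asarray(intervals, dtype=int)
    c = intervals.max()
    return rd.ClassIntervalAssignment(
        n_intervals=int(c),
        interval=intervals,
        boundaries=np.arange(c, dtype=float),
        counts=np.bincount(intervals, minlength=c + 1)[1:],
    )


class TestStandardizedResiduals:
    def test_observed_equals_expected_gives_zero(self):
        # dichotomous item at its location: E = 0.5, V = 0.25 -> z = +-1
        item = make_item(0.0, [0.0], item_id="d")
        matrix = rd.ResponseMatrix(
            person_ids=np.array(["p0", "p1"], dtype=object),
            group=np.array(["a", "b"], dtype=object),
            scores=np.array([[1.0], [0.0]]),
            items=[rd.ItemDef("d", 1)],
        )
        persons = make_persons([0.0, 0.0], groups=["a", "b"])
        itemset = rd.ItemParameterSet(items=[item])
        resid = rd.standardized_residuals(matrix, itemset, persons)
        assert resid.z[0, 0] == pytest.approx(1.0)
        assert resid.z[1, 0] == pytest.approx(-1.0)

    def test_matches_hand_enumerated_moments(self, example_item):
        from conftest import pcm_probs_oracle

        beta = example_item.location + 0.7
        p = pcm_probs_oracle(beta, example_item.location, example_item.thresholds)
        k = np.arange(5)
        e = float(k @ p)
        v = float((k**2) @ p - e**2)
        matrix = rd.ResponseMatrix(
            person_ids=np.array(["p0"], dtype=object),
            group=np.array(["a"], dtype=object),
            scores=np.array([[3.0]]),
            items=[rd.ItemDef("ex", 4)],
        )
        persons = make_persons([beta])
        resid = rd.standardized_residuals(
            matrix, rd.ItemParameterSet(items=[example_item]), persons
        )
        assert resid.z[0, 0] == pytest.approx((3 - e) / np.sqrt(v), abs=1e-10)

    def test_extreme_persons_absent(self, dif_fit):
        matrix, _, items, persons = dif_fit
        resid = rd.standardized_residuals(matrix, items, persons)
        assert np.all(np.isnan(resid.z[persons.extreme]))
        ok = ~persons.extreme & np.isfinite(persons.location)
        assert np.all(np.isfinite(resid.z[ok][matrix.answered[ok]]))

    def test_total_score_constraint_under_ml(self, clean_fit):
        # at ML person estimates the sum of (observed - expected) per person is 0
        matrix, _, items, _ = clean_fit
        persons_ml = rd.estimate_persons(matrix, items, method="ml")
        ok = ~persons_ml.extreme & np.isfinite(persons_ml.location)
        total_resid = np.zeros(matrix.n_persons)
        for j, it in enumerate(matrix.items):
            e, _ = rd.rasch_core._moments_grid(items[it.item_id], persons_ml.location[ok])
            total_resid[ok] += matrix.scores[ok, j] - e
        assert np.max(np.abs(total_resid[ok])) < 1e-6


class TestClassIntervals:
    def test_even_split(self):
        persons = make_persons(np.linspace(-2, 2, 100))
        a = rd.assign_class_intervals(persons, 10)
        assert np.all(a.counts == 10)

    def test_remainders_to_lowest_intervals(self):
        persons = make_persons(np.linspace(-2, 2, 95))
        a = rd.assign_class_intervals(persons, 10)
        assert sorted(set(a.counts)) == [9, 10]
        assert list(a.counts) == [10] * 5 + [9] * 5

    def test_interval_monotone_in_location(self):
        rng = np.random.default_rng(1)
        persons = make_persons(rng.normal(size=200))
        a = rd.assign_class_intervals(persons, 10)
        order = np.argsort(persons.location)
        assert np.all(np.diff(a.interval[order]) >= 0)

    def test_ties_never_split_and_match_partition_oracle(self):
        # integer-valued locations with heavy ties
        rng = np.random.default_rng(2)
        locs = rng.integers(0, 12, size=1000).astype(float)
        persons = make_persons(locs)
        a = rd.assign_class_intervals(persons, 10)
        for u in np.unique(locs):
            assert len(set(a.interval[locs == u])) == 1
        # independent greedy quantile partition over sorted unique values
        uniq, counts = np.unique(locs, return_counts=True)
        base, rem = divmod(len(locs), 10)
        targets = np.cumsum([base + 1] * rem + [base] * (10 - rem))
        expect, c, filled = {}, 0, 0
        for u, k in zip(uniq, counts):
            while filled >= targets[c] and c < 9:
                c += 1
            expect[u] = c + 1
            filled += k
        for u in uniq:
            assert a.interval[locs == u][0] == expect[u]

    def test_argument_validation(self):
        persons = make_persons(np.linspace(0, 1, 30))
        with pytest.raises(ValueError):
            rd.assign_class_intervals(persons, 1)
        few = make_persons([0.0] * 20 + [1.0] * 20)
        with pytest.warns(UserWarning, match="distinct locations"):
            a = rd.assign_class_intervals(few, 10)
        assert a.n_intervals == 2


def anova_oracle(y, f1, f2):
    """Definitional balanced two-way ANOVA sums of squares (textbook form)."""
    y = np.asarray(y, dtype=float)
    lv1, lv2 = np.unique(f1), np.unique(f2)
    gm = y.mean()
    n = len(y)
    r = n / (len(lv1) * len(lv2))  # replicates per cell (balanced)
    ss_1 = sum((y[f1 == a].mean() - gm) ** 2 * (y[f1 == a]).size for a in lv1)
    ss_2 = sum((y[f2 == b].mean() - gm) ** 2 * (y[f2 == b]).size for b in lv2)
    ss_cells = 0.0
    for a in lv1:
        for b in lv2:
            cell = y[(f1 == a) & (f2 == b)]
            ss_cells += len(cell) * (cell.mean() - gm) ** 2
    ss_int = ss_cells - ss_1 - ss_2
    ss_err = sum(
        ((y[(f1 == a) & (f2 == b)] - y[(f1 == a) & (f2 == b)].mean()) ** 2).sum()
        for a in lv1
        for b in lv2
    )
    df1, df2 = len(lv1) - 1, len(lv2) - 1
    dfi = df1 * df2
    dfe = n - len(lv1) * len(lv2)
    mse = ss_err / dfe
    return (
        ss_1 / df1 / mse,
        ss_2 / df2 / mse,
        ss_int / dfi / mse,
    )


class TestDifAnovaItem:
    def test_balanced_fixture_matches_definitional_oracle(self):
        rng = np.random.default_rng(42)
        iv = np.repeat([1, 2, 3], 8)
        g = np.tile(np.repeat(["a", "b"], 4), 3)
        z = rng.normal(size=24) + 0.4 * (g == "a") + 0.2 * iv
        res = dif_anova_item(z, make_assignment(iv), g, item_id="x")
        f_c, f_g, f_i = anova_oracle(z, iv, g)
        assert res.f_class == pytest.approx(f_c, abs=1e-8)
        assert res.f_group == pytest.approx(f_g, abs=1e-8)
        assert res.f_interaction == pytest.approx(f_i, abs=1e-8)
        assert res.df_class == (2, 18)
        assert res.df_group == (1, 18)
        assert res.df_interaction == (2, 18)

    def test_type_i_error_near_nominal(self):
        # pure N(0,1) residuals: each effect rejects at ~alpha
        rng = np.random.default_rng(3)
        n, reps, alpha = 240, 600, 0.05
        iv = np.repeat(np.arange(1, 7), n // 6)
        g = np.tile(np.repeat(["a", "b"], n // 12), 6)
        rej = np.zeros(3)
        assignment = make_assignment(iv)
        for _ in range(reps):
            z = rng.normal(size=n)
            res = dif_anova_item(z, assignment, g)
            rej += [res.p_class < alpha, res.p_group < alpha, res.p_interaction < alpha]
        assert np.all(np.abs(rej / reps - alpha) < 0.025)

    def test_group_shift_raises_group_f_only(self):
        rng = np.random.default_rng(4)
        n = 400
        iv = np.repeat(np.arange(1, 11), n // 10)
        g = np.tile(np.repeat(["a", "b"], n // 20), 10)
        z = rng.normal(size=n)
        z[g == "a"] += 0.5
        res = dif_anova_item(z, make_assignment(iv), g)
        assert res.p_group < 1e-4
        assert res.p_interaction > 0.01

    def test_single_group_item_gets_class_test_only(self):
        rng = np.random.default_rng(5)
        iv = np.repeat(np.arange(1, 6), 10)
        g = np.array(["a"] * 50, dtype=object)
        res = dif_anova_item(
            rng.normal(size=50), make_assignment(iv), g, group_restriction="a"
        )
        assert np.isfinite(res.f_class)
        assert np.isnan(res.f_group) and np.isnan(res.f_interaction)

    def test_constant_residuals_undefined(self):
        iv = np.repeat([1, 2], 10)
        g = np.tile(["a", "b"], 10)
        with pytest.warns(UserWarning, match="identical"):
            res = dif_anova_item(np.zeros(20), make_assignment(iv), g)
        assert np.isnan(res.f_group)


class TestSampleSizeAdjustment:
    def make_result(self, n_eff, f=20.0):
        return rd.AnovaResult(
            item_id="x", group_restriction="all",
            f_class=f, f_group=f, f_interaction=f,
            df_class=(9.0, n_eff - 20), df_group=(1.0, n_eff - 20),
            df_interaction=(9.0, n_eff - 20),
            p_class=0.01, p_group=0.01, p_interaction=0.01,
            n_effective=n_eff, n_cells=20,
        )

    def test_identity_at_target(self):
        res = rd.adjust_for_sample_size(self.make_result(960), 960)
        assert res.f_group_adj == res.f_group
        assert res.p_group_adj == res.p_group

    def test_tenfold_scaling(self):
        res = rd.adjust_for_sample_size(self.make_result(9600, f=20.0), 960)
        assert res.f_group_adj == pytest.approx(2.0)

    def test_small_samples_pass_through(self):
        res = rd.adjust_for_sample_size(self.make_result(500), 960)
        assert res.f_group_adj == res.f_group

    def test_never_creates_significance(self, dif_fit):
        matrix, _, items, persons = dif_fit
        analysis = rd.dif_analysis(matrix, items, persons)
        for r in analysis.results:
            for eff in ("class", "group", "interaction"):
                p_raw = getattr(r, f"p_{eff}")
                p_adj = getattr(r, f"p_{eff}_adj")
                if np.isfinite(p_raw) and np.isfinite(p_adj):
                    assert p_adj >= p_raw - 1e-12

    def test_rejects_target_below_cells(self):
        with pytest.raises(ValueError):
            rd.adjust_for_sample_size(self.make_result(960), 10)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 24, 0.002083), (0.05, 20, 0.002500), (0.05, 1, 0.05)],
    )
    def test_reported_levels(self, alpha, n, expected):
        assert round(rd.bonferroni_threshold(alpha, n), 6) == expected

    def test_zero_tests_invalid(self):
        with pytest.raises(ValueError):
            rd.bonferroni_threshold(0.05, 0)

    def test_test_count_rule(self):
        # 3 tests per two-group item, 1 per resolved single-group copy:
        # 8 ordinary items -> 24; 4 ordinary + 8 copies -> 20
        def res(restriction):
            return rd.AnovaResult(
                item_id="x", group_restriction=restriction,
                f_class=1.0, f_group=np.nan, f_interaction=np.nan,
                df_class=(1, 1), df_group=(np.nan, np.nan),
                df_interaction=(np.nan, np.nan),
                p_class=0.5, p_group=np.nan, p_interaction=np.nan,
                n_effective=100, n_cells=10,
            )

        assert count_dif_tests([res("all")] * 8) == 24
        assert count_dif_tests([res("all")] * 4 + [res("g")] * 8) == 20


class TestRanking:
    def test_injected_item_ranked_first(self, dif_fit):
        matrix, _, items, persons = dif_fit
        analysis = rd.dif_analysis(matrix, items, persons)
        assert analysis.flagged
        assert analysis.flagged[0].item_id == "item4"

    def test_nothing_significant_empty(self):
        r = rd.AnovaResult(
            item_id="x", group_restriction="all",
            f_class=1.0, f_group=1.0, f_interaction=1.0,
            df_class=(9, 100), df_group=(1, 100), df_interaction=(9, 100),
            p_class=0.5, p_group=0.5, p_interaction=0.5,
            n_effective=120, n_cells=20,
        )
        assert rd.rank_dif_items([r], 0.002) == []

    def test_tie_broken_by_item_order(self):
        def res(iid):
            return rd.AnovaResult(
                item_id=iid, group_restriction="all",
                f_class=1.0, f_group=7.0, f_interaction=1.0,
                df_class=(9, 100), df_group=(1, 100), df_interaction=(9, 100),
                p_class=0.5, p_group=1e-5, p_interaction=0.5,
                n_effective=120, n_cells=20,
            )

        ranked = rd.rank_dif_items([res("b"), res("a")], 0.01)
        assert [r.item_id for r in ranked] == ["b", "a"]
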