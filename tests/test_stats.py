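"""Inferential layer vs independent oracles (hand ranks, scipy, pingouin)."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import equicost as ec
from equicost.stats import summarize_groups


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [v * v for v in x]
        assert ec.spearman(x, y).rho == pytest.approx(1.0)
        assert ec.spearman(x, y[::-1]).rho == pytest.approx(-1.0)

    def test_tied_vector_against_hand_midranks(self):
        """One tie in x: mid-ranks written out by hand, rho as their Pearson
        correlation, independent of the implementation's ranking path."""
        x = [10, 20, 20, 30, 40, 50]
        y = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])  # by hand
        ry = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        expected = float(np.corrcoef(rx, ry)[0, 1])
        res = ec.spearman(x, y)
        assert res.rho == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=4, max_size=12, unique=True
        ).flatmap(
            lambda xs: st.tuples(
                st.just(xs),
                st.lists(
                    st.floats(-100, 100, allow_nan=False),
                    min_size=len(xs),
                    max_size=len(xs),
                    unique=True,
                ),
            )
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_scipy_reference(self, pair):
        x, y = pair
        res = ec.spearman(x, y)
        ref_rho, ref_p = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref_rho, abs=1e-10)
        if abs(res.rho) < 1:
            assert res.p_value == pytest.approx(ref_p, abs=1e-8)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = ec.spearman(x, y).rho
        assert ec.spearman(np.exp(x), y).rho == pytest.approx(base)
        assert ec.spearman(x, 3 * y + 7).rho == pytest.approx(base)

    def test_exact_permutation_p_value(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        res = ec.spearman(x, y, method="exact")
        assert 0 <= res.p_value <= 1
        # enumeration oracle of the same tail probability
        ref = sps.permutation_test(
            (np.array(y),),
            lambda perm: sps.spearmanr(x, perm).statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=math.inf,
        )
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ec.EquicostError):
            ec.spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ec.EquicostError):
            ec.spearman([1, 2], [1, 2])
        with pytest.raises(ec.EquicostError):
            ec.spearman([1, 2, 3], [1, 2])


class TestAnova:
    def test_two_groups_equal_squared_pooled_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        res = ec.anova_oneway([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1.5, n) for m, n in ((0, 5), (1, 8), (0.5, 6), (2, 4))]
        res = ec.anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.df_between == 3 and res.df_within == sum(len(g) for g in groups) - 4

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(i, 1, 6) for i in range(4)]
        res = ec.anova_oneway(groups)
        res_perm = ec.anova_oneway(groups[::-1])
        assert res.f_statistic == pytest.approx(res_perm.f_statistic)

    def test_identical_constant_groups_give_undefined_f(self):
        res = ec.anova_oneway([[3.0, 3.0, 3.0], [3.0, 3.0]])
        assert math.isnan(res.f_statistic) and math.isnan(res.p_value)

    def test_welch_variant_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 8), (1, 3, 10), (0.5, 0.5, 6))]
        res = ec.anova_oneway(groups, welch=True)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(np.arange(3), [len(g) for g in groups]),
            }
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.f_statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)


class TestAnovaFromSummary:
    def test_exact_equivalence_with_raw_anova(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            k = rng.integers(2, 6)
            groups = [
                rng.normal(rng.normal(0, 2), rng.uniform(0.5, 3), rng.integers(2, 9))
                for _ in range(k)
            ]
            raw = ec.anova_oneway(groups)
            summ = ec.anova_from_summary(summarize_groups(groups))
            assert summ.f_statistic == pytest.approx(raw.f_statistic, rel=1e-9)
            assert summ.ss_between == pytest.approx(raw.ss_between, rel=1e-9)
            assert summ.ss_within == pytest.approx(raw.ss_within, rel=1e-9)
            assert (summ.df_between, summ.df_within) == (raw.df_between, raw.df_within)

    def test_equal_means_give_zero_f(self):
        rows = [ec.GroupSummary("a", 5, 2.0, 1.0), ec.GroupSummary("b", 7, 2.0, 2.0)]
        assert ec.anova_from_summary(rows).f_statistic == pytest.approx(0.0)

    def test_small_groups_rejected(self):
        with pytest.raises(ec.EquicostError):
            ec.GroupSummary("a", 1, 0.0, 0.0)
        with pytest.raises(ec.EquicostError):
            ec.anova_from_summary([ec.GroupSummary("a", 5, 1.0, 1.0)])


class TestCorrelationSuite:
    def test_families_on_constructed_data(self, full_study):
        dataset, _ = full_study
        counties = sorted({i.county for i in dataset.institutions})
        rng = np.random.default_rng(9)
        # GDP increasing in county revenue so the revenue family is positive
        revenue_by_county = {
            c: sum(
                float(dataset.finance_for(i.institution_id).nephsp_revenue)
                for i in dataset.institutions
                if i.county == c
            )
            for c in counties
        }
        cov = [
            {"county": c, "gdp": revenue_by_county[c] * (1 + 0.1 * rng.random())}
            for c in counties
        ]
        results = {r.label: r for r in ec.correlation_suite(dataset, cov)}
        assert results["nephsp_revenue_vs_county_gdp"].rho > 0
        r_cases = results["total_equivalents_vs_annual_cases"]
        assert r_cases.rho > 0 and r_cases.p_value < 0.01
        for r in results.values():
            assert -1 <= r.rho <= 1 and 0 <= r.p_value <= 1
            assert r.n == len(dataset.institutions)

    def test_cases_proportional_to_equivalents_gives_rho_one(self, small_study):
        """When every institution delivers the same single service, annual
        case volume is proportional to total equivalents, so the rank
        correlation of that family is exactly 1."""
        dataset, _ = small_study
        workloads = [
            ec.WorkloadRecord(
                institution_id=i.institution_id,
                service_class="nephsp",
                category="health education",
                item="lecture",
                workers_per_case=1,
                minutes_per_case=15 + 0.1 * idx,  # keep unit values non-constant
                annual_cases=1000 + 17 * idx,
            )
            for idx, i in enumerate(dataset.institutions)
        ]
        ds = ec.StudyDataset(
            institutions=dataset.institutions,
            workloads=workloads,
            finances=dataset.finances,
        )
        results = {r.label: r for r in ec.correlation_suite(ds)}
        assert results["total_equivalents_vs_annual_cases"].rho == pytest.approx(1.0)

    def test_missing_county_covariate_is_fatal(self, full_study):
        dataset, _ = full_study
        with pytest.raises(ec.EquicostError, match="county"):
            ec.correlation_suite(dataset, [{"county": "nowhere", "gdp": 1.0}])

    def test_permuted_covariate_decorrelates_on_average(self, full_study):
        """Null behaviour: permuting GDP across counties kills the revenue
        correlation on average over permutations."""
        dataset, _ = full_study
        counties = sorted({i.county for i in dataset.institutions})
        rng = np.random.default_rng(11)
        gdps = np.linspace(1.0, 10.0, len(counties))
        rhos = []
        for _ in range(100):
            perm = rng.permutation(gdps)
            cov = [{"county": c, "gdp": g} for c, g in zip(counties, perm)]
            results = {r.label: r for r in ec.correlation_suite(dataset, cov)}
            rhos.append(results["nephsp_revenue_vs_county_gdp"].rho)
        assert abs(np.mean(rhos)) < 0.1
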