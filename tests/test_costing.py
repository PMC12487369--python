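"""Cost allocation: hand-checkable chains, conservation under factor
rounding, monotonicity, and parameter recovery."""
from decimal import Decimal

import pytest

import equicost as ec
from equicost.equivalents import TOTAL_LABEL

from conftest import build_tiny_dataset


class TestCoreOps:
    def test_identity_ratio(self):
        f = ec.cost_per_equivalent(Decimal("100"), 100.0)
        assert f.rounded == Decimal("1.00")
        assert f.unrounded == pytest.approx(1.0)

    def test_zero_equivalents_is_a_domain_error_naming_scope(self):
        with pytest.raises(ec.EquicostError, match="EmptyTown"):
            ec.cost_per_equivalent(Decimal("10"), 0.0, scope="EmptyTown")

    def test_allocation_with_zero_programme_equivalents(self):
        assert ec.estimated_nephsp_cost(Decimal("18.00"), 0.0) == Decimal("0.00")

    def test_per_capita_edges(self):
        assert ec.per_capita(Decimal("0"), 1000) == Decimal("0.00")
        with pytest.raises(ec.EquicostError):
            ec.per_capita(Decimal("10"), 0)


class TestPipeline:
    def test_one_equivalent_world(self):
        """One institution, one case of one worker for 15 minutes, cost 150:
        the whole chain collapses to 150 per equivalent and 150 allocated."""
        ds = build_tiny_dataset(
            institutions=[
                ec.Institution(
                    institution_id="A1",
                    region="Eastern",
                    county="c",
                    township="t",
                    registered_residents=100,
                    health_professionals=1,
                )
            ],
            workloads=[
                ec.WorkloadRecord(
                    institution_id="A1",
                    service_class="nephsp",
                    category="health education",
                    item="lecture",
                    workers_per_case=1,
                    minutes_per_case=15,
                    annual_cases=1,
                )
            ],
            finances=[
                ec.FinanceRecord(
                    institution_id="A1",
                    operational_cost=Decimal("150.00"),
                    nephsp_revenue=Decimal("0"),
                    nephsp_expenditure=Decimal("0"),
                )
            ],
        )
        [est] = [e for e in ec.cost_pipeline(ds, "total")]
        assert est.cost_per_equivalent == Decimal("150.00")
        assert est.estimated_nephsp_cost == Decimal("150.00")
        assert est.per_capita_estimated_cost == Decimal("1.50")

    def test_tiny_dataset_chain_by_hand(self, tiny_dataset):
        by_scope = {e.scope: e for e in ec.cost_pipeline(tiny_dataset, "institution")}
        # A1: 4000 / 400 eq = 10.00; allocated 10 × 160 = 1600; 1600/1000 residents
        a1 = by_scope["A1"]
        assert a1.cost_per_equivalent == Decimal("10.00")
        assert a1.estimated_nephsp_cost == Decimal("1600.00")
        assert a1.per_capita_estimated_cost == Decimal("1.60")
        assert a1.per_capita_actual_subsidy == Decimal("1.00")
        assert a1.per_capita_actual_expenditure == Decimal("1.10")
        assert a1.per_capita_allocated_subsidy == Decimal("74.00")
        # pooled: 5000 / 600 eq = 8.33; group ratio, not mean of ratios
        total = by_scope[TOTAL_LABEL]
        assert total.cost_per_equivalent == Decimal("8.33")
        assert total.estimated_nephsp_cost == Decimal("2165.80")  # 8.33 × 260

    def test_conservation_bound_under_factor_rounding(self, full_study):
        """allocated(programme) + factor × other equivalents ≈ operational
        cost, within 0.005 CNY per equivalent of rounding slack."""
        dataset, _ = full_study
        for est in ec.cost_pipeline(dataset, "region"):
            other = est.total_equivalents_all - est.total_equivalents_nephsp
            reconstructed = float(est.estimated_nephsp_cost) + float(
                est.cost_per_equivalent
            ) * other
            assert abs(reconstructed - float(est.operational_cost)) <= (
                0.005 * est.total_equivalents_all + 0.01
            )

    def test_monotonicity_in_cost_and_equivalents(self):
        base = ec.estimated_nephsp_cost(Decimal("18.00"), 1000.0)
        assert ec.estimated_nephsp_cost(Decimal("18.00"), 1500.0) >= base
        assert ec.estimated_nephsp_cost(Decimal("20.00"), 1000.0) >= base

    def test_unrounded_mode_recovers_constructed_cost_rate(self):
        """Costs built as c* × equivalents give back c* (to the cent-level
        precision the finance ledger can represent)."""
        cfg = ec.GeneratorConfig(
            seed=11, noise_sd=0.0, revenue_lag_factor=1.0,
            n_regions=2, counties_per_region=1, townships_per_county=2,
        )
        dataset, truth = ec.generate_study(cfg)
        results = ec.EquivalentCostModel(dataset).fit("institution", rounding="unrounded")
        for est in results.estimates:
            if est.level != "institution":
                continue
            assert est.cost_per_equivalent_unrounded == pytest.approx(
                truth.true_cost_per_equivalent[est.scope], rel=1e-6
            )

    def test_per_capita_consistency(self, full_study):
        dataset, _ = full_study
        for est in ec.cost_pipeline(dataset, "region"):
            assert abs(
                float(est.per_capita_estimated_cost) * est.registered_residents
                - float(est.estimated_nephsp_cost)
            ) <= 0.005 * est.registered_residents

    def test_groups_failing_preconditions_are_skipped_with_reason(self, tiny_dataset):
        ds = build_tiny_dataset(
            workloads=[w for w in tiny_dataset.workloads if w.institution_id == "A1"]
        )
        results = ec.EquivalentCostModel(ds).fit("institution")
        assert {e.scope for e in results.estimates} == {"A1", TOTAL_LABEL}
        assert any(scope == "A2" for scope, _ in results.skipped)


class TestFundingGap:
    def test_break_even_hand_values(self):
        assert ec.break_even_population(Decimal("74"), 74) == pytest.approx(1.0)
        assert ec.break_even_population(1000, 50) == pytest.approx(20.0)
        with pytest.raises(ec.EquicostError):
            ec.break_even_population(100, 0)

    def test_boundary_reference_population_is_not_a_shortfall(self, tiny_dataset):
        # revenue 1400, rate 74 → break-even 18.9189...
        be = ec.break_even_population(Decimal("1400"), 74)
        report = ec.funding_gap_report(tiny_dataset, be)
        assert not report.implied_gap_flag
        assert ec.funding_gap_report(tiny_dataset, be + 1).implied_gap_flag

    def test_revenue_matching_rate_times_population_has_zero_gap(self):
        ds = build_tiny_dataset(
            finances=[
                ec.FinanceRecord(
                    institution_id="A1",
                    operational_cost="4000",
                    nephsp_revenue=Decimal("74000.00"),  # 74 × 1000
                    nephsp_expenditure="0",
                ),
                ec.FinanceRecord(
                    institution_id="A2",
                    operational_cost="1000",
                    nephsp_revenue=Decimal("37000.00"),  # 74 × 500
                    nephsp_expenditure="0",
                ),
            ]
        )
        report = ec.funding_gap_report(ds, reference_population=1500)
        assert report.break_even_population == pytest.approx(1500.0)
        assert not report.implied_gap_flag

    def test_aggregate_study_shortfall_flagged(self, tables_dataset):
        report = ec.funding_gap_report(tables_dataset, reference_population=1_695_105)
        assert report.implied_gap_flag
        assert report.break_even_population < report.reference_population
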