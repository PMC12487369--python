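from decimal import Decimal

import pytest

import equicost as ec


@pytest.fixture(scope="session")
def tables_dataset() -> ec.StudyDataset:
    """The packaged regional-aggregate pseudo-institutions."""
    return ec.fixture_from_tables()


@pytest.fixture(scope="session")
def small_config() -> ec.GeneratorConfig:
    return ec.GeneratorConfig(
        seed=123, n_regions=2, counties_per_region=2, townships_per_county=2
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return ec.generate_study(small_config)


@pytest.fixture(scope="session")
def full_study():
    """Default study design: 5 regions × 2 counties × 5 townships."""
    return ec.generate_study(ec.GeneratorConfig(seed=20200101))


def build_tiny_dataset(**overrides) -> ec.StudyDataset:
    """Two hand-written institutions with arithmetic simple enough to check
    by hand (all equivalents are small integers or .5 fractions)."""
    institutions = [
        ec.Institution(
            institution_id="A1",
            region="Eastern",
            county="county-1",
            township="town-1",
            registered_residents=1000,
            health_professionals=10,
        ),
        ec.Institution(
            institution_id="A2",
            region="Southern",
            county="county-2",
            township="town-2",
            registered_residents=500,
            health_professionals=5,
        ),
    ]
    workloads = [
        # A1: nephsp 1.6*100 = 160 eq; primary 1.0*240 = 240 eq
        ec.WorkloadRecord(
            institution_id="A1",
            service_class="nephsp",
            category="health education",
            item="health knowledge lectures",
            workers_per_case=2,
            minutes_per_case=12,
            annual_cases=100,
        ),
        ec.WorkloadRecord(
            institution_id="A1",
            service_class="primary_medical",
            category="clinical medical services",
            item="consultation",
            workers_per_case=1,
            minutes_per_case=15,
            annual_cases=240,
        ),
        # A2: nephsp 2.0*50 = 100 eq; primary 0.5*200 = 100 eq
        ec.WorkloadRecord(
            institution_id="A2",
            service_class="nephsp",
            category="elderly health management",
            item="annual elderly health examination",
            workers_per_case=3,
            minutes_per_case=10,
            annual_cases=50,
        ),
        ec.WorkloadRecord(
            institution_id="A2",
            service_class="primary_medical",
            category="nursing services",
            item="dressing change",
            workers_per_case=1,
            minutes_per_case=7.5,
            annual_cases=200,
        ),
    ]
    finances = [
        ec.FinanceRecord(
            institution_id="A1",
            operational_cost=Decimal("4000.00"),  # 10 CNY per equivalent
            nephsp_revenue=Decimal("1000.00"),
            nephsp_expenditure=Decimal("1100.00"),
            total_operating_revenue=Decimal("5000.00"),
            total_operating_expenditure=Decimal("5200.00"),
        ),
        ec.FinanceRecord(
            institution_id="A2",
            operational_cost=Decimal("1000.00"),  # 5 CNY per equivalent
            nephsp_revenue=Decimal("400.00"),
            nephsp_expenditure=Decimal("450.00"),
            total_operating_revenue=Decimal("2000.00"),
            total_operating_expenditure=Decimal("2100.00"),
        ),
    ]
    kwargs = dict(
        institutions=institutions,
        workloads=workloads,
        finances=finances,
        reference_year=2020,
        per_capita_allocated_subsidy=Decimal("74"),
    )
    kwargs.update(overrides)
    return ec.StudyDataset(**kwargs)


@pytest.fixture()
def tiny_dataset() -> ec.StudyDataset:
    return build_tiny_dataset()
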