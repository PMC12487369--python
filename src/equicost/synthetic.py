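"""Seeded generator of complete synthetic costing studies.

The real survey microdata behind studies of this kind are rarely releasable,
so this module emulates the study design itself: a multi-stage stratified
sample (regions × counties × townships, one health center per township), a
fixed service catalogue, workload records drawn per catalogue item, and
finance records constructed from a known true cost per equivalent.  The
ground truth is recorded alongside the dataset but never consumed by the
estimation pipeline — it exists so tests can check parameter recovery.

Also here: ``fixture_from_tables`` rebuilds the five regional aggregates of
the source study's published tables as pseudo-institutions, so every printed
derived quantity can be recomputed without any external data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .catalogue import NEPHSP, PRIMARY_MEDICAL, CatalogueSpec, default_catalogue
from .data import (
    FinanceRecord,
    Institution,
    StudyDataset,
    WorkloadRecord,
    parse_currency,
)
from .equivalents import STANDARD_MINUTES, unit_equivalent

DEFAULT_REGIONS = ("Eastern", "Southern", "Western", "Northern", "Central")

# Median registered residents per institution, loosely calibrated to the
# study's regional pattern (largest in the east, smallest in the west).
DEFAULT_RESIDENT_MEDIANS = {
    "Eastern": 55_000,
    "Southern": 30_000,
    "Western": 17_000,
    "Northern": 25_000,
    "Central": 25_000,
}

# Relative programme workload by category (share-of-programme weights).
# Whole-population services (health education, elderly management, resident
# health records) dominate; clinical-niche services are small.
DEFAULT_CATEGORY_WEIGHTS = {
    "health education": 26.5,
    "elderly health management": 26.3,
    "establishment of resident health records": 25.5,
    "preventive inoculation": 6.2,
    "chronic disease management (hypertension)": 6.1,
    "traditional Chinese medicine health management": 3.0,
    "children health management": 2.8,
    "chronic disease management (type 2 diabetes)": 1.4,
    "maternal health management": 1.3,
    "severe mental disorder management": 0.35,
    "supervision and co-management of health and family planning": 0.32,
    "tuberculosis patient management": 0.13,
    "reporting and management of infectious diseases and public health emergencies": 0.10,
}
DEMOGRAPHIC_CATEGORIES = {
    "elderly health management": ("elderly_fraction", 0.20),
    "chronic disease management (hypertension)": ("hypertension_prevalence", 0.18),
}
PRIMARY_CATEGORY_WEIGHTS = {
    "clinical medical services": 0.45,
    "nursing services": 0.20,
    "medical technology services": 0.15,
    "pharmaceutical services": 0.10,
    "public health support services": 0.10,
}


class GeneratorConfig(BaseModel):
    """Study-design and distributional knobs for :func:`generate_study`."""

    seed: int = 20200101
    n_regions: int = Field(default=5, ge=1)
    counties_per_region: int = Field(default=2, ge=1)
    townships_per_county: int = Field(default=5, ge=1)
    region_names: tuple[str, ...] | None = None

    resident_dispersion: float = Field(default=0.45, gt=0)  # log-normal sigma
    resident_medians: dict[str, float] | None = None
    staff_per_1000_mean: float = Field(default=1.30, gt=0)
    staff_per_1000_sd: float = Field(default=0.35, ge=0)

    nephsp_equivalents_per_resident: float = Field(default=6.2, gt=0)
    nephsp_share_mean: float = Field(default=38.0, gt=0, lt=100)
    nephsp_share_sd: float = Field(default=6.0, ge=0)
    elderly_fraction: float = Field(default=0.20, gt=0, lt=1)
    hypertension_prevalence: float = Field(default=0.18, gt=0, lt=1)

    true_cost_mean: float = Field(default=18.0, gt=0)   # CNY per equivalent
    true_cost_region_sd: float = Field(default=4.0, ge=0)
    true_cost_within_sd: float = Field(default=2.0, ge=0)

    revenue_rate: float = Field(default=74.0, gt=0)      # CNY per person
    revenue_lag_factor: float = Field(default=1.10, gt=0)
    carryover_mean: float = Field(default=0.04, ge=0)
    carryover_sd: float = Field(default=0.05, ge=0)
    noise_sd: float = Field(default=0.05, ge=0)          # relative, on cost

    standard_minutes: float = Field(default=STANDARD_MINUTES, gt=0)
    reference_year: int = 2020

    @model_validator(mode="after")
    def _region_names_cover(self):
        if self.region_names is not None and len(self.region_names) < self.n_regions:
            raise ValueError("region_names shorter than n_regions")
        return self

    def regions(self) -> list[str]:
        names = self.region_names or DEFAULT_REGIONS
        if self.n_regions <= len(names):
            return list(names[: self.n_regions])
        extra = [f"Region{i}" for i in range(len(names) + 1, self.n_regions + 1)]
        return list(names) + extra


@dataclass
class GroundTruth:
    """Per-institution generating values; consumed only by tests."""

    true_cost_per_equivalent: dict[str, float] = field(default_factory=dict)
    true_nephsp_share: dict[str, float] = field(default_factory=dict)
    target_nephsp_share: dict[str, float] = field(default_factory=dict)
    allocation_population: dict[str, int] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "institution_id": list(self.true_cost_per_equivalent),
                "true_cost_per_equivalent": list(self.true_cost_per_equivalent.values()),
                "true_nephsp_share": list(self.true_nephsp_share.values()),
                "target_nephsp_share": list(self.target_nephsp_share.values()),
                "allocation_population": list(self.allocation_population.values()),
            }
        )


def _category_weights(config: GeneratorConfig, catalogue: CatalogueSpec) -> dict[str, float]:
    weights = {}
    for name in catalogue.category_names(NEPHSP):
        w = DEFAULT_CATEGORY_WEIGHTS.get(name, 1.0)
        if name in DEMOGRAPHIC_CATEGORIES:
            attr, default_frac = DEMOGRAPHIC_CATEGORIES[name]
            w *= getattr(config, attr) / default_frac
        weights[name] = w
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def _draw_item_profile(rng: np.random.Generator) -> tuple[int, float]:
    workers = int(rng.choice([1, 2, 3], p=[0.55, 0.33, 0.12]))
    minutes = float(np.round(rng.uniform(2.0, 60.0), 1))
    return workers, minutes


def generate_study(config: GeneratorConfig) -> tuple[StudyDataset, GroundTruth]:
    """Draw one full synthetic study; deterministic for a fixed config+seed."""
    rng = np.random.default_rng(config.seed)
    catalogue = default_catalogue()
    cat_weights = _category_weights(config, catalogue)
    nephsp_items = {
        c.name: list(c.items) for c in catalogue.categories(NEPHSP)
    }
    primary_items = {
        c.name: list(c.items) for c in catalogue.categories(PRIMARY_MEDICAL)
    }
    primary_weights = {
        name: PRIMARY_CATEGORY_WEIGHTS.get(name, 0.1) for name in primary_items
    }
    pw_total = sum(primary_weights.values())
    primary_weights = {k: v / pw_total for k, v in primary_weights.items()}

    institutions: list[Institution] = []
    workloads: list[WorkloadRecord] = []
    finances: list[FinanceRecord] = []
    truth = GroundTruth()

    regions = config.regions()
    medians = dict(DEFAULT_RESIDENT_MEDIANS)
    if config.resident_medians:
        medians.update(config.resident_medians)

    for r_idx, region in enumerate(regions):
        region_cost = max(
            5.0, rng.normal(config.true_cost_mean, config.true_cost_region_sd)
        )
        median = medians.get(region, 30_000)
        for c_idx in range(config.counties_per_region):
            county = f"{region} county {c_idx + 1}"
            for t_idx in range(config.townships_per_county):
                township = f"{county} township {t_idx + 1}"
                inst_id = f"THC-{r_idx + 1}{c_idx + 1}{t_idx + 1:02d}"
                residents = int(
                    round(
                        math.exp(
                            rng.normal(math.log(median), config.resident_dispersion)
                        )
                    )
                )
                residents = max(residents, 500)
                staff = max(
                    2,
                    int(
                        round(
                            residents
                            / 1000.0
                            * max(
                                0.2,
                                rng.normal(
                                    config.staff_per_1000_mean, config.staff_per_1000_sd
                                ),
                            )
                        )
                    ),
                )
                institutions.append(
                    Institution(
                        institution_id=inst_id,
                        region=region,
                        county=county,
                        township=township,
                        registered_residents=residents,
                        health_professionals=staff,
                    )
                )

                inst_workloads, eq_nephsp = _draw_nephsp_workloads(
                    rng, config, inst_id, residents, cat_weights, nephsp_items
                )
                share_target = float(
                    np.clip(
                        rng.normal(config.nephsp_share_mean, config.nephsp_share_sd),
                        5.0,
                        95.0,
                    )
                )
                primary_workloads, eq_primary = _draw_primary_workloads(
                    rng, config, inst_id, eq_nephsp, share_target,
                    primary_weights, primary_items,
                )
                workloads.extend(inst_workloads + primary_workloads)

                eq_all = eq_nephsp + eq_primary
                true_cost = max(
                    5.0, region_cost + rng.normal(0.0, config.true_cost_within_sd)
                )
                noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                operational_cost = parse_currency(
                    max(0.0, true_cost * eq_all * (1.0 + noise))
                )
                alloc_pop = int(round(residents * config.revenue_lag_factor))
                revenue = parse_currency(config.revenue_rate * alloc_pop)
                carry = (
                    abs(rng.normal(config.carryover_mean, config.carryover_sd))
                    if config.carryover_sd > 0
                    else config.carryover_mean
                )
                expenditure = parse_currency(float(revenue) * (1.0 + carry))
                rev_share = float(np.clip(rng.normal(0.18, 0.04), 0.05, 0.90))
                exp_share = float(np.clip(rng.normal(0.20, 0.04), 0.05, 0.90))
                finances.append(
                    FinanceRecord(
                        institution_id=inst_id,
                        operational_cost=operational_cost,
                        nephsp_revenue=revenue,
                        nephsp_expenditure=expenditure,
                        total_operating_revenue=parse_currency(float(revenue) / rev_share),
                        total_operating_expenditure=parse_currency(
                            float(expenditure) / exp_share
                        ),
                    )
                )
                truth.true_cost_per_equivalent[inst_id] = true_cost
                truth.true_nephsp_share[inst_id] = (
                    100.0 * eq_nephsp / eq_all if eq_all > 0 else math.nan
                )
                truth.target_nephsp_share[inst_id] = share_target
                truth.allocation_population[inst_id] = alloc_pop

    dataset = StudyDataset(
        institutions=institutions,
        workloads=workloads,
        finances=finances,
        reference_year=config.reference_year,
        per_capita_allocated_subsidy=parse_currency(config.revenue_rate),
    )
    return dataset, truth


def _draw_nephsp_workloads(rng, config, inst_id, residents, cat_weights, items_by_cat):
    records: list[WorkloadRecord] = []
    eq_total = 0.0
    total_eq_target = config.nephsp_equivalents_per_resident * residents
    for category, items in items_by_cat.items():
        cat_target = (
            total_eq_target
            * cat_weights[category]
            * math.exp(rng.normal(0.0, 0.15))
        )
        item_split = rng.dirichlet(np.full(len(items), 2.0))
        for item, frac in zip(items, item_split):
            workers, minutes = _draw_item_profile(rng)
            ue = unit_equivalent(workers, minutes, config.standard_minutes)
            cases = int(round(cat_target * frac / ue))
            records.append(
                WorkloadRecord(
                    institution_id=inst_id,
                    service_class=NEPHSP,
                    category=category,
                    item=item,
                    workers_per_case=workers,
                    minutes_per_case=minutes,
                    annual_cases=cases,
                )
            )
            eq_total += ue * cases
    return records, eq_total


def _draw_primary_workloads(
    rng, config, inst_id, eq_nephsp, share_target, primary_weights, items_by_cat
):
    records: list[WorkloadRecord] = []
    eq_total = 0.0
    target = eq_nephsp * (100.0 - share_target) / share_target
    for category, items in items_by_cat.items():
        cat_target = target * primary_weights[category]
        item_split = rng.dirichlet(np.full(len(items), 2.0))
        for item, frac in zip(items, item_split):
            workers, minutes = _draw_item_profile(rng)
            ue = unit_equivalent(workers, minutes, config.standard_minutes)
            cases = int(round(cat_target * frac / ue))
            records.append(
                WorkloadRecord(
                    institution_id=inst_id,
                    service_class=PRIMARY_MEDICAL,
                    category=category,
                    item=item,
                    workers_per_case=workers,
                    minutes_per_case=minutes,
                    annual_cases=cases,
                )
            )
            eq_total += ue * cases
    return records, eq_total


# ---------------------------------------------------------------------------
# Published regional aggregates as a ready-made dataset
# ---------------------------------------------------------------------------

def regional_reference_table() -> pd.DataFrame:
    """The packaged regional-aggregate table (one row per economic zone)."""
    with resources.files("equicost.fixtures").joinpath("regional_totals.csv").open() as fh:
        return pd.read_csv(fh)


def fixture_from_tables() -> StudyDataset:
    """The published regional totals as five pseudo-institutions.

    Each economic zone's aggregates (residents, staffing, finance and
    equivalent totals over its 10 health centers) become one synthetic
    pseudo-institution whose two workload records reproduce the zone's
    all-activity and programme equivalent totals exactly.  Every derived
    quantity in the published tables can then be recomputed by the ordinary
    pipeline at ``group_by="region"`` (regional columns) or ``"total"``.
    """
    table = regional_reference_table()
    institutions, workloads, finances = [], [], []
    for _, row in table.iterrows():
        inst_id = f"AGG-{row['region']}"
        label = f"{row['region']} (aggregate)"
        institutions.append(
            Institution(
                institution_id=inst_id,
                region=row["region"],
                county=label,
                township=label,
                registered_residents=int(row["registered_residents"]),
                health_professionals=int(row["health_professionals"]),
            )
        )
        eq_nephsp = float(row["equivalents_nephsp"])
        eq_primary = float(row["equivalents_all"]) - eq_nephsp
        # one case at (1 worker, 15·eq minutes) carries an exact fractional
        # equivalent total through integer-valued annual_cases
        workloads.append(
            WorkloadRecord(
                institution_id=inst_id,
                service_class=NEPHSP,
                category="programme aggregate",
                item="programme aggregate",
                workers_per_case=1.0,
                minutes_per_case=STANDARD_MINUTES * eq_nephsp,
                annual_cases=1,
            )
        )
        workloads.append(
            WorkloadRecord(
                institution_id=inst_id,
                service_class=PRIMARY_MEDICAL,
                category="primary-medical aggregate",
                item="primary-medical aggregate",
                workers_per_case=1.0,
                minutes_per_case=STANDARD_MINUTES * eq_primary,
                annual_cases=1,
            )
        )
        revenue = parse_currency(row["nephsp_revenue"])
        expenditure = parse_currency(row["nephsp_expenditure"])
        finances.append(
            FinanceRecord(
                institution_id=inst_id,
                operational_cost=parse_currency(row["operational_cost"]),
                nephsp_revenue=revenue,
                nephsp_expenditure=expenditure,
                total_operating_revenue=parse_currency(
                    float(revenue) / (float(row["revenue_share_pct"]) / 100.0)
                ),
                total_operating_expenditure=parse_currency(
                    float(expenditure) / (float(row["expenditure_share_pct"]) / 100.0)
                ),
            )
        )
    return StudyDataset(
        institutions=institutions,
        workloads=workloads,
        finances=finances,
        reference_year=2020,
        per_capita_allocated_subsidy=Decimal("74"),
    )


def category_share_summaries():
    """The published per-category programme-share summaries (n, mean %, SD)
    across the five zones, as :class:`~equicost.stats.GroupSummary` rows."""
    from .stats import GroupSummary

    with resources.files("equicost.fixtures").joinpath(
        "category_share_summary.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return [
        GroupSummary(r.label, int(r.n), float(r.mean), float(r.sd))
        for r in df.itertuples()
    ]
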