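"""Cost allocation by the equivalent method, and the funding-gap arithmetic.

Once all operational activity is expressed in standard service equivalents,
the cost of one equivalent is the institution's (or region's) total
operational-activity cost divided by its total equivalent value, and the
programme's estimated cost is that factor times the programme's equivalent
total.  Group-level costing always divides the group's summed cost by the
group's summed equivalents, never averages of institution-level ratios.

Published cost tables round the cost-per-equivalent factor to the cent before
multiplying it back out, so the default ("paper") rounding mode does the
same; the unrounded chain is available via ``rounding="unrounded"``.  The
induced conservation error is bounded by half a cent per equivalent.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .data import EquicostError, StudyDataset
from .equivalents import (
    STANDARD_MINUTES,
    TOTAL_LABEL,
    EquivalentSummary,
    _scope_column,
    summarize_equivalents,
)

logger = logging.getLogger(__name__)

TWO_DP = Decimal("0.01")

ROUNDING_MODES = ("paper", "unrounded")


def _dec(x: float | Decimal) -> Decimal:
    return x if isinstance(x, Decimal) else Decimal(repr(x))


def _q2(x: Decimal) -> Decimal:
    return x.quantize(TWO_DP, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class CostFactor:
    """Cost of one standard service equivalent: 2-dp reporting value plus the
    unrounded ratio it was derived from."""

    rounded: Decimal
    unrounded: float

    def value(self, rounding: str = "paper") -> Decimal | float:
        return self.rounded if rounding == "paper" else self.unrounded


def cost_per_equivalent(
    operational_cost: Decimal | float, total_equivalents_all: float, scope: str = ""
) -> CostFactor:
    """Operational-activity cost divided by total equivalent value."""
    if total_equivalents_all <= 0:
        raise EquicostError(
            f"cost_per_equivalent undefined for scope {scope!r}: zero total equivalents"
        )
    ratio = _dec(operational_cost) / _dec(total_equivalents_all)
    return CostFactor(rounded=_q2(ratio), unrounded=float(ratio))


def estimated_nephsp_cost(
    cost_factor: Decimal | float, total_equivalents_nephsp: float
) -> Decimal:
    """Programme cost allocated as cost-per-equivalent × programme equivalents.

    Pass the 2-dp factor for the published convention, or the unrounded ratio
    for the exact proportional allocation.
    """
    if total_equivalents_nephsp < 0:
        raise EquicostError("programme equivalents must be non-negative")
    return _q2(_dec(cost_factor) * _dec(total_equivalents_nephsp))


def per_capita(amount: Decimal | float, population: int | float) -> Decimal:
    """Amount divided by population, reported to 2 dp (CNY per person)."""
    if population <= 0:
        raise EquicostError("per-capita measure undefined for non-positive population")
    return _q2(_dec(amount) / _dec(population))


@dataclass(frozen=True)
class CostEstimate:
    """The full cost-estimation chain for one aggregation scope."""

    scope: str
    level: str
    registered_residents: int
    operational_cost: Decimal
    total_equivalents_all: float
    total_equivalents_nephsp: float
    nephsp_share_pct: float | None
    cost_per_equivalent: Decimal       # 2-dp reporting value
    cost_per_equivalent_unrounded: float
    estimated_nephsp_cost: Decimal
    per_capita_estimated_cost: Decimal
    per_capita_actual_subsidy: Decimal
    per_capita_actual_expenditure: Decimal
    per_capita_allocated_subsidy: Decimal


def _group_finance(dataset: StudyDataset, group_by: str) -> pd.DataFrame:
    inst = dataset.institutions_frame()
    fin = pd.DataFrame(
        {
            "institution_id": f.institution_id,
            "operational_cost": f.operational_cost,
            "nephsp_revenue": f.nephsp_revenue,
            "nephsp_expenditure": f.nephsp_expenditure,
        }
        for f in dataset.finances
    )
    df = inst.merge(fin, on="institution_id", validate="one_to_one")
    col = _scope_column(group_by) if group_by != "total" else None
    df["__scope__"] = df[col].astype(str) if col else TOTAL_LABEL
    agg = df.groupby("__scope__", sort=True).agg(
        registered_residents=("registered_residents", "sum"),
        operational_cost=("operational_cost", "sum"),
        nephsp_revenue=("nephsp_revenue", "sum"),
        nephsp_expenditure=("nephsp_expenditure", "sum"),
    )
    return agg


def cost_pipeline(
    dataset: StudyDataset,
    group_by: str = "region",
    *,
    rounding: str = "paper",
    standard_minutes: float = STANDARD_MINUTES,
) -> list[CostEstimate]:
    """Run the whole estimation chain per group plus the grand total.

    Groups whose preconditions fail (no workload, zero population) are logged
    and skipped rather than silently dropped.
    """
    estimates, skipped = cost_pipeline_detailed(
        dataset, group_by, rounding=rounding, standard_minutes=standard_minutes
    )
    for scope, reason in skipped:
        logger.warning("skipped scope %r: %s", scope, reason)
    return estimates


def cost_pipeline_detailed(
    dataset: StudyDataset,
    group_by: str = "region",
    *,
    rounding: str = "paper",
    standard_minutes: float = STANDARD_MINUTES,
) -> tuple[list[CostEstimate], list[tuple[str, str]]]:
    """As :func:`cost_pipeline`, also returning (scope, reason) skip records."""
    if rounding not in ROUNDING_MODES:
        raise EquicostError(f"unknown rounding mode {rounding!r}; expected {ROUNDING_MODES}")
    summaries = {s.scope: s for s in summarize_equivalents(dataset, group_by, standard_minutes)}
    finance = _group_finance(dataset, group_by)
    if group_by != "total":
        # grand-total finance row to pair with the grand-total summary
        finance.loc[TOTAL_LABEL] = _group_finance(dataset, "total").loc[TOTAL_LABEL]

    estimates: list[CostEstimate] = []
    skipped: list[tuple[str, str]] = []
    for scope in finance.index:
        if scope not in summaries:
            skipped.append((str(scope), "no workload records for scope"))
    for scope, summary in summaries.items():
        if scope not in finance.index:
            skipped.append((scope, "no finance/roster rows for scope"))
            continue
        row = finance.loc[scope]
        try:
            est = _estimate_scope(dataset, scope, summary, row, rounding)
        except EquicostError as exc:
            skipped.append((scope, str(exc)))
            continue
        estimates.append(est)
    return estimates, skipped


def _estimate_scope(
    dataset: StudyDataset,
    scope: str,
    summary: EquivalentSummary,
    finance_row: pd.Series,
    rounding: str,
) -> CostEstimate:
    factor = cost_per_equivalent(
        finance_row["operational_cost"], summary.total_equivalents_all, scope
    )
    allocated = estimated_nephsp_cost(
        factor.value(rounding), summary.total_equivalents_nephsp
    )
    residents = int(finance_row["registered_residents"])
    return CostEstimate(
        scope=scope,
        level=summary.level,
        registered_residents=residents,
        operational_cost=_q2(_dec(finance_row["operational_cost"])),
        total_equivalents_all=summary.total_equivalents_all,
        total_equivalents_nephsp=summary.total_equivalents_nephsp,
        nephsp_share_pct=summary.nephsp_share,
        cost_per_equivalent=factor.rounded,
        cost_per_equivalent_unrounded=factor.unrounded,
        estimated_nephsp_cost=allocated,
        per_capita_estimated_cost=per_capita(allocated, residents),
        per_capita_actual_subsidy=per_capita(finance_row["nephsp_revenue"], residents),
        per_capita_actual_expenditure=per_capita(
            finance_row["nephsp_expenditure"], residents
        ),
        per_capita_allocated_subsidy=dataset.per_capita_allocated_subsidy,
    )


def estimates_frame(estimates: list[CostEstimate]) -> pd.DataFrame:
    from .equivalents import round2

    return pd.DataFrame(
        {
            "scope": e.scope,
            "level": e.level,
            "registered_residents": e.registered_residents,
            "operational_cost": e.operational_cost,
            "total_equivalents_all": round2(e.total_equivalents_all),
            "total_equivalents_nephsp": round2(e.total_equivalents_nephsp),
            "nephsp_share_pct": None if e.nephsp_share_pct is None else round2(e.nephsp_share_pct),
            "cost_per_equivalent": e.cost_per_equivalent,
            "estimated_nephsp_cost": e.estimated_nephsp_cost,
            "per_capita_estimated_cost": e.per_capita_estimated_cost,
            "per_capita_actual_subsidy": e.per_capita_actual_subsidy,
            "per_capita_actual_expenditure": e.per_capita_actual_expenditure,
            "per_capita_allocated_subsidy": e.per_capita_allocated_subsidy,
        }
        for e in estimates
    )


# ---------------------------------------------------------------------------
# Funding-lag / break-even analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FundingGapReport:
    """Break-even population implied by realised programme revenue.

    Subsidy allocations are computed from population figures two years old;
    if the allocation-basis population exceeded ``break_even_population``
    (= realised revenue / per-capita rate), the institutions received less
    than the rate times that population — a funding shortfall.
    """

    scope: str
    actual_revenue: Decimal
    per_capita_rate: Decimal
    break_even_population: float
    current_population: int
    reference_population: float
    implied_gap_flag: bool


def break_even_population(
    actual_revenue: Decimal | float, per_capita_rate: Decimal | float
) -> float:
    """Population at which revenue exactly covers the per-capita rate."""
    rate = _dec(per_capita_rate)
    if rate <= 0:
        raise EquicostError("per-capita rate must be positive")
    return float(_dec(actual_revenue) / rate)


def funding_gap_report(
    dataset: StudyDataset, reference_population: float, scope: str = TOTAL_LABEL
) -> FundingGapReport:
    """Flag a shortfall when the allocation-basis population exceeds the
    break-even population implied by realised revenue."""
    if reference_population <= 0:
        raise EquicostError("reference population must be positive")
    revenue = _q2(sum((f.nephsp_revenue for f in dataset.finances), Decimal("0")))
    rate = dataset.per_capita_allocated_subsidy
    be = break_even_population(revenue, rate)
    current = sum(i.registered_residents for i in dataset.institutions)
    return FundingGapReport(
        scope=scope,
        actual_revenue=revenue,
        per_capita_rate=rate,
        break_even_population=be,
        current_population=current,
        reference_population=float(reference_population),
        implied_gap_flag=not math.isclose(reference_population, be, rel_tol=0, abs_tol=1e-9)
        and reference_population > be,
    )
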