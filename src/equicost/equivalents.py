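"""Standard-service-equivalent arithmetic.

The equivalent method standardises heterogeneous service workloads into a
single unit before costs are allocated: one *standard service equivalent* is
the workload of one health worker delivering one 15-minute consultation.  A
service needing ``w`` workers for ``m`` minutes per delivery therefore costs
``w × m / 15`` equivalents per case, and its annual workload is that times the
annual number of cases.  Totals are additive over items, institutions and
regions, which is what lets institution-level survey data roll up to the
regional tables.

Values are kept at full precision internally; printed tables round to 2 dp,
so rounding happens only at the reporting edge (after summation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .catalogue import NEPHSP
from .data import EquicostError, StudyDataset, WorkloadRecord

STANDARD_MINUTES = 15.0

AGGREGATION_LEVELS = ("institution", "county", "region", "total")
TOTAL_LABEL = "Total"


def round2(x: float) -> float:
    """Round half away from zero to 2 dp (currency/table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def unit_equivalent(
    workers_per_case: float,
    minutes_per_case: float,
    standard_minutes: float = STANDARD_MINUTES,
) -> float:
    """Equivalents needed for one delivery: person-minutes over the standard.

    E.g. two workers collaborating for 12 minutes is 24 person-minutes, i.e.
    1.6 equivalents against the 15-person-minute standard.  Symmetric in
    workers and minutes: only their product (person-minutes) matters.
    """
    if workers_per_case <= 0 or minutes_per_case <= 0 or standard_minutes <= 0:
        raise EquicostError(
            "unit_equivalent requires positive workers, minutes and standard"
        )
    return workers_per_case * minutes_per_case / standard_minutes


def service_total_equivalent(
    record: WorkloadRecord, standard_minutes: float = STANDARD_MINUTES
) -> float:
    """Annual equivalents contributed by one workload record."""
    return (
        unit_equivalent(record.workers_per_case, record.minutes_per_case, standard_minutes)
        * record.annual_cases
    )


@dataclass(frozen=True)
class EquivalentSummary:
    """Equivalent-value totals for one aggregation scope."""

    scope: str
    level: str
    total_equivalents_all: float
    total_equivalents_nephsp: float

    @property
    def nephsp_share(self) -> float | None:
        """Programme share of all operational workload, percent (unrounded);
        None when the scope has no workload at all."""
        if self.total_equivalents_all == 0:
            return None
        return 100.0 * self.total_equivalents_nephsp / self.total_equivalents_all

    @property
    def nephsp_share_2dp(self) -> float | None:
        s = self.nephsp_share
        return None if s is None else round2(s)


@dataclass(frozen=True)
class CategoryShare:
    """One programme category's workload within an aggregation scope."""

    scope: str
    category: str
    total_equivalents: float
    share_of_nephsp: float | None  # percent of the scope's programme total
    unit_equivalent: float | None  # workload-weighted mean equivalents/case


def _equivalents_frame(dataset: StudyDataset, standard_minutes: float) -> pd.DataFrame:
    """Per-record equivalents joined with the institution roster."""
    work = dataset.workloads_frame()
    if work.empty:
        raise EquicostError("dataset has no workload records")
    work["unit_equivalent"] = (
        work["workers_per_case"] * work["minutes_per_case"] / standard_minutes
    )
    work["total_equivalent"] = work["unit_equivalent"] * work["annual_cases"]
    inst = dataset.institutions_frame()[["institution_id", "region", "county"]]
    return work.merge(inst, on="institution_id", validate="many_to_one")


def _scope_column(level: str) -> str:
    if level not in AGGREGATION_LEVELS:
        raise EquicostError(
            f"unknown aggregation level {level!r}; expected one of {AGGREGATION_LEVELS}"
        )
    return {"institution": "institution_id", "county": "county", "region": "region"}.get(
        level, "__total__"
    )


def summarize_equivalents(
    dataset: StudyDataset,
    group_by: str = "region",
    standard_minutes: float = STANDARD_MINUTES,
) -> list[EquivalentSummary]:
    """Total and programme equivalent values per group, plus a grand total.

    The all-activities total covers both service classes; the programme total
    only the essential-public-health class.  The grand-total row (scope
    ``Total``) is always last and equals the exact sum of the group rows.
    """
    df = _equivalents_frame(dataset, standard_minutes)

    def _summary(scope: str, level: str, sub: pd.DataFrame) -> EquivalentSummary:
        return EquivalentSummary(
            scope=scope,
            level=level,
            total_equivalents_all=float(math.fsum(sub["total_equivalent"])),
            total_equivalents_nephsp=float(
                math.fsum(sub.loc[sub["service_class"] == NEPHSP, "total_equivalent"])
            ),
        )

    out: list[EquivalentSummary] = []
    if group_by != "total":
        col = _scope_column(group_by)
        for scope, sub in df.groupby(col, sort=True):
            out.append(_summary(str(scope), group_by, sub))
    out.append(_summary(TOTAL_LABEL, "total", df))
    return out


def category_shares(
    dataset: StudyDataset,
    scope: str = "total",
    standard_minutes: float = STANDARD_MINUTES,
) -> list[CategoryShare]:
    """Per-category programme workload within each group of an aggregation.

    ``share_of_nephsp`` normalises by the group's programme total (shares over
    all categories sum to 100); ``unit_equivalent`` is the workload-weighted
    mean equivalents per case over the category's items in the group
    (Σ unit_eq × cases / Σ cases), or None when no cases were delivered.
    """
    df = _equivalents_frame(dataset, standard_minutes)
    df = df[df["service_class"] == NEPHSP]
    if df.empty:
        raise EquicostError("dataset has no programme workload records")
    out: list[CategoryShare] = []
    if scope == "total":
        groups = [(TOTAL_LABEL, df)]
    else:
        col = _scope_column(scope)
        groups = [(str(k), sub) for k, sub in df.groupby(col, sort=True)]
    for label, sub in groups:
        denom = float(math.fsum(sub["total_equivalent"]))
        for category, cat in sub.groupby("category", sort=True):
            total = float(math.fsum(cat["total_equivalent"]))
            cases = float(cat["annual_cases"].sum())
            out.append(
                CategoryShare(
                    scope=label,
                    category=str(category),
                    total_equivalents=total,
                    share_of_nephsp=(100.0 * total / denom) if denom > 0 else None,
                    unit_equivalent=(total / cases) if cases > 0 else None,
                )
            )
    return out


def summaries_frame(summaries: list[EquivalentSummary]) -> pd.DataFrame:
    """Tabular view of summaries with 2-dp reporting columns."""
    return pd.DataFrame(
        {
            "scope": s.scope,
            "level": s.level,
            "total_equivalents_all": round2(s.total_equivalents_all),
            "total_equivalents_nephsp": round2(s.total_equivalents_nephsp),
            "nephsp_share_pct": s.nephsp_share_2dp,
        }
        for s in summaries
    )
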