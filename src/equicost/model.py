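"""Model/Results front end over the costing pipeline.

``EquivalentCostModel`` is constructed from a validated study dataset (or the
three CSV tables) and ``fit()`` runs the full equivalent-method chain at a
chosen aggregation level, returning a ``CostResults`` object that carries the
per-scope estimates, the skipped scopes with reasons, and convenience
accessors for the downstream analyses (category shares, funding gap,
correlation families) plus a printable ``summary()``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

import pandas as pd

from .costing import (
    CostEstimate,
    FundingGapReport,
    cost_pipeline_detailed,
    estimates_frame,
    funding_gap_report,
)
from .data import EquicostError, StudyDataset, load_dataset
from .equivalents import (
    STANDARD_MINUTES,
    CategoryShare,
    category_shares,
    round2,
)


class EquivalentCostModel:
    """Equivalent-method cost model for a primary-care service study."""

    def __init__(self, dataset: StudyDataset, *, standard_minutes: float = STANDARD_MINUTES):
        self.dataset = dataset
        self.standard_minutes = standard_minutes

    @classmethod
    def from_csv(
        cls,
        institutions_path: str | Path,
        workloads_path: str | Path,
        finances_path: str | Path,
        *,
        per_capita_allocated_subsidy: float | str | Decimal = Decimal("74"),
        reference_year: int = 2020,
        standard_minutes: float = STANDARD_MINUTES,
    ) -> "EquivalentCostModel":
        dataset = load_dataset(
            institutions_path,
            workloads_path,
            finances_path,
            reference_year=reference_year,
            per_capita_allocated_subsidy=per_capita_allocated_subsidy,
        )
        return cls(dataset, standard_minutes=standard_minutes)

    def fit(self, group_by: str = "region", *, rounding: str = "paper") -> "CostResults":
        estimates, skipped = cost_pipeline_detailed(
            self.dataset,
            group_by,
            rounding=rounding,
            standard_minutes=self.standard_minutes,
        )
        if not estimates:
            raise EquicostError("no scope could be costed; all groups were skipped")
        return CostResults(
            model=self,
            group_by=group_by,
            rounding=rounding,
            estimates=estimates,
            skipped=skipped,
        )


@dataclass
class CostResults:
    """Fitted cost estimates at one aggregation level."""

    model: EquivalentCostModel
    group_by: str
    rounding: str
    estimates: list[CostEstimate]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def frame(self) -> pd.DataFrame:
        return estimates_frame(self.estimates).set_index("scope")

    @property
    def total(self) -> CostEstimate:
        for e in self.estimates:
            if e.level == "total":
                return e
        raise EquicostError("results carry no grand-total scope")

    def scope(self, name: str) -> CostEstimate:
        for e in self.estimates:
            if e.scope == name:
                return e
        raise KeyError(name)

    # -- downstream analyses -------------------------------------------------
    def category_shares(self, scope: str = "total") -> list[CategoryShare]:
        return category_shares(
            self.model.dataset, scope, standard_minutes=self.model.standard_minutes
        )

    def funding_gap(self, reference_population: float) -> FundingGapReport:
        return funding_gap_report(self.model.dataset, reference_population)

    def correlations(self, covariates=None):
        from .stats import correlation_suite

        return correlation_suite(self.model.dataset, covariates)

    # -- presentation --------------------------------------------------------
    def headline(self) -> dict[str, float | None]:
        """The study's headline metrics for the grand-total scope."""
        t = self.total
        return {
            "cost_per_equivalent": float(t.cost_per_equivalent),
            "nephsp_share_pct": None
            if t.nephsp_share_pct is None
            else round2(t.nephsp_share_pct),
            "estimated_nephsp_cost": float(t.estimated_nephsp_cost),
            "per_capita_estimated_cost": float(t.per_capita_estimated_cost),
            "per_capita_actual_subsidy": float(t.per_capita_actual_subsidy),
            "per_capita_actual_expenditure": float(t.per_capita_actual_expenditure),
            "per_capita_allocated_subsidy": float(t.per_capita_allocated_subsidy),
        }

    def summary(self) -> str:
        lines = [
            "Equivalent-method cost estimation",
            f"  aggregation: {self.group_by}   rounding: {self.rounding}   "
            f"standard: {self.model.standard_minutes:g} person-minutes",
            "",
            self.frame.to_string(),
        ]
        t = self.headline()
        lines += [
            "",
            "Headline (grand total):",
            f"  cost per standard service equivalent  CNY {t['cost_per_equivalent']:.2f}",
            f"  programme share of total workload     {t['nephsp_share_pct']:.2f} %"
            if t["nephsp_share_pct"] is not None
            else "  programme share of total workload     undefined",
            f"  per-capita actual subsidy             CNY {t['per_capita_actual_subsidy']:.2f}",
            f"  per-capita actual expenditure         CNY {t['per_capita_actual_expenditure']:.2f}",
            f"  per-capita allocated subsidy          CNY {t['per_capita_allocated_subsidy']:.2f}",
            f"  per-capita estimated cost             CNY {t['per_capita_estimated_cost']:.2f}",
        ]
        if self.skipped:
            lines.append("")
            lines.append("Skipped scopes:")
            lines += [f"  {s}: {r}" for s, r in self.skipped]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CostResults group_by={self.group_by!r} rounding={self.rounding!r} "
            f"n_scopes={len(self.estimates)}>"
        )
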