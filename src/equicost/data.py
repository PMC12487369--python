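"""Typed records, validation and delimited-text IO for a costing study.

A study is three tables keyed by institution:

* institution roster — region / county / township, registered residents served
  (the population denominator) and health-professional headcount;
* workload records — per service item, the staffing intensity (workers and
  minutes per delivery) and annual delivery count;
* finance records — total operational-activity cost and the public-health
  programme's revenue/expenditure against the institution's full accounts.

Currency amounts are held as exact 2-dp decimals (CNY fen) so that
conservation checks are free of binary-float drift; thousands separators are
tolerated on input and never emitted.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import pydantic
from pydantic import BaseModel, Field, field_validator, model_validator

from .catalogue import NEPHSP, PRIMARY_MEDICAL, CatalogueSpec

TWO_DP = Decimal("0.01")


class EquicostError(Exception):
    """Base class for all package errors."""


class DatasetValidationError(EquicostError):
    """A dataset violated a structural invariant; message names the culprit."""


def parse_currency(value: str | float | int | Decimal) -> Decimal:
    """Parse a currency amount, tolerating thousands separators, to 2 dp."""
    if isinstance(value, Decimal):
        return value.quantize(TWO_DP, rounding=ROUND_HALF_UP)
    if isinstance(value, str):
        value = value.replace(",", "").strip()
    try:
        return Decimal(str(value)).quantize(TWO_DP, rounding=ROUND_HALF_UP)
    except InvalidOperation as exc:
        raise DatasetValidationError(f"unparseable currency amount: {value!r}") from exc


class Institution(BaseModel):
    model_config = pydantic.ConfigDict(frozen=True)

    institution_id: str
    region: str
    county: str
    township: str
    registered_residents: int = Field(ge=0)
    health_professionals: int = Field(ge=0)


class WorkloadRecord(BaseModel):
    model_config = pydantic.ConfigDict(frozen=True)

    institution_id: str
    service_class: Literal["primary_medical", "nephsp"]
    category: str
    item: str
    workers_per_case: float = Field(gt=0)
    minutes_per_case: float = Field(gt=0)
    annual_cases: int = Field(ge=0)


class FinanceRecord(BaseModel):
    model_config = pydantic.ConfigDict(frozen=True)

    institution_id: str
    operational_cost: Decimal = Field(ge=0)
    nephsp_revenue: Decimal = Field(ge=0)
    nephsp_expenditure: Decimal = Field(ge=0)
    total_operating_revenue: Decimal | None = Field(default=None, ge=0)
    total_operating_expenditure: Decimal | None = Field(default=None, ge=0)

    @field_validator(
        "operational_cost",
        "nephsp_revenue",
        "nephsp_expenditure",
        "total_operating_revenue",
        "total_operating_expenditure",
        mode="before",
    )
    @classmethod
    def _coerce_currency(cls, v):
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        return parse_currency(v)

    @model_validator(mode="after")
    def _programme_within_accounts(self):
        if (
            self.total_operating_revenue is not None
            and self.nephsp_revenue > self.total_operating_revenue
        ):
            raise ValueError(
                f"{self.institution_id}: programme revenue exceeds total operating revenue"
            )
        if (
            self.total_operating_expenditure is not None
            and self.nephsp_expenditure > self.total_operating_expenditure
        ):
            raise ValueError(
                f"{self.institution_id}: programme expenditure exceeds total operating expenditure"
            )
        return self


INSTITUTION_COLUMNS = (
    "institution_id",
    "region",
    "county",
    "township",
    "registered_residents",
    "health_professionals",
)
WORKLOAD_COLUMNS = (
    "institution_id",
    "service_class",
    "category",
    "item",
    "workers_per_case",
    "minutes_per_case",
    "annual_cases",
)
FINANCE_COLUMNS = (
    "institution_id",
    "operational_cost",
    "nephsp_revenue",
    "nephsp_expenditure",
    "total_operating_revenue",
    "total_operating_expenditure",
)


@dataclass
class StudyDataset:
    """A validated study: roster, workloads, finances for one reference year."""

    institutions: list[Institution]
    workloads: list[WorkloadRecord]
    finances: list[FinanceRecord]
    reference_year: int = 2020
    per_capita_allocated_subsidy: Decimal = Decimal("74")

    def __post_init__(self):
        self.per_capita_allocated_subsidy = parse_currency(
            self.per_capita_allocated_subsidy
        )
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        ids = [i.institution_id for i in self.institutions]
        dup = {x for x in ids if ids.count(x) > 1}
        if dup:
            raise DatasetValidationError(
                f"duplicate institution_id(s): {sorted(dup)}"
            )
        known = set(ids)
        for w in self.workloads:
            if w.institution_id not in known:
                raise DatasetValidationError(
                    f"workload record references unknown institution {w.institution_id!r}"
                )
        keys = [
            (w.institution_id, w.service_class, w.category, w.item)
            for w in self.workloads
        ]
        if len(keys) != len(set(keys)):
            seen, dups = set(), set()
            for k in keys:
                (dups if k in seen else seen).add(k)
            raise DatasetValidationError(f"duplicate workload key(s): {sorted(dups)[:3]}")
        fin_ids = [f.institution_id for f in self.finances]
        for f in self.finances:
            if f.institution_id not in known:
                raise DatasetValidationError(
                    f"finance record references unknown institution {f.institution_id!r}"
                )
        missing = known - set(fin_ids)
        if missing:
            raise DatasetValidationError(
                f"institution(s) without a finance record: {sorted(missing)}"
            )
        if len(fin_ids) != len(set(fin_ids)):
            raise DatasetValidationError("an institution has more than one finance record")

    # -- frame views --------------------------------------------------------
    def institutions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([i.model_dump() for i in self.institutions])

    def workloads_frame(self) -> pd.DataFrame:
        return pd.DataFrame([w.model_dump() for w in self.workloads])

    def finances_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([f.model_dump() for f in self.finances])
        for c in FINANCE_COLUMNS[1:]:
            df[c] = df[c].map(lambda d: float(d) if d is not None else float("nan"))
        return df

    def finance_for(self, institution_id: str) -> FinanceRecord:
        for f in self.finances:
            if f.institution_id == institution_id:
                return f
        raise KeyError(institution_id)

    def institution(self, institution_id: str) -> Institution:
        for i in self.institutions:
            if i.institution_id == institution_id:
                return i
        raise KeyError(institution_id)


# ---------------------------------------------------------------------------
# Delimited-text readers/writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, expected: Sequence[str], required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DatasetValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in required if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing or unknown:
        raise DatasetValidationError(
            f"{path.name}: column mismatch (missing {missing}, unknown {unknown}); "
            f"expected schema {list(expected)}"
        )
    return df


def _build(model, row: pd.Series, path: Path, idx: int):
    try:
        return model(**{k: v for k, v in row.items() if not pd.isna(v)})
    except (pydantic.ValidationError, DatasetValidationError) as exc:
        raise DatasetValidationError(f"{path.name} row {idx + 2}: {exc}") from exc


def _strip_thousands(df: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
    for c in cols:
        if c in df.columns:
            df[c] = df[c].str.replace(",", "", regex=False)
    return df


def load_dataset(
    institutions_path: str | Path,
    workloads_path: str | Path,
    finances_path: str | Path,
    *,
    reference_year: int = 2020,
    per_capita_allocated_subsidy: Decimal | float | str = Decimal("74"),
) -> StudyDataset:
    """Load and validate the three study tables from CSV files.

    Numeric columns tolerate thousands separators. Any structural problem
    (missing file, schema mismatch, dangling reference, negative amount)
    raises :class:`DatasetValidationError` naming the offending file/row.
    """
    inst_df = _read_table(Path(institutions_path), INSTITUTION_COLUMNS, INSTITUTION_COLUMNS)
    work_df = _read_table(Path(workloads_path), WORKLOAD_COLUMNS, WORKLOAD_COLUMNS)
    fin_df = _read_table(Path(finances_path), FINANCE_COLUMNS, FINANCE_COLUMNS[:4])
    inst_df = _strip_thousands(inst_df, ("registered_residents", "health_professionals"))
    work_df = _strip_thousands(work_df, ("workers_per_case", "minutes_per_case", "annual_cases"))

    institutions = [
        _build(Institution, row, Path(institutions_path), i)
        for i, row in inst_df.iterrows()
    ]
    workloads = [
        _build(WorkloadRecord, row, Path(workloads_path), i)
        for i, row in work_df.iterrows()
    ]
    finances = [
        _build(FinanceRecord, row, Path(finances_path), i)
        for i, row in fin_df.iterrows()
    ]
    return StudyDataset(
        institutions=institutions,
        workloads=workloads,
        finances=finances,
        reference_year=reference_year,
        per_capita_allocated_subsidy=parse_currency(per_capita_allocated_subsidy),
    )


def write_dataset(dataset: StudyDataset, output_dir: str | Path) -> dict[str, Path]:
    """Write the three study tables as CSV; returns the paths written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {
        "institutions": dataset.institutions_frame(),
        "workloads": dataset.workloads_frame(),
        "finances": pd.DataFrame(
            [
                {
                    k: (str(v) if isinstance(v, Decimal) else v)
                    for k, v in f.model_dump().items()
                }
                for f in dataset.finances
            ]
        ),
    }
    for name, frame in frames.items():
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    return paths


def write_table(
    rows,
    path: str | Path,
    format: Literal["csv", "json"] = "csv",
    *,
    allow_empty: bool = False,
) -> Path:
    """Write a tabular result (DataFrame or iterable of mappings) to disk.

    Decimal cells are serialised at their stored precision, so a write/read
    round trip preserves printed values exactly.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if rows.empty and not allow_empty:
        raise EquicostError(f"refusing to write empty table to {path} (allow_empty=False)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = rows.copy()
    for c in out.columns:
        if out[c].map(lambda v: isinstance(v, Decimal)).any():
            out[c] = out[c].map(lambda v: str(v) if isinstance(v, Decimal) else v)
    if format == "csv":
        out.to_csv(path, index=False)
    elif format == "json":
        out.to_json(path, orient="records", indent=1)
    else:
        raise EquicostError(f"unknown output format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Catalogue completeness check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogueDiscrepancy:
    kind: Literal["missing_category", "extra_category", "missing_item", "extra_item"]
    service_class: str
    category: str
    item: str | None = None


def validate_catalogue(
    dataset: StudyDataset, expected: CatalogueSpec
) -> list[CatalogueDiscrepancy]:
    """Compare the dataset's delivered services against a catalogue spec.

    Reporting only; the dataset is never mutated. A category or item counts as
    present if any institution carries a workload record for it.
    """
    found = []
    for service_class in (PRIMARY_MEDICAL, NEPHSP):
        have_cats = {w.category for w in dataset.workloads if w.service_class == service_class}
        have_items = {
            (w.category, w.item)
            for w in dataset.workloads
            if w.service_class == service_class
        }
        want_cats = set(expected.category_names(service_class))
        want_items = set(expected.items(service_class))
        for c in sorted(want_cats - have_cats):
            found.append(CatalogueDiscrepancy("missing_category", service_class, c))
        for c in sorted(have_cats - want_cats):
            found.append(CatalogueDiscrepancy("extra_category", service_class, c))
        for c, it in sorted(want_items - have_items):
            if c in have_cats:  # whole-category absence already reported above
                found.append(CatalogueDiscrepancy("missing_item", service_class, c, it))
        for c, it in sorted(have_items - want_items):
            if c in want_cats:
                found.append(CatalogueDiscrepancy("extra_item", service_class, c, it))
    return found
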