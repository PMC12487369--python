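"""Human-readable study report: the five standard tables plus a JSON headline.

Table layout mirrors the published study: institutions/staffing by region,
programme finance by region, the cost-estimation chain by region, programme
category shares with a between-category ANOVA, and per-category unit
equivalent values with across-county ANOVA flags.  "Mean ± SD" cells are
emitted as two numeric columns plus a formatted string column so the CSVs
stay machine-readable.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import StudyDataset, write_table
from .equivalents import category_shares, round2
from .model import EquivalentCostModel
from .stats import anova_oneway

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    table2: pd.DataFrame  # institutions & staffing by region
    table3: pd.DataFrame  # programme finance by region
    table4: pd.DataFrame  # cost estimation chain by region
    table5: pd.DataFrame  # category share mean±SD across regions (+ ANOVA)
    table6: pd.DataFrame  # unit equivalents mean±SD (+ per-category ANOVA)
    headline: dict
    correlations: pd.DataFrame | None = None


def _mean_sd_cols(df: pd.DataFrame, value: str) -> pd.DataFrame:
    g = df.groupby("region", sort=True)[value]
    out = pd.DataFrame(
        {"total": g.sum(), "mean": g.mean(), "sd": g.std(ddof=1)}
    )
    out["mean_sd"] = [
        f"{m:,.0f} ± {s:,.0f}" if not math.isnan(s) else f"{m:,.0f} ± n/a"
        for m, s in zip(out["mean"], out["sd"])
    ]
    return out


def build_table2(dataset: StudyDataset) -> pd.DataFrame:
    inst = dataset.institutions_frame()
    res = _mean_sd_cols(inst, "registered_residents").add_prefix("residents_")
    staff = _mean_sd_cols(inst, "health_professionals").add_prefix("staff_")
    n = inst.groupby("region", sort=True).size().rename("n_institutions")
    out = pd.concat([n, res, staff], axis=1)
    total = {
        "n_institutions": int(n.sum()),
        "residents_total": int(res["residents_total"].sum()),
        "residents_mean": inst["registered_residents"].mean(),
        "residents_sd": inst["registered_residents"].std(ddof=1),
        "staff_total": int(staff["staff_total"].sum()),
        "staff_mean": inst["health_professionals"].mean(),
        "staff_sd": inst["health_professionals"].std(ddof=1),
    }
    out.loc["Total"] = pd.Series(total)
    return out


def build_table3(dataset: StudyDataset) -> pd.DataFrame:
    inst = dataset.institutions_frame()[["institution_id", "region", "registered_residents"]]
    fin = dataset.finances_frame()
    df = inst.merge(fin, on="institution_id")
    rows = {}
    grouped = list(df.groupby("region", sort=True)) + [("Total", df)]
    for region, sub in grouped:
        row = {}
        for side, col in (("revenue", "nephsp_revenue"), ("expenditure", "nephsp_expenditure")):
            total = sub[col].sum()
            row[f"{side}_total"] = round2(total)
            row[f"{side}_mean"] = round2(sub[col].mean())
            sd = sub[col].std(ddof=1)
            row[f"{side}_sd"] = None if math.isnan(sd) else round2(sd)
            row[f"{side}_per_capita"] = round2(total / sub["registered_residents"].sum())
            denom = sub[f"total_operating_{side}"].sum()
            row[f"{side}_share_pct"] = (
                round2(100.0 * total / denom) if denom and not math.isnan(denom) else None
            )
        rows[region] = row
    return pd.DataFrame(rows).T


def build_table4(dataset: StudyDataset, rounding: str = "paper") -> pd.DataFrame:
    results = EquivalentCostModel(dataset).fit(group_by="region", rounding=rounding)
    return results.frame


def build_table5(dataset: StudyDataset) -> pd.DataFrame:
    shares = category_shares(dataset, scope="region")
    df = pd.DataFrame(
        {"region": s.scope, "category": s.category, "share": s.share_of_nephsp}
        for s in shares
    ).dropna(subset=["share"])
    piv = df.pivot(index="category", columns="region", values="share")
    out = pd.DataFrame(
        {
            "n": piv.notna().sum(axis=1),
            "mean": piv.mean(axis=1),
            "sd": piv.std(axis=1, ddof=1),
        }
    ).sort_values("mean", ascending=False)
    groups = [row.dropna().to_numpy() for _, row in piv.iterrows()]
    out["F"] = np.nan
    out["P"] = np.nan
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        res = anova_oneway(groups)
        out.loc[out.index[0], "F"] = res.f_statistic
        out.loc[out.index[0], "P"] = res.p_value
    else:
        logger.info("table5: too few per-region share replicates for ANOVA")
    out["mean_sd"] = [f"{m:.2f} ± {s:.2f}" for m, s in zip(out["mean"], out["sd"])]
    return out


def build_table6(dataset: StudyDataset) -> pd.DataFrame:
    shares = category_shares(dataset, scope="institution")
    county_of = {i.institution_id: i.county for i in dataset.institutions}
    df = pd.DataFrame(
        {
            "county": county_of[s.scope],
            "category": s.category,
            "unit_equivalent": s.unit_equivalent,
        }
        for s in shares
    ).dropna(subset=["unit_equivalent"])
    rows = []
    for category, sub in df.groupby("category", sort=True):
        by_county = sub.groupby("county")["unit_equivalent"].mean()
        row = {
            "category": category,
            "n": len(by_county),
            "mean": by_county.mean(),
            "sd": by_county.std(ddof=1) if len(by_county) > 1 else math.nan,
        }
        groups = [
            g.to_numpy()
            for _, g in sub.groupby("county")["unit_equivalent"]
            if len(g) >= 2
        ]
        if len(groups) >= 2:
            res = anova_oneway(groups)
            row["F"], row["P"] = res.f_statistic, res.p_value
        else:
            row["F"], row["P"] = math.nan, math.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("category").sort_values("mean", ascending=False)
    out["mean_sd"] = [
        f"{m:.2f} ± {s:.2f}" if not math.isnan(s) else f"{m:.2f} ± n/a"
        for m, s in zip(out["mean"], out["sd"])
    ]
    return out


def run_report(
    dataset: StudyDataset,
    covariates: pd.DataFrame | None = None,
    output_dir: str | Path | None = None,
    *,
    rounding: str = "paper",
) -> ReportBundle:
    """Build all report tables (and write them when ``output_dir`` is set)."""
    model = EquivalentCostModel(dataset)
    results = model.fit(group_by="region", rounding=rounding)
    for scope, reason in results.skipped:
        logger.warning("report: skipped scope %r: %s", scope, reason)

    bundle = ReportBundle(
        table2=build_table2(dataset),
        table3=build_table3(dataset),
        table4=results.frame,
        table5=build_table5(dataset),
        table6=build_table6(dataset),
        headline=results.headline(),
    )
    if covariates is not None and len(covariates):
        corr = results.correlations(covariates)
        bundle.correlations = pd.DataFrame(
            {"label": c.label, "rho": c.rho, "n": c.n, "p_value": c.p_value}
            for c in corr
        )
    else:
        logger.info("no covariates supplied; correlation section omitted")

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("table2", "table3", "table4", "table5", "table6"):
            frame = getattr(bundle, name)
            write_table(frame.reset_index(), out / f"{name}.csv", "csv", allow_empty=True)
            logger.info("wrote %s (%d rows)", out / f"{name}.csv", len(frame))
        if bundle.correlations is not None:
            write_table(bundle.correlations, out / "correlations.csv", "csv")
        (out / "headline.json").write_text(json.dumps(bundle.headline, indent=1))
    return bundle
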