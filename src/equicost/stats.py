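"""Inferential layer: tie-aware Spearman correlation and one-way ANOVA,
including reconstruction of the ANOVA from published (n, mean, SD) rows.

The summary-statistics path matters because published comparison tables print
only group summaries: with ``ss_between = Σ nᵢ(x̄ᵢ − x̄)²`` (grand mean
weighted by nᵢ) and ``ss_within = Σ (nᵢ − 1) sᵢ²`` the F statistic is an
exact algebraic function of the summaries, identical to the raw-data ANOVA
when the summaries are exact and reproducible to input-rounding tolerance
when they are printed at 2 dp.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data import EquicostError


@dataclass(frozen=True)
class CorrelationResult:
    label: str
    rho: float
    n: int
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float  # nan when ss_within == 0 (F undefined)
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary: size, mean and sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise EquicostError(f"group {self.label!r}: n must be ≥ 2 for a defined SD")
        if self.sd < 0:
            raise EquicostError(f"group {self.label!r}: negative SD")


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    return float(a @ b) / denom


def spearman(x, y, *, label: str = "", method: str = "t") -> CorrelationResult:
    """Spearman's rho as the Pearson correlation of mid-ranks (average ranks
    for ties).

    ``method="t"`` gives the large-sample two-sided p-value from the
    t-approximation with n − 2 degrees of freedom; ``method="exact"``
    enumerates all permutations of one argument (only for n ≤ 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EquicostError("spearman requires two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise EquicostError("spearman requires at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise EquicostError("spearman requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EquicostError("spearman undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    rho = min(1.0, max(-1.0, _pearson(rx, ry)))
    if method == "exact":
        if n > 8:
            raise EquicostError("exact permutation p-value limited to n ≤ 8")
        hits = total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson(rx, np.asarray(perm))) >= target:
                hits += 1
        p = hits / total
    elif method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    else:
        raise EquicostError(f"unknown p-value method {method!r}")
    return CorrelationResult(label=label, rho=rho, n=n, p_value=min(p, 1.0))


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------

def _anova_from_ss(ssb: float, ssw: float, dfb: int, dfw: int) -> AnovaResult:
    if dfb < 1 or dfw < 1:
        raise EquicostError("ANOVA requires df_between ≥ 1 and df_within ≥ 1")
    ssb = max(ssb, 0.0)
    ssw = max(ssw, 0.0)
    if ssw == 0.0:
        return AnovaResult(math.nan, dfb, dfw, math.nan, ssb, ssw)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(f, dfb, dfw, p, ssb, ssw)


def anova_oneway(groups, *, welch: bool = False) -> AnovaResult:
    """Classical equal-variance one-way ANOVA on raw groups.

    ``welch=True`` switches to the Welch heteroscedastic variant (F against
    an F distribution with Satterthwaite denominator df; the SS fields then
    report the classical decomposition for reference).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise EquicostError("ANOVA requires at least 2 groups")
    for i, g in enumerate(arrays):
        if g.ndim != 1 or g.size < 2:
            raise EquicostError(f"ANOVA group {i} must have at least 2 values")
        if not np.isfinite(g).all():
            raise EquicostError(f"ANOVA group {i} contains non-finite values")
    ns = np.array([g.size for g in arrays])
    means = np.array([g.mean() for g in arrays])
    grand = float(np.concatenate(arrays).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    dfb = len(arrays) - 1
    dfw = int((ns - 1).sum())
    if not welch:
        return _anova_from_ss(ssb, ssw, dfb, dfw)
    variances = np.array([g.var(ddof=1) for g in arrays])
    if (variances == 0).any():
        return AnovaResult(math.nan, dfb, dfw, math.nan, ssb, ssw)
    w = ns / variances
    mw = float((w * means).sum() / w.sum())
    k = len(arrays)
    num = float((w * (means - mw) ** 2).sum()) / (k - 1)
    lam = float((((1 - w / w.sum()) ** 2) / (ns - 1)).sum()) * 3.0 / (k * k - 1)
    f = num / (1 + 2 * lam * (k - 2) / 3)
    dfw_welch = 1.0 / lam
    p = float(sps.f.sf(f, k - 1, dfw_welch))
    return AnovaResult(f, dfb, int(round(dfw_welch)), p, ssb, ssw)


def anova_from_summary(summaries) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, SD) summaries.

    Algebraically identical to :func:`anova_oneway` on the raw data the
    summaries came from.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise EquicostError("ANOVA requires at least 2 group summaries")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    grand = float((ns * means).sum() / ns.sum())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    return _anova_from_ss(ssb, ssw, len(summaries) - 1, int((ns - 1).sum()))


def summarize_groups(groups, labels=None) -> list[GroupSummary]:
    """Reduce raw groups to (n, mean, sample SD) summaries."""
    labels = labels or [f"group{i}" for i in range(len(list(groups)))]
    out = []
    for lab, g in zip(labels, groups):
        g = np.asarray(g, dtype=float)
        out.append(GroupSummary(lab, int(g.size), float(g.mean()), float(g.std(ddof=1))))
    return out


# ---------------------------------------------------------------------------
# The study's correlation families on a full dataset
# ---------------------------------------------------------------------------

def correlation_suite(dataset, covariates=None) -> list[CorrelationResult]:
    """The three correlation families examined by the costing study.

    1. institution programme revenue vs county-level GDP (needs ``covariates``
       with columns ``county`` and ``gdp`` covering every county);
    2. per-capita estimated cost vs registered residents served, and vs the
       programme's equivalent-value share;
    3. institution programme equivalent total vs its mean unit equivalent
       value, and vs its annual case volume.
    """
    import pandas as pd

    from .catalogue import NEPHSP
    from .costing import cost_pipeline_detailed
    from .equivalents import STANDARD_MINUTES

    estimates, _ = cost_pipeline_detailed(dataset, "institution")
    est = {e.scope: e for e in estimates if e.level == "institution"}
    inst_ids = [i.institution_id for i in dataset.institutions if i.institution_id in est]
    results: list[CorrelationResult] = []

    def _family(x, y, label):
        # a family degenerate on this dataset (e.g. a constant vector) is
        # skipped with a notice rather than aborting the whole suite
        try:
            results.append(spearman(x, y, label=label))
        except EquicostError as exc:
            logging.getLogger(__name__).info("correlation %s skipped: %s", label, exc)

    if covariates is not None:
        cov = pd.DataFrame(covariates)
        gdp = dict(zip(cov["county"].astype(str), cov["gdp"].astype(float)))
        for i in dataset.institutions:
            if i.county not in gdp:
                raise EquicostError(f"covariates missing county {i.county!r}")
        revenue = [float(dataset.finance_for(i).nephsp_revenue) for i in inst_ids]
        county_gdp = [gdp[dataset.institution(i).county] for i in inst_ids]
        _family(revenue, county_gdp, "nephsp_revenue_vs_county_gdp")

    pcc = [float(est[i].per_capita_estimated_cost) for i in inst_ids]
    residents = [dataset.institution(i).registered_residents for i in inst_ids]
    share = [est[i].nephsp_share_pct for i in inst_ids]
    _family(pcc, residents, "per_capita_cost_vs_residents")
    _family(pcc, share, "per_capita_cost_vs_nephsp_share")

    work = dataset.workloads_frame()
    work = work[work["service_class"] == NEPHSP]
    work["eq"] = (
        work["workers_per_case"] * work["minutes_per_case"] / STANDARD_MINUTES
    ) * work["annual_cases"]
    per_inst = work.groupby("institution_id").agg(eq=("eq", "sum"), cases=("annual_cases", "sum"))
    per_inst = per_inst.reindex(inst_ids).dropna()
    unit = per_inst["eq"] / per_inst["cases"].where(per_inst["cases"] > 0)
    ok = unit.notna()
    _family(per_inst.loc[ok, "eq"], unit[ok], "total_equivalents_vs_unit_equivalent")
    _family(per_inst["eq"], per_inst["cases"], "total_equivalents_vs_annual_cases")
    return results
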