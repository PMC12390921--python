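"""Time-phased aggregation of activity costs into program cost reports.

The engine walks every activity of a :class:`~saltcost.params.ParameterBook`
through each calendar year of the horizon, applies its cost rule
(fixed annual, annualised capital, per-MT, or premix-from-spec), and folds the
results into a :class:`CostReport`: per-year totals, undiscounted annual
averages, per-capita and per-MT unit costs, per-activity and stakeholder-group
breakdowns, and (optionally) incremental costs against a baseline program.

Conventions match common practice for activity-based program costing:

* annual averages are plain arithmetic means of the per-year totals over the
  horizon — discounting enters only through the equivalent annual cost of
  capital items;
* the per-capita denominator is the mean population over the horizon;
* the per-MT denominator is the mean annual fortified-salt tonnage
  (switchable to all fortifiable salt via ``per_mt_denominator``);
* displayed totals round to the nearest 1,000 USD and per-MT values to one
  decimal; internal arithmetic is unrounded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .demand import annual_fortifiable_salt_mt, annual_fortified_salt_mt
from .finance import equivalent_annual_cost
from .params import (
    REFINERY_CATEGORIES,
    ActivitySchedule,
    Category,
    ParameterBook,
)
from .premix import annual_premix_cost

__all__ = [
    "activity_cost_in_year",
    "compute_report",
    "percent_shares",
    "share_percent",
    "CostReport",
    "ActivityResult",
    "GROUPS",
]

#: Stakeholder-facing cost groups used in summary tables.
GROUPS = ("premix", "refinery_related", "government_related")


def category_group(category: Category) -> str:
    if category is Category.premix:
        return "premix"
    if category in REFINERY_CATEGORIES:
        return "refinery_related"
    return "government_related"


def activity_cost_in_year(
    activity: ActivitySchedule, book: ParameterBook, year: int
) -> float:
    """Cost (base-year USD) contributed by one activity in one horizon year.

    Capital lump sums contribute their equivalent annual cost in *every*
    horizon year (the expenditure happens during phase-in; the cost is spread
    over the asset's life).  All other rules contribute only in their active
    years.
    """
    if year not in book.years:
        raise ValueError(f"year {year} outside horizon")
    rule = activity.cost_rule
    if rule.kind == "capital":
        return equivalent_annual_cost(
            rule.capital,
            book.finance.discount_rate,
            book.finance.equipment_life_years,
        )
    if year not in activity.active_years:
        return 0.0
    if rule.kind == "fixed_annual":
        return rule.fixed_annual
    if rule.kind == "per_mt":
        return rule.per_mt * annual_fortified_salt_mt(book.demand, year)
    # premix_from_spec: baseline spec applies during phase-in years
    return annual_premix_cost(book, year)


@dataclass(frozen=True)
class ActivityResult:
    activity_id: str
    label: str
    phase: str
    stakeholder: str
    category: str
    annual_average: float
    share_pct: float  # unrounded percent of total


@dataclass
class CostReport:
    """Cost results for one parameter book (all values base-year USD)."""

    book_id: str
    program_id: str
    scenario: str
    years: list[int]
    per_year_total: dict[int, float]
    per_year_by_activity: dict[str, dict[int, float]]
    annual_average_total: float
    annual_average_per_capita: float
    annual_average_per_mt: float
    mean_population: float
    mean_fortified_mt: float
    by_activity: dict[str, ActivityResult]
    by_group: dict[str, float]
    by_group_share: dict[str, float]
    incremental_vs_baseline: Optional["CostReport"] = None
    per_mt_denominator: str = "fortified"
    rounded_shares: dict[str, int] = field(default_factory=dict)

    # -- writers ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (metric, year|average)."""
        rows: list[dict] = []

        def emit(report: "CostReport", prefix: str) -> None:
            for y in report.years:
                rows.append(
                    {
                        "book_id": self.book_id,
                        "program": self.program_id,
                        "scenario": self.scenario,
                        "metric": f"{prefix}total",
                        "period": str(y),
                        "value": report.per_year_total[y],
                    }
                )
            for name, value in (
                (f"{prefix}annual_average_total", report.annual_average_total),
                (f"{prefix}annual_average_per_capita", report.annual_average_per_capita),
                (f"{prefix}annual_average_per_mt", report.annual_average_per_mt),
            ):
                rows.append(
                    {
                        "book_id": self.book_id,
                        "program": self.program_id,
                        "scenario": self.scenario,
                        "metric": name,
                        "period": "average",
                        "value": value,
                    }
                )
            for act_id, res in report.by_activity.items():
                rows.append(
                    {
                        "book_id": self.book_id,
                        "program": self.program_id,
                        "scenario": self.scenario,
                        "metric": f"{prefix}activity:{act_id}",
                        "period": "average",
                        "value": res.annual_average,
                    }
                )

        emit(self, "")
        if self.incremental_vs_baseline is not None:
            emit(self.incremental_vs_baseline, "incremental_")
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        payload = {
            "schema_version": "1.0",
            "book_id": self.book_id,
            "program": self.program_id,
            "scenario": self.scenario,
            "per_mt_denominator": self.per_mt_denominator,
            "per_year_total": {str(y): self.per_year_total[y] for y in self.years},
            "annual_average_total": self.annual_average_total,
            "annual_average_per_capita": self.annual_average_per_capita,
            "annual_average_per_mt": self.annual_average_per_mt,
            "by_activity": {
                k: {
                    "label": v.label,
                    "phase": v.phase,
                    "stakeholder": v.stakeholder,
                    "category": v.category,
                    "annual_average": v.annual_average,
                    "share_pct": v.share_pct,
                }
                for k, v in self.by_activity.items()
            },
            "by_group": dict(self.by_group),
            "by_group_share": dict(self.by_group_share),
        }
        if self.rounded_shares:
            payload["rounded_shares"] = dict(self.rounded_shares)
        if self.incremental_vs_baseline is not None:
            payload["incremental_vs_baseline"] = (
                self.incremental_vs_baseline.to_json_dict()
            )
        return payload

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_json_dict(), **kwargs)

    def format_table(self) -> str:
        """Human-readable activity table (rounded to nearest 1,000 USD)."""
        lines = [
            f"Program: {self.program_id}  scenario: {self.scenario}  "
            f"({self.years[0]}-{self.years[-1]})",
            f"{'activity':<58}{'avg USD/yr':>14}{'share':>8}",
        ]
        shares = self.rounded_shares or percent_shares(self).rounded_shares
        for act_id, res in self.by_activity.items():
            lines.append(
                f"{res.label[:56]:<58}{round(res.annual_average, -3):>14,.0f}"
                f"{shares.get(act_id, 0):>7d}%"
            )
        lines.append(
            f"{'Total annual average':<58}"
            f"{round(self.annual_average_total, -3):>14,.0f}{100:>7d}%"
        )
        lines.append(
            f"Per capita: {self.annual_average_per_capita:.3f} USD/person/yr   "
            f"Per MT: {self.annual_average_per_mt:.1f} USD/MT"
        )
        return "\n".join(lines)


def _metric_delta(report: CostReport, baseline: CostReport) -> CostReport:
    """Metric-wise difference report (report minus baseline)."""
    years = report.years
    per_year = {
        y: report.per_year_total[y] - baseline.per_year_total[y] for y in years
    }
    act_ids = list(report.by_activity) + [
        a for a in baseline.by_activity if a not in report.by_activity
    ]
    by_activity: dict[str, ActivityResult] = {}
    per_year_by_activity: dict[str, dict[int, float]] = {}
    total = report.annual_average_total - baseline.annual_average_total
    for act_id in act_ids:
        r = report.by_activity.get(act_id)
        b = baseline.by_activity.get(act_id)
        ref = r or b
        avg = (r.annual_average if r else 0.0) - (b.annual_average if b else 0.0)
        by_activity[act_id] = ActivityResult(
            activity_id=act_id,
            label=ref.label,
            phase=ref.phase,
            stakeholder=ref.stakeholder,
            category=ref.category,
            annual_average=avg,
            share_pct=100.0 * avg / total if total else 0.0,
        )
        ry = report.per_year_by_activity.get(act_id, {})
        by = baseline.per_year_by_activity.get(act_id, {})
        per_year_by_activity[act_id] = {
            y: ry.get(y, 0.0) - by.get(y, 0.0) for y in years
        }
    by_group = {
        g: report.by_group[g] - baseline.by_group[g] for g in GROUPS
    }
    return CostReport(
        book_id=f"{report.book_id}-minus-{baseline.book_id}",
        program_id=report.program_id,
        scenario=report.scenario,
        years=years,
        per_year_total=per_year,
        per_year_by_activity=per_year_by_activity,
        annual_average_total=total,
        annual_average_per_capita=(
            report.annual_average_per_capita - baseline.annual_average_per_capita
        ),
        annual_average_per_mt=(
            report.annual_average_per_mt - baseline.annual_average_per_mt
        ),
        mean_population=report.mean_population,
        mean_fortified_mt=report.mean_fortified_mt,
        by_activity=by_activity,
        by_group=by_group,
        by_group_share={
            g: 100.0 * v / total if total else 0.0 for g, v in by_group.items()
        },
        per_mt_denominator=report.per_mt_denominator,
    )


def compute_report(
    book: ParameterBook,
    baseline: Optional[CostReport] = None,
    per_mt_denominator: str = "fortified",
) -> CostReport:
    """Run the full cost model for one book.

    ``per_mt_denominator`` selects the tonnage used for unit costs:
    ``"fortified"`` (salt actually fortified, the default) or
    ``"fortifiable"`` (all discretionary + manufactured-food salt).
    """
    if per_mt_denominator not in ("fortified", "fortifiable"):
        raise ValueError("per_mt_denominator must be 'fortified' or 'fortifiable'")
    if baseline is not None and baseline.years != book.years:
        raise ValueError(
            "baseline report horizon does not match book horizon "
            f"({baseline.years[0]}-{baseline.years[-1]} vs "
            f"{book.years[0]}-{book.years[-1]})"
        )
    years = book.years
    n = len(years)
    per_year_by_activity: dict[str, dict[int, float]] = {}
    for act in book.activities:
        per_year_by_activity[act.activity_id] = {
            y: activity_cost_in_year(act, book, y) for y in years
        }
    per_year_total = {
        y: sum(series[y] for series in per_year_by_activity.values()) for y in years
    }
    total_avg = sum(per_year_total.values()) / n

    mean_pop = sum(book.demand.population_by_year[y] for y in years) / n
    if per_mt_denominator == "fortified":
        mean_mt = sum(annual_fortified_salt_mt(book.demand, y) for y in years) / n
    else:
        mean_mt = sum(annual_fortifiable_salt_mt(book.demand, y) for y in years) / n

    by_activity: dict[str, ActivityResult] = {}
    by_group = {g: 0.0 for g in GROUPS}
    for act in book.activities:
        avg = sum(per_year_by_activity[act.activity_id].values()) / n
        by_activity[act.activity_id] = ActivityResult(
            activity_id=act.activity_id,
            label=act.label,
            phase=act.phase.value,
            stakeholder=act.stakeholder.value,
            category=act.category.value,
            annual_average=avg,
            share_pct=100.0 * avg / total_avg if total_avg else 0.0,
        )
        by_group[category_group(act.category)] += avg

    report = CostReport(
        book_id=book.book_id,
        program_id=book.program.program_id,
        scenario=book.scenario,
        years=years,
        per_year_total=per_year_total,
        per_year_by_activity=per_year_by_activity,
        annual_average_total=total_avg,
        annual_average_per_capita=total_avg / mean_pop if mean_pop else math.nan,
        annual_average_per_mt=total_avg / mean_mt if mean_mt else math.nan,
        mean_population=mean_pop,
        mean_fortified_mt=mean_mt,
        by_activity=by_activity,
        by_group=by_group,
        by_group_share={
            g: 100.0 * v / total_avg if total_avg else 0.0
            for g, v in by_group.items()
        },
        per_mt_denominator=per_mt_denominator,
    )
    if baseline is not None:
        report.incremental_vs_baseline = _metric_delta(report, baseline)
    return report


def share_percent(component: float, total: float) -> int:
    """Percent of total, rounded to the nearest whole percent.

    Components below 0.5% of the total round *down* to 0% (so tiny line items
    display as 0 rather than 1).
    """
    if total <= 0:
        raise ValueError("total must be > 0 to compute shares")
    pct = 100.0 * component / total
    if pct < 0.5:
        return 0
    return int(math.floor(pct + 0.5))


def percent_shares(report: CostReport) -> CostReport:
    """Attach rounded per-activity percent shares to a report (returns it)."""
    if report.annual_average_total <= 0:
        raise ValueError("cannot compute shares of a zero-total report")
    report.rounded_shares = {
        act_id: share_percent(res.annual_average, report.annual_average_total)
        for act_id, res in report.by_activity.items()
    }
    return report
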