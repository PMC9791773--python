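"""Tabular I/O and food-composition conversion.

CSV dialects (UTF-8, header row):

* profiles:  subject_id, age_years, sex, residence, income_band, household_size
* records:   subject_id, day, energy_kcal, one column per component id,
             then any extra nutrient columns (per-day amounts)
* scores:    subject_id, age_group, <component>_score ..., total
* food composition table: food, component_id (blank for unassigned items),
             energy_kcal, then nutrient columns — all per 100 g edible portion

Writers are deterministic: fixed column order, scores at 2 decimals and
densities at 1 (full precision lives in the audit output), so identical
inputs produce byte-identical files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort_analysis import CohortReport
from .errors import InputSchemaError
from .scoring import (
    CPDIResult,
    DailyIntakeRecord,
    ExcludedSubject,
    SubjectProfile,
    SubjectReject,
)
from .standards import default_cpdi_standard

__all__ = [
    "RowIssue",
    "FoodCompositionTable",
    "FoodItem",
    "read_cohort",
    "write_cohort",
    "write_scores",
    "read_scores",
    "write_rejects",
    "write_report",
    "render_report_text",
    "write_audit",
    "load_fct",
    "convert_foods_to_nutrients",
]

PROFILE_COLUMNS = ["subject_id", "age_years", "sex", "residence", "income_band", "household_size"]
RECORD_BASE_COLUMNS = ["subject_id", "day", "energy_kcal"]


@dataclass(frozen=True)
class RowIssue:
    """Line-numbered diagnostic for a rejected input row."""

    path: str
    line: int  # 1-based line in the file, header = line 1
    message: str


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputSchemaError(f"{path}: missing mandatory columns {missing}")


def read_cohort(
    profiles_path: str | Path,
    records_path: str | Path,
    component_ids: Sequence[str] | None = None,
) -> tuple[list[SubjectProfile], list[DailyIntakeRecord], list[RowIssue]]:
    """Read profile and recall CSVs into domain objects.

    Columns not in ``component_ids`` (default: the 11 default-standard
    components) and not structural are treated as extra nutrients.
    Malformed rows (negative amounts, non-numeric fields) are skipped and
    reported as line-numbered issues rather than raising.
    """
    component_ids = list(component_ids or default_cpdi_standard().component_ids)
    issues: list[RowIssue] = []

    pdf = pd.read_csv(profiles_path, dtype={"subject_id": str})
    _require_columns(pdf, PROFILE_COLUMNS[:2], str(profiles_path))
    profiles: list[SubjectProfile] = []
    for pos, row in enumerate(pdf.itertuples(index=False)):
        line = pos + 2
        try:
            profiles.append(
                SubjectProfile(
                    subject_id=str(row.subject_id),
                    age_years=int(row.age_years),
                    sex=str(getattr(row, "sex", "unknown")),
                    residence=str(getattr(row, "residence", "unknown")),
                    income_band=str(getattr(row, "income_band", "unknown")),
                    household_size=int(getattr(row, "household_size", 0) or 0),
                )
            )
        except (TypeError, ValueError) as exc:
            issues.append(RowIssue(str(profiles_path), line, f"bad profile row: {exc}"))

    rdf = pd.read_csv(records_path, dtype={"subject_id": str})
    _require_columns(rdf, RECORD_BASE_COLUMNS, str(records_path))
    present_components = [c for c in component_ids if c in rdf.columns]
    extra_cols = [
        c for c in rdf.columns
        if c not in RECORD_BASE_COLUMNS and c not in present_components
    ]
    records: list[DailyIntakeRecord] = []
    for pos, row in rdf.iterrows():
        line = int(pos) + 2
        try:
            amounts = {c: float(row[c]) for c in present_components if pd.notna(row[c])}
            extras = {c: float(row[c]) for c in extra_cols if pd.notna(row[c])}
            records.append(
                DailyIntakeRecord(
                    subject_id=str(row["subject_id"]),
                    day=int(row["day"]),
                    energy_kcal=float(row["energy_kcal"]),
                    amounts=amounts,
                    extra_nutrients=extras,
                )
            )
        except (TypeError, ValueError) as exc:
            issues.append(RowIssue(str(records_path), line, f"bad record row: {exc}"))
    if rdf.empty:
        import warnings

        warnings.warn(f"{records_path}: no recall records", stacklevel=2)
    return profiles, records, issues


def write_cohort(
    profiles: Sequence[SubjectProfile],
    records: Sequence[DailyIntakeRecord],
    profiles_path: str | Path,
    records_path: str | Path,
    component_ids: Sequence[str] | None = None,
) -> None:
    """Write a cohort in the dialect :func:`read_cohort` reads."""
    component_ids = list(component_ids or default_cpdi_standard().component_ids)
    pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "residence": p.residence,
                "income_band": p.income_band,
                "household_size": p.household_size,
            }
            for p in profiles
        ],
        columns=PROFILE_COLUMNS,
    ).to_csv(profiles_path, index=False)

    extra_names = sorted({n for r in records for n in r.extra_nutrients})
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "day": r.day, "energy_kcal": round(r.energy_kcal, 4)}
        for c in component_ids:
            row[c] = round(r.amounts.get(c, 0.0), 4)
        for n in extra_names:
            row[n] = round(r.extra_nutrients.get(n, 0.0), 4)
        rows.append(row)
    pd.DataFrame(rows, columns=RECORD_BASE_COLUMNS + component_ids + extra_names).to_csv(
        records_path, index=False
    )


def write_scores(results: Sequence[CPDIResult], path: str | Path) -> None:
    """Scores CSV: subject_id, age_group, one column per subscore, total (2 dp)."""
    if not results:
        pd.DataFrame(columns=["subject_id", "age_group", "total"]).to_csv(path, index=False)
        return
    comp_ids = [cs.component_id for cs in results[0].component_scores]
    rows = []
    for res in sorted(results, key=lambda r: r.subject_id):
        row = {"subject_id": res.subject_id, "age_group": res.age_group.value}
        for cs in res.component_scores:
            row[f"{cs.component_id}_score"] = f"{cs.score:.2f}"
        row["total"] = f"{res.total:.2f}"
        rows.append(row)
    cols = ["subject_id", "age_group"] + [f"{c}_score" for c in comp_ids] + ["total"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a scores CSV back into a subjects x components subscore matrix."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id"], str(path))
    score_cols = [c for c in df.columns if c.endswith("_score")]
    if not score_cols:
        raise InputSchemaError(f"{path}: no *_score columns found")
    m = df.set_index("subject_id")[score_cols].astype(float)
    m.columns = [c.removesuffix("_score") for c in score_cols]
    return m


def write_rejects(
    entries: Sequence[SubjectReject | ExcludedSubject | RowIssue], path: str | Path
) -> None:
    """Machine-readable rejects CSV covering filter, scoring and parse rejects."""
    rows = []
    for e in entries:
        if isinstance(e, ExcludedSubject):
            rows.append(
                {"subject_id": e.subject_id, "reason": e.reason,
                 "detail": f"mean_energy={e.mean_energy:.1f}"}
            )
        elif isinstance(e, SubjectReject):
            rows.append({"subject_id": e.subject_id, "reason": e.reason, "detail": e.detail})
        else:
            rows.append(
                {"subject_id": "", "reason": "malformed_row",
                 "detail": f"{e.path}:{e.line}: {e.message}"}
            )
    pd.DataFrame(rows, columns=["subject_id", "reason", "detail"]).to_csv(path, index=False)


def write_report(report: CohortReport, path: str | Path) -> None:
    """Machine-readable JSON report."""
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def render_report_text(report: CohortReport) -> str:
    """Human-readable summary table of a cohort report."""
    lines = [
        f"Cohort: n = {report.n_subjects}",
        f"Total score: mean {report.mean_total:.2f} (SD {report.sd_total:.2f}), "
        f"median {report.median_total:.2f} [P25 {report.p25:.2f}, P75 {report.p75:.2f}]",
        "Diet-quality categories: "
        + ", ".join(f"{k} {v}" for k, v in report.category_counts.items()),
        f"Cronbach's alpha: raw {report.alpha_raw:.2f}, "
        f"standardized {report.alpha_standardized:.2f}",
        f"PCA: {report.n_eigen_gt_1} eigenvalues > 1, cumulative variance "
        f"{100 * report.cumulative_variance_top_k:.1f}%",
        "",
        f"{'component':<22}{'median':>8}{'P25':>8}{'P75':>8}{'item-rest r':>13}",
    ]
    for cid, (med, p25, p75) in report.component_medians.items():
        r = report.item_rest.get(cid, float("nan"))
        lines.append(f"{cid:<22}{med:>8.2f}{p25:>8.2f}{p75:>8.2f}{r:>13.2f}")
    if report.nutrient_correlations:
        lines += ["", f"{'nutrient':<22}{'r':>8}{'p':>12}"]
        for name, (r, p) in report.nutrient_correlations.items():
            lines.append(f"{name:<22}{r:>8.2f}{p:>12.4g}")
    return "\n".join(lines) + "\n"


def write_audit(results: Sequence[CPDIResult], path: str | Path) -> None:
    """Per-subject audit: densities (1 dp) and full-precision subscores."""
    rows = []
    for res in sorted(results, key=lambda r: r.subject_id):
        for cs in res.component_scores:
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "age_group": res.age_group.value,
                    "component_id": cs.component_id,
                    "density_per_1000kcal": f"{cs.density:.1f}",
                    "score": repr(cs.score),
                    "max_score": cs.max_score,
                    "missing": cs.component_id in res.missing_components,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# food-composition conversion


@dataclass(frozen=True)
class FoodItem:
    """Per-100-g nutrient profile of one food, with its component assignment."""

    name: str
    component_id: str | None
    energy_kcal: float
    nutrients: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class FoodCompositionTable:
    items: Mapping[str, FoodItem]

    def __post_init__(self) -> None:
        for item in self.items.values():
            if item.energy_kcal < 0 or any(v < 0 for v in item.nutrients.values()):
                raise InputSchemaError(f"food {item.name!r}: negative per-100g amount")


def load_fct(path: str | Path) -> FoodCompositionTable:
    """Load a food-composition CSV (per 100 g edible portion)."""
    df = pd.read_csv(path)
    _require_columns(df, ["food", "energy_kcal"], str(path))
    nutrient_cols = [c for c in df.columns if c not in ("food", "component_id", "energy_kcal")]
    items = {}
    for row in df.itertuples(index=False):
        comp = getattr(row, "component_id", None)
        if comp is not None and (pd.isna(comp) or comp == ""):
            comp = None
        items[str(row.food)] = FoodItem(
            name=str(row.food),
            component_id=None if comp is None else str(comp),
            energy_kcal=float(row.energy_kcal),
            nutrients={c: float(getattr(row, c)) for c in nutrient_cols},
        )
    return FoodCompositionTable(items)


def convert_foods_to_nutrients(
    item_intakes: Mapping[str, float],
    fct: FoodCompositionTable,
    strict: bool = True,
) -> tuple[float, dict[str, float], dict[str, float], list[str]]:
    """Convert food-item grams into energy, component amounts and nutrients.

    Each nutrient contribution is per-100g value x grams / 100; component
    amounts are the summed grams of the items assigned to that component.
    Unknown items raise in strict mode, otherwise they are skipped and
    listed in the returned rejects.
    """
    energy = 0.0
    component_amounts: dict[str, float] = {}
    nutrients: dict[str, float] = {}
    unknown: list[str] = []
    for food, grams in item_intakes.items():
        if grams < 0:
            raise ValueError(f"negative intake for {food!r}")
        item = fct.items.get(food)
        if item is None:
            if strict:
                raise InputSchemaError(f"food item not in composition table: {food!r}")
            unknown.append(food)
            continue
        factor = grams / 100.0
        energy += item.energy_kcal * factor
        if item.component_id is not None:
            component_amounts[item.component_id] = (
                component_amounts.get(item.component_id, 0.0) + grams
            )
        for name, per100 in item.nutrients.items():
            nutrients[name] = nutrients.get(name, 0.0) + per100 * factor
    return energy, component_amounts, nutrients, unknown
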