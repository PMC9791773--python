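"""Scoring engine: recall records -> energy densities -> CPDI points.

The pipeline per child is:

1. exclude implausible reporters (mean energy < 400 or > 4000 kcal/d);
2. average the (typically three) 24-h recall days and convert each
   component's mean daily amount into a density per 1000 kcal, using the
   ratio of mean amount to mean energy;
3. apply the category-specific piecewise-linear rule to each density;
4. sum the 11 subscores into a 0-90 total.

Densities make the score energy-adjusted: doubling every amount and the
energy of a day's intake leaves every subscore unchanged.

Scoring rules (density d, maximum score M):

* adequacy, recommended density R:      min(d / R, 1) * M
* moderation, interval [L, U]:          M inside [L, U];
                                        0 at d = 0 or d > 2U;
                                        (1 - |1 - d/L|) * M on (0, L);
                                        (1 - |1 - d/U|) * M on (U, 2U]
* limitation, limit density T:          0 for d >= T, else (1 - d/T) * M

The moderation rule divides by the *nearest* bound, which is the only
reading of "upper limit or lower limit" that is continuous at both ends
of the interval and reproduces the published worked example
((1 - |1 - 150/100|) x 10 = 5).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

from .errors import (
    AgeOutOfRangeError,
    CategoryMismatchError,
    DegenerateIntakeError,
)
from .standards import (
    AdequacyCutoffs,
    AgeGroup,
    Category,
    ComponentStandard,
    IndexStandard,
    LimitationCutoffs,
    ModerationCutoffs,
    assign_age_group,
)

__all__ = [
    "DailyIntakeRecord",
    "SubjectProfile",
    "DensityVector",
    "ComponentScore",
    "CPDIResult",
    "ExcludedSubject",
    "SubjectReject",
    "filter_plausible_energy",
    "average_and_densify",
    "score_adequacy",
    "score_moderation",
    "score_limitation",
    "score_component",
    "score_subject",
    "score_cohort",
]

ENERGY_MIN_KCAL = 400.0
ENERGY_MAX_KCAL = 4000.0


@dataclass(frozen=True)
class DailyIntakeRecord:
    """One child-day of 24-h recall.

    ``amounts`` maps component id to the day's consumed amount in that
    component's unit (g for foods, ug RAE for vitamin A, mg for iron).
    ``extra_nutrients`` carries per-day nutrient intakes that are not
    scored but feed nutrient-adequacy-ratio analyses.
    """

    subject_id: str
    day: int
    energy_kcal: float
    amounts: Mapping[str, float]
    extra_nutrients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"day index must be >= 1, got {self.day}")
        if not math.isfinite(self.energy_kcal) or self.energy_kcal < 0:
            raise ValueError(f"energy must be finite and >= 0, got {self.energy_kcal}")
        for cid, amt in self.amounts.items():
            if not math.isfinite(amt) or amt < 0:
                raise ValueError(f"amount for {cid!r} must be finite and >= 0, got {amt}")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    age_years: int
    sex: str = "unknown"
    residence: str = "unknown"
    income_band: str = "unknown"
    household_size: int = 0


@dataclass(frozen=True)
class DensityVector:
    """Averaged per-1000-kcal densities for one child."""

    subject_id: str
    mean_energy: float
    densities: Mapping[str, float]
    n_days_used: int
    missing_components: tuple[str, ...] = ()


@dataclass(frozen=True)
class ComponentScore:
    component_id: str
    density: float
    score: float
    max_score: float


@dataclass(frozen=True)
class CPDIResult:
    """Per-component subscores and total for one child."""

    subject_id: str
    age_group: AgeGroup
    component_scores: tuple[ComponentScore, ...]
    total: float
    missing_components: tuple[str, ...] = ()
    unknown_components: tuple[str, ...] = ()

    def subscore(self, component_id: str) -> float:
        for cs in self.component_scores:
            if cs.component_id == component_id:
                return cs.score
        raise KeyError(component_id)


@dataclass(frozen=True)
class ExcludedSubject:
    subject_id: str
    mean_energy: float
    reason: str  # "energy_below_minimum" | "energy_above_maximum"


@dataclass(frozen=True)
class SubjectReject:
    subject_id: str
    reason: str
    detail: str = ""


def _group_by_subject(records: Iterable[DailyIntakeRecord]) -> dict[str, list[DailyIntakeRecord]]:
    grouped: dict[str, list[DailyIntakeRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.subject_id, []).append(rec)
    return grouped


def filter_plausible_energy(
    records: Iterable[DailyIntakeRecord] | Mapping[str, Sequence[DailyIntakeRecord]],
    min_kcal: float = ENERGY_MIN_KCAL,
    max_kcal: float = ENERGY_MAX_KCAL,
) -> tuple[dict[str, list[DailyIntakeRecord]], list[ExcludedSubject]]:
    """Drop subjects with implausible mean daily energy intake.

    A subject is excluded iff their mean energy over all supplied days is
    strictly below ``min_kcal`` or strictly above ``max_kcal`` (defaults
    400 and 4000 kcal/d); means exactly on a bound are kept. Returns the
    kept records grouped by subject plus a machine-readable exclusion list.
    """
    grouped = dict(records) if isinstance(records, Mapping) else _group_by_subject(records)
    kept: dict[str, list[DailyIntakeRecord]] = {}
    excluded: list[ExcludedSubject] = []
    for sid, recs in grouped.items():
        if not recs:
            raise ValueError(f"subject {sid!r} has no records")
        mean_energy = sum(r.energy_kcal for r in recs) / len(recs)
        if mean_energy < min_kcal:
            excluded.append(ExcludedSubject(sid, mean_energy, "energy_below_minimum"))
        elif mean_energy > max_kcal:
            excluded.append(ExcludedSubject(sid, mean_energy, "energy_above_maximum"))
        else:
            kept[sid] = list(recs)
    return kept, excluded


def average_and_densify(
    records: Sequence[DailyIntakeRecord],
    components: Sequence[str] | None = None,
) -> DensityVector:
    """Average a subject's recall days and convert to per-1000-kcal densities.

    Uses the ratio of means: density = (mean daily amount / mean daily
    energy) x 1000, i.e. intakes are averaged across days first and the
    child is densified once. When ``components`` is given, components
    absent from every record get density 0 and are reported in
    ``missing_components``.
    """
    if not records:
        raise ValueError("need at least one record")
    sids = {r.subject_id for r in records}
    if len(sids) > 1:
        raise ValueError(f"records span multiple subjects: {sorted(sids)}")
    n = len(records)
    mean_energy = sum(r.energy_kcal for r in records) / n
    if mean_energy <= 0:
        raise DegenerateIntakeError(
            f"subject {records[0].subject_id!r}: mean energy is {mean_energy}; density undefined"
        )
    seen: set[str] = set()
    for r in records:
        seen.update(r.amounts.keys())
    wanted = list(components) if components is not None else sorted(seen)
    missing = tuple(c for c in wanted if c not in seen)
    densities = {}
    for cid in dict.fromkeys(list(wanted) + sorted(seen - set(wanted))):
        mean_amount = sum(r.amounts.get(cid, 0.0) for r in records) / n
        densities[cid] = mean_amount / mean_energy * 1000.0
    return DensityVector(
        subject_id=records[0].subject_id,
        mean_energy=mean_energy,
        densities=densities,
        n_days_used=n,
        missing_components=missing,
    )


def _check_category(standard: ComponentStandard, expected: Category) -> None:
    if standard.category is not expected:
        raise CategoryMismatchError(
            f"{standard.component_id} is a {standard.category.value} component; "
            f"use the {standard.category.value} rule"
        )


def _check_density(density: float) -> None:
    if not math.isfinite(density) or density < 0:
        raise ValueError(f"density must be finite and >= 0, got {density}")


def score_adequacy(density: float, standard: ComponentStandard, group: AgeGroup) -> float:
    """Proportional-to-recommendation score, capped at the maximum."""
    _check_category(standard, Category.ADEQUACY)
    _check_density(density)
    cut: AdequacyCutoffs = standard.cutoffs_for(group)
    if density >= cut.recommended:
        return float(standard.max_score)
    return density / cut.recommended * standard.max_score


def score_moderation(density: float, standard: ComponentStandard, group: AgeGroup) -> float:
    """Window score: full inside [lower, upper], zero at 0 and above 2 x upper."""
    _check_category(standard, Category.MODERATION)
    _check_density(density)
    cut: ModerationCutoffs = standard.cutoffs_for(group)
    M = standard.max_score
    if density == 0.0 or density > cut.zero_above:
        return 0.0
    if cut.lower <= density <= cut.upper:
        return float(M)
    bound = cut.lower if density < cut.lower else cut.upper
    raw = (1.0 - abs(1.0 - density / bound)) * M
    return min(max(raw, 0.0), float(M))


def score_limitation(density: float, standard: ComponentStandard, group: AgeGroup) -> float:
    """Restriction score: full at zero intake, zero at/above the limit."""
    _check_category(standard, Category.LIMITATION)
    _check_density(density)
    cut: LimitationCutoffs = standard.cutoffs_for(group)
    if density >= cut.limit:
        return 0.0
    return (1.0 - density / cut.limit) * standard.max_score


_RULES = {
    Category.ADEQUACY: score_adequacy,
    Category.MODERATION: score_moderation,
    Category.LIMITATION: score_limitation,
}


def score_component(density: float, standard: ComponentStandard, group: AgeGroup) -> float:
    """Dispatch to the category-appropriate scoring rule."""
    return _RULES[standard.category](density, standard, group)


def score_subject(
    profile: SubjectProfile,
    records: Sequence[DailyIntakeRecord],
    standard: IndexStandard,
) -> CPDIResult:
    """Score one child against a standard.

    Components missing from every recall day are scored as zero
    consumption (dropping them would silently shrink the 0-90 scale) and
    flagged; record amounts whose ids are not in the standard are ignored
    by scoring and reported in ``unknown_components``.
    """
    group = assign_age_group(profile.age_years)
    dv = average_and_densify(records, components=standard.component_ids)
    unknown = tuple(
        sorted(set(dv.densities) - set(standard.component_ids))
    )
    scores = []
    for comp in standard.components:
        d = dv.densities.get(comp.component_id, 0.0)
        s = score_component(d, comp, group)
        scores.append(ComponentScore(comp.component_id, d, s, float(comp.max_score)))
    total = sum(cs.score for cs in scores)
    return CPDIResult(
        subject_id=profile.subject_id,
        age_group=group,
        component_scores=tuple(scores),
        total=total,
        missing_components=dv.missing_components,
        unknown_components=unknown,
    )


def score_cohort(
    profiles: Iterable[SubjectProfile],
    records: Iterable[DailyIntakeRecord],
    standard: IndexStandard,
) -> tuple[list[CPDIResult], list[SubjectReject]]:
    """Score every scorable subject; collect per-subject failures.

    Output is sorted by subject id. Records without a profile, subjects
    without records, out-of-range ages and degenerate energies become
    entries in the rejects list instead of exceptions.
    """
    profile_map = {p.subject_id: p for p in profiles}
    grouped = _group_by_subject(records)
    rejects: list[SubjectReject] = []
    for sid in sorted(set(grouped) - set(profile_map)):
        rejects.append(SubjectReject(sid, "orphan_records", "no profile for subject"))
    results: list[CPDIResult] = []
    for sid in sorted(profile_map):
        recs = grouped.get(sid)
        if not recs:
            rejects.append(SubjectReject(sid, "no_records", "profile without recall records"))
            continue
        try:
            results.append(score_subject(profile_map[sid], recs, standard))
        except AgeOutOfRangeError as exc:
            rejects.append(SubjectReject(sid, "age_out_of_range", str(exc)))
        except DegenerateIntakeError as exc:
            rejects.append(SubjectReject(sid, "degenerate_energy", str(exc)))
    return results, rejects
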