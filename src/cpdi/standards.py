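"""Scoring standards for the Chinese Preschooler Dietary Index (CPDI).

The CPDI scores a child's diet on 11 components, each expressed as a
density (amount per 1000 kcal of energy intake) and compared against
age-specific cutoffs. Components fall into three categories:

* **adequacy** -- foods to consume sufficiently (vegetables, fruits, dairy,
  soybeans, aquatic products): full marks at or above a recommended
  density, proportional credit below it.
* **moderation** -- foods and nutrients to consume in a window (cereals,
  eggs, red meat and poultry, vitamin A, iron): full marks inside a
  recommended interval, zero at no consumption or beyond twice the upper
  bound, linear in between.
* **limitation** -- foods to restrict (high-sugar/high-fat snacks): full
  marks at zero consumption, declining linearly to zero at a limit density.

A standard is *data*, not code: the default ships as a YAML document and
users may load variant standards (different components, cutoffs or
weights) through the same schema. The default CPDI has 11 components whose
maximum subscores sum to 90 points, with separate cutoffs for children
aged 2-3 and 4-5 completed years.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import AgeOutOfRangeError, StandardInvariantError, StandardSchemaError

__all__ = [
    "AgeGroup",
    "AgeGroupSpec",
    "Category",
    "ComponentStandard",
    "AdequacyCutoffs",
    "ModerationCutoffs",
    "LimitationCutoffs",
    "IndexStandard",
    "assign_age_group",
    "default_cpdi_standard",
    "load_standard",
    "save_standard",
    "standard_to_mapping",
]


class Category(str, enum.Enum):
    """Scoring rule family a component belongs to."""

    ADEQUACY = "adequacy"
    MODERATION = "moderation"
    LIMITATION = "limitation"


class AgeGroup(str, enum.Enum):
    """Age stratum of the index: completed years 2-3 (young) or 4-5 (old)."""

    YOUNG = "young"
    OLD = "old"


@dataclass(frozen=True)
class AgeGroupSpec:
    """Metadata for one age group.

    ``energy_range_kcal`` is the guideline daily energy requirement band
    for the group (young: 1000-1200 kcal/d, old: 1200-1400 kcal/d). It is
    not used in scoring; the synthetic-cohort generator reads it to place
    simulated energy intakes.
    """

    group: AgeGroup
    ages: tuple[int, ...]
    energy_range_kcal: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.energy_range_kcal
        if not lo < hi:
            raise StandardInvariantError(
                f"age group {self.group.value}: energy range low must be < high, got {lo}, {hi}"
            )


@dataclass(frozen=True)
class AdequacyCutoffs:
    """Density at which an adequacy component reaches its maximum score."""

    recommended: float

    def __post_init__(self) -> None:
        if not self.recommended > 0:
            raise StandardInvariantError(
                f"adequacy recommended density must be > 0, got {self.recommended}"
            )


@dataclass(frozen=True)
class ModerationCutoffs:
    """Max-score interval [lower, upper] plus the zero-score density.

    ``zero_above`` must equal twice ``upper``: the linear decay
    (1 - |1 - density/upper|) reaches exactly zero there, so any other
    value would make the verbal zero rule contradict the formula.
    """

    lower: float
    upper: float
    zero_above: float

    def __post_init__(self) -> None:
        if not 0 < self.lower <= self.upper:
            raise StandardInvariantError(
                f"moderation cutoffs need 0 < lower <= upper, got {self.lower}, {self.upper}"
            )
        if not math.isclose(self.zero_above, 2 * self.upper, rel_tol=1e-12):
            raise StandardInvariantError(
                f"moderation zero_above must equal 2 x upper ({2 * self.upper}), got {self.zero_above}"
            )


@dataclass(frozen=True)
class LimitationCutoffs:
    """Density at/above which a limitation component scores zero.

    The same value is the denominator of the limitation formula."""

    limit: float

    def __post_init__(self) -> None:
        if not self.limit > 0:
            raise StandardInvariantError(f"limitation limit must be > 0, got {self.limit}")


_CUTOFF_TYPES: dict[Category, type] = {
    Category.ADEQUACY: AdequacyCutoffs,
    Category.MODERATION: ModerationCutoffs,
    Category.LIMITATION: LimitationCutoffs,
}


@dataclass(frozen=True)
class ComponentStandard:
    """One index component: identity, weight, unit and per-age-group cutoffs."""

    component_id: str
    display_name: str
    category: Category
    unit: str
    max_score: float
    cutoffs: Mapping[AgeGroup, AdequacyCutoffs | ModerationCutoffs | LimitationCutoffs]

    def __post_init__(self) -> None:
        if not self.max_score > 0:
            raise StandardInvariantError(
                f"{self.component_id}: max_score must be > 0, got {self.max_score}"
            )
        expected = _CUTOFF_TYPES[self.category]
        for group, cut in self.cutoffs.items():
            if not isinstance(cut, expected):
                raise StandardInvariantError(
                    f"{self.component_id}: {self.category.value} component has "
                    f"{type(cut).__name__} cutoffs for group {group.value}"
                )

    def cutoffs_for(self, group: AgeGroup):
        try:
            return self.cutoffs[group]
        except KeyError:
            raise StandardSchemaError(
                f"no cutoffs for age group {group.value}", component=self.component_id
            ) from None


@dataclass(frozen=True)
class IndexStandard:
    """An ordered collection of components plus age-group metadata."""

    name: str
    components: tuple[ComponentStandard, ...]
    age_groups: Mapping[AgeGroup, AgeGroupSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.component_id for c in self.components]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StandardInvariantError(f"duplicate component ids: {dupes}")

    @property
    def component_ids(self) -> tuple[str, ...]:
        return tuple(c.component_id for c in self.components)

    @property
    def max_total(self) -> float:
        return float(sum(c.max_score for c in self.components))

    def component(self, component_id: str) -> ComponentStandard:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(component_id)


def assign_age_group(age_years: float) -> AgeGroup:
    """Map an age in completed years to the index's age stratum.

    Fractional ages are floored (2.9 years -> the "2 years" band, matching
    survey age banding). Ages outside [2, 5] are outside the index's
    domain and raise :class:`AgeOutOfRangeError`.
    """
    if not math.isfinite(age_years):
        raise AgeOutOfRangeError(f"age must be finite, got {age_years}")
    completed = math.floor(age_years)
    if completed in (2, 3):
        return AgeGroup.YOUNG
    if completed in (4, 5):
        return AgeGroup.OLD
    raise AgeOutOfRangeError(
        f"the index is defined for completed ages 2-5; got {age_years}"
    )


# ---------------------------------------------------------------------------
# serialization

def _require(mapping: Mapping[str, Any], key: str, component: str | None, kind: str):
    if key not in mapping:
        raise StandardSchemaError(f"missing {kind} field {key!r}", component=component, field=key)
    return mapping[key]


def _num(value: Any, component: str | None, field_name: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise StandardSchemaError(
            f"expected a number, got {value!r}", component=component, field=field_name
        )
    return float(value)


def _parse_cutoffs(category: Category, doc: Mapping[str, Any], component: str):
    if not isinstance(doc, Mapping):
        raise StandardSchemaError("cutoffs must be a mapping", component=component, field="cutoffs")
    if category is Category.ADEQUACY:
        return AdequacyCutoffs(
            recommended=_num(_require(doc, "recommended", component, "adequacy cutoff"),
                             component, "recommended")
        )
    if category is Category.MODERATION:
        return ModerationCutoffs(
            lower=_num(_require(doc, "lower", component, "moderation cutoff"), component, "lower"),
            upper=_num(_require(doc, "upper", component, "moderation cutoff"), component, "upper"),
            zero_above=_num(_require(doc, "zero_above", component, "moderation cutoff"),
                            component, "zero_above"),
        )
    return LimitationCutoffs(
        limit=_num(_require(doc, "limit", component, "limitation cutoff"), component, "limit")
    )


def _parse_standard(doc: Mapping[str, Any]) -> IndexStandard:
    if not isinstance(doc, Mapping):
        raise StandardSchemaError("standard document must be a mapping")
    name = str(_require(doc, "name", None, "standard"))

    age_groups: dict[AgeGroup, AgeGroupSpec] = {}
    for key, spec in (doc.get("age_groups") or {}).items():
        try:
            group = AgeGroup(key)
        except ValueError:
            raise StandardSchemaError(f"unknown age group {key!r}", field="age_groups") from None
        ages = tuple(int(a) for a in _require(spec, "ages", None, "age group"))
        lo, hi = _require(spec, "energy_range_kcal", None, "age group")
        age_groups[group] = AgeGroupSpec(group, ages, (float(lo), float(hi)))

    raw_components = _require(doc, "components", None, "standard")
    if not isinstance(raw_components, list) or not raw_components:
        raise StandardSchemaError("'components' must be a non-empty list", field="components")

    components = []
    for entry in raw_components:
        cid = str(_require(entry, "id", None, "component"))
        cat_raw = _require(entry, "category", cid, "component")
        try:
            category = Category(cat_raw)
        except ValueError:
            raise StandardSchemaError(
                f"unknown category {cat_raw!r}", component=cid, field="category"
            ) from None
        cut_doc = _require(entry, "cutoffs", cid, "component")
        cutoffs = {}
        for gkey, gdoc in cut_doc.items():
            try:
                group = AgeGroup(gkey)
            except ValueError:
                raise StandardSchemaError(
                    f"unknown age group {gkey!r}", component=cid, field="cutoffs"
                ) from None
            cutoffs[group] = _parse_cutoffs(category, gdoc, cid)
        components.append(
            ComponentStandard(
                component_id=cid,
                display_name=str(entry.get("name", cid)),
                category=category,
                unit=str(_require(entry, "unit", cid, "component")),
                max_score=_num(_require(entry, "max_score", cid, "component"), cid, "max_score"),
                cutoffs=cutoffs,
            )
        )
    return IndexStandard(name=name, components=tuple(components), age_groups=age_groups)


def _fmt_num(x: float) -> float | int:
    return int(x) if float(x).is_integer() else float(x)


def standard_to_mapping(standard: IndexStandard) -> dict[str, Any]:
    """Serialize a standard to the plain mapping form of the YAML schema."""
    doc: dict[str, Any] = {"name": standard.name, "age_groups": {}, "components": []}
    for group in AgeGroup:
        if group in standard.age_groups:
            spec = standard.age_groups[group]
            doc["age_groups"][group.value] = {
                "ages": list(spec.ages),
                "energy_range_kcal": [_fmt_num(v) for v in spec.energy_range_kcal],
            }
    for comp in standard.components:
        cuts: dict[str, Any] = {}
        for group in AgeGroup:
            if group not in comp.cutoffs:
                continue
            cut = comp.cutoffs[group]
            if isinstance(cut, AdequacyCutoffs):
                cuts[group.value] = {"recommended": _fmt_num(cut.recommended)}
            elif isinstance(cut, ModerationCutoffs):
                cuts[group.value] = {
                    "lower": _fmt_num(cut.lower),
                    "upper": _fmt_num(cut.upper),
                    "zero_above": _fmt_num(cut.zero_above),
                }
            else:
                cuts[group.value] = {"limit": _fmt_num(cut.limit)}
        doc["components"].append(
            {
                "id": comp.component_id,
                "name": comp.display_name,
                "category": comp.category.value,
                "unit": comp.unit,
                "max_score": _fmt_num(comp.max_score),
                "cutoffs": cuts,
            }
        )
    return doc


def load_standard(source: str | Path | Mapping[str, Any]) -> IndexStandard:
    """Load and validate a standard from a YAML document.

    ``source`` may be a filesystem path, a YAML string, or an
    already-parsed mapping. Schema violations raise
    :class:`StandardSchemaError` naming the offending component and field;
    structural violations (e.g. lower > upper) raise
    :class:`StandardInvariantError`.
    """
    if isinstance(source, Mapping):
        return _parse_standard(source)
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    return _parse_standard(yaml.safe_load(text))


def save_standard(standard: IndexStandard, path: str | Path | None = None) -> str:
    """Serialize a standard to YAML; deterministic field order.

    Returns the YAML text; also writes it to ``path`` when given.
    ``load_standard(save_standard(s))`` reproduces ``s`` exactly.
    """
    text = yaml.safe_dump(standard_to_mapping(standard), sort_keys=False, allow_unicode=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


_DEFAULT_CACHE: IndexStandard | None = None


def default_cpdi_standard() -> IndexStandard:
    """The default CPDI standard: 11 components, 90 points total.

    Loaded from the packaged YAML document; returned objects are frozen
    dataclasses, so the cached instance is safe to share.
    """
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        text = resources.files("cpdi.data").joinpath("cpdi_default.yaml").read_text("utf-8")
        std = load_standard(text)
        if len(std.components) != 11 or std.max_total != 90:
            raise StandardInvariantError(
                "packaged default must have 11 components totalling 90 points"
            )
        _DEFAULT_CACHE = std
    return _DEFAULT_CACHE
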