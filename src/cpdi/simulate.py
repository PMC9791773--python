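"""Synthetic survey-like cohorts with known ground truth.

Real multi-province recall surveys of Chinese preschoolers are
application-gated, so this module generates cohorts with the same shape:
one profile per child (age 2-5, sex, urban/rural residence, income band,
household size) and three consecutive 24-h recall days per child, each
carrying energy and per-component amounts.

The generative model, per child:

* demographics drawn from configurable marginals (defaults emulate the
  survey the index was developed on: 54.1% boys, 28.0% urban, income
  bands 41.2 / 27.5 / 21.0 / 5.7 / 4.6%);
* a true mean daily energy, log-normal with median at the midpoint of
  the age group's guideline energy band;
* a true density (amount per 1000 kcal) per component from a
  zero-inflated log-normal — zero-inflation captures the pronounced
  non-consumption of foods like dairy (roughly 7 in 10 children consume
  none over three days), log-normality the right skew of intake data;
* urban residence and income band shift the log-density location of
  selected components, so diet quality rises with urbanicity and income
  as observed in practice;
* each recall day realizes energy and amounts around the child's truth
  with multiplicative log-normal day-to-day noise; with the noise scale
  at zero, densifying a child's records returns the true densities
  exactly.

Randomness is a single seed split hierarchically, one stream per child,
so enlarging a cohort never perturbs earlier children's draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import DailyIntakeRecord, SubjectProfile
from .standards import AgeGroup, IndexStandard, assign_age_group, default_cpdi_standard

__all__ = [
    "DensityModel",
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_targeted_subject",
    "generate_factor_subscores",
    "INCOME_BANDS",
]

INCOME_BANDS = ("low", "lower_middle", "middle", "upper_middle", "high")


@dataclass(frozen=True)
class DensityModel:
    """Zero-inflated log-normal density model for one component.

    ``median`` is the log-normal median (units per 1000 kcal) among
    consumers; ``sigma`` the log-scale SD; ``zero_prob`` the probability
    of zero consumption across all recall days.
    """

    median: float
    sigma: float
    zero_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.median < 0 or self.sigma < 0 or not 0 <= self.zero_prob <= 1:
            raise ValueError(f"invalid density model: {self}")


# Component density defaults (units per 1000 kcal among consumers) chosen
# to mirror the consumption pattern reported for Chinese preschoolers:
# cereal-heavy diets, widespread non-consumption of dairy, fruit and
# aquatic products, generous red meat, near-zero snack reporting, adequate
# iron, low vitamin A.
_DEFAULT_DENSITY_MODELS: dict[str, DensityModel] = {
    "vegetables": DensityModel(100.0, 0.6, 0.05),
    "fruits": DensityModel(40.0, 0.9, 0.50),
    "dairy": DensityModel(130.0, 0.9, 0.693),
    "soybeans": DensityModel(10.0, 1.0, 0.35),
    "aquatic_products": DensityModel(8.0, 1.0, 0.55),
    "cereals": DensityModel(150.0, 0.35, 0.0),
    "eggs": DensityModel(15.0, 0.7, 0.30),
    "red_meat_poultry": DensityModel(60.0, 0.6, 0.15),
    "vitamin_a": DensityModel(140.0, 0.7, 0.02),
    "iron": DensityModel(12.0, 0.4, 0.0),
    "snacks": DensityModel(20.0, 0.8, 0.85),
}

# Additive shifts of log-density location for urban residence and per
# income step above the lowest band; concentrated on the foods whose
# consumption rises most with affluence.
_DEFAULT_URBAN_SHIFT: dict[str, float] = {
    "fruits": 0.30,
    "dairy": 0.40,
    "aquatic_products": 0.25,
    "vegetables": 0.10,
    "eggs": 0.15,
    "vitamin_a": 0.15,
}
_DEFAULT_INCOME_SHIFT: dict[str, float] = {
    "fruits": 0.12,
    "dairy": 0.15,
    "aquatic_products": 0.10,
    "vegetables": 0.04,
    "eggs": 0.06,
    "vitamin_a": 0.05,
}

# Unscored nutrients per 1000 kcal (for adequacy-ratio demonstrations).
_DEFAULT_EXTRA_NUTRIENTS: dict[str, DensityModel] = {
    "fiber_g": DensityModel(3.5, 0.5, 0.0),
    "calcium_mg": DensityModel(250.0, 0.6, 0.0),
    "zinc_mg": DensityModel(5.0, 0.4, 0.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic cohort."""

    n_subjects: int = 100
    seed: int = 0
    age_probs: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.225, 3: 0.247, 4: 0.250, 5: 0.278}
    )
    male_prop: float = 0.541
    urban_prop: float = 0.280
    income_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(
            zip(INCOME_BANDS, (0.412, 0.275, 0.210, 0.057, 0.046))
        )
    )
    density_models: Mapping[str, DensityModel] = field(
        default_factory=lambda: dict(_DEFAULT_DENSITY_MODELS)
    )
    urban_log_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_URBAN_SHIFT)
    )
    income_log_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INCOME_SHIFT)
    )
    extra_nutrient_models: Mapping[str, DensityModel] = field(
        default_factory=lambda: dict(_DEFAULT_EXTRA_NUTRIENTS)
    )
    energy_sigma: float = 0.15
    n_days: int = 3
    day_sigma: float = 0.20

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.energy_sigma < 0 or self.day_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        for label, probs in (("age_probs", self.age_probs), ("income_probs", self.income_probs)):
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{label} must sum to 1, got {total}")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{label} must be nonnegative")
        for p in (self.male_prop, self.urban_prop):
            if not 0 <= p <= 1:
                raise ValueError("proportions must lie in [0, 1]")

    def noiseless(self) -> "GeneratorConfig":
        """Copy with zero day-to-day variation (densities recover exactly)."""
        return replace(self, day_sigma=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """True per-subject latent values behind a generated cohort."""

    config: GeneratorConfig
    true_densities: Mapping[str, Mapping[str, float]]  # subject -> component -> density
    true_mean_energy: Mapping[str, float]


def _energy_midpoint(age_years: int, standard: IndexStandard) -> float:
    group = assign_age_group(age_years)
    spec = standard.age_groups.get(group)
    if spec is None:
        return 1100.0 if group is AgeGroup.YOUNG else 1300.0
    lo, hi = spec.energy_range_kcal
    return (lo + hi) / 2.0


def generate_cohort(
    config: GeneratorConfig,
    standard: IndexStandard | None = None,
) -> tuple[list[SubjectProfile], list[DailyIntakeRecord], GroundTruth]:
    """Draw a cohort of profiles and recall records; deterministic per seed."""
    standard = standard or default_cpdi_standard()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_subjects)

    ages = sorted(config.age_probs)
    age_p = [config.age_probs[a] for a in ages]
    bands = [b for b in INCOME_BANDS if b in config.income_probs]
    band_p = [config.income_probs[b] for b in bands]

    width = len(str(config.n_subjects))
    profiles: list[SubjectProfile] = []
    records: list[DailyIntakeRecord] = []
    densities_truth: dict[str, dict[str, float]] = {}
    energy_truth: dict[str, float] = {}

    for i, child_seed in enumerate(children):
        rng = np.random.default_rng(child_seed)
        sid = f"S{i + 1:0{width}d}"
        age = int(rng.choice(ages, p=age_p))
        sex = "male" if rng.random() < config.male_prop else "female"
        residence = "urban" if rng.random() < config.urban_prop else "rural"
        income = str(rng.choice(bands, p=band_p))
        household = int(rng.integers(2, 8))
        profiles.append(
            SubjectProfile(sid, age, sex, residence, income, household)
        )

        mean_energy = _energy_midpoint(age, standard) * math.exp(
            rng.normal(0.0, config.energy_sigma)
        )
        income_step = bands.index(income)
        true_d: dict[str, float] = {}
        for cid, model in config.density_models.items():
            if rng.random() < model.zero_prob:
                true_d[cid] = 0.0
                continue
            shift = 0.0
            if residence == "urban":
                shift += config.urban_log_shift.get(cid, 0.0)
            shift += income_step * config.income_log_shift.get(cid, 0.0)
            true_d[cid] = model.median * math.exp(shift + rng.normal(0.0, model.sigma))
        extra_d = {
            name: model.median * math.exp(rng.normal(0.0, model.sigma))
            for name, model in config.extra_nutrient_models.items()
        }
        densities_truth[sid] = true_d
        energy_truth[sid] = mean_energy

        for day in range(1, config.n_days + 1):
            e_day = mean_energy * math.exp(rng.normal(0.0, config.day_sigma))
            amounts = {}
            for cid, d in true_d.items():
                noise = math.exp(rng.normal(0.0, config.day_sigma)) if config.day_sigma else 1.0
                amounts[cid] = d * e_day / 1000.0 * noise
            extras = {}
            for name, d in extra_d.items():
                noise = math.exp(rng.normal(0.0, config.day_sigma)) if config.day_sigma else 1.0
                extras[name] = d * e_day / 1000.0 * noise
            records.append(
                DailyIntakeRecord(sid, day, e_day, amounts, extras)
            )

    truth = GroundTruth(config, densities_truth, energy_truth)
    return profiles, records, truth


def generate_targeted_subject(
    age_years: int,
    densities: Mapping[str, float],
    energy_kcal: float = 1200.0,
    n_days: int = 3,
    subject_id: str = "target",
) -> tuple[SubjectProfile, list[DailyIntakeRecord]]:
    """A noiseless subject whose averaged densities equal ``densities`` exactly.

    Used to replay worked examples: every recall day carries the same
    energy and amount = density x energy / 1000, so the ratio-of-means
    densification is an exact inverse.
    """
    if energy_kcal <= 0:
        raise ValueError("energy must be > 0")
    for cid, d in densities.items():
        if d < 0:
            raise ValueError(f"density for {cid!r} must be >= 0")
    profile = SubjectProfile(subject_id, age_years)
    amounts = {cid: d * energy_kcal / 1000.0 for cid, d in densities.items()}
    records = [
        DailyIntakeRecord(subject_id, day, energy_kcal, dict(amounts))
        for day in range(1, n_days + 1)
    ]
    return profile, records


def generate_factor_subscores(
    n: int, k: int, loading: float, seed: int
) -> pd.DataFrame:
    """One-common-factor item matrix: X_j = loading*F + sqrt(1-loading^2)*eps_j.

    All items load equally on a single standard-normal factor, so the
    population inter-item correlation is loading**2 and standardized
    Cronbach's alpha equals the Spearman-Brown value
    k*loading^2 / (1 + (k-1)*loading^2) — a closed-form target for
    reliability-recovery tests.
    """
    if not 0 <= loading <= 1:
        raise ValueError("loading must be in [0, 1]")
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 and k >= 2")
    rng = np.random.default_rng(seed)
    factor = rng.standard_normal(n)
    eps = rng.standard_normal((n, k))
    data = loading * factor[:, None] + math.sqrt(1.0 - loading**2) * eps
    cols = [f"item_{j + 1:02d}" for j in range(k)]
    return pd.DataFrame(data, columns=cols, index=[f"S{i + 1}" for i in range(n)])
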