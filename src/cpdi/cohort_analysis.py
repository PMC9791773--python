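"""Cohort-level statistics: categorization, adequacy ratios, reliability, validity.

These procedures summarize a scored cohort the way diet-quality indices
are conventionally evaluated:

* total-score categorization into low / medium / high by the cohort's
  25th and 75th percentiles (ties at a boundary fall in the inclusive
  medium band);
* nutrient adequacy ratios (NAR): daily intake over the recommended
  amount, truncated at 1;
* item-rest Spearman correlations (each component subscore against the
  total minus that component) and the full pairwise subscore correlation
  matrix;
* Cronbach's alpha, both raw (covariance-based) and standardized
  (mean-correlation-based) — reported side by side because field usage of
  "standard" vs "nonstandard" alpha is inconsistent;
* PCA of the subscore correlation matrix: eigenvalues, the Kaiser
  eigenvalue-greater-than-1 count, and that count's cumulative variance
  share.

Percentiles use numpy's linear-interpolation convention; Spearman ties
receive average ranks. Subscores have unequal ranges (10 vs 2.5 points),
so PCA is run on the correlation matrix, not the covariance matrix.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .scoring import CPDIResult

__all__ = [
    "QualityCategory",
    "CategorizedCohort",
    "ItemRestResult",
    "PCAResult",
    "CohortReport",
    "subscore_matrix",
    "categorize",
    "nutrient_adequacy_ratio",
    "item_rest_correlations",
    "cronbach_alpha",
    "pca_dimensions",
    "correlate_with_nutrients",
    "build_cohort_report",
    "report_from_subscores",
]


class QualityCategory(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


@dataclass(frozen=True)
class CategorizedCohort:
    categories: tuple[QualityCategory, ...]
    p25: float
    p75: float

    def counts(self) -> dict[str, int]:
        return {
            cat.value: sum(1 for c in self.categories if c is cat)
            for cat in QualityCategory
        }


@dataclass(frozen=True)
class ItemRestResult:
    """Item-rest Spearman r per component plus the pairwise matrix."""

    item_rest: "pd.Series"
    item_rest_p: "pd.Series"
    pairwise: "pd.DataFrame"
    undefined: tuple[str, ...] = ()


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: tuple[float, ...]
    n_eigen_gt_1: int
    cumulative_variance_top_k: float
    dropped_components: tuple[str, ...] = ()


@dataclass(frozen=True)
class CohortReport:
    """Everything the cohort-level analysis computes, in one bundle."""

    n_subjects: int
    mean_total: float
    sd_total: float
    median_total: float
    p25: float
    p75: float
    category_counts: Mapping[str, int]
    component_medians: Mapping[str, tuple[float, float, float]]  # median, P25, P75
    alpha_raw: float
    alpha_standardized: float
    item_rest: Mapping[str, float]
    pca_eigenvalues: tuple[float, ...]
    n_eigen_gt_1: int
    cumulative_variance_top_k: float
    nutrient_correlations: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "total_score": {
                "mean": self.mean_total,
                "sd": self.sd_total,
                "median": self.median_total,
                "p25": self.p25,
                "p75": self.p75,
            },
            "category_counts": dict(self.category_counts),
            "component_medians": {
                k: {"median": v[0], "p25": v[1], "p75": v[2]}
                for k, v in self.component_medians.items()
            },
            "reliability": {
                "alpha_raw": self.alpha_raw,
                "alpha_standardized": self.alpha_standardized,
                "item_rest_spearman": dict(self.item_rest),
            },
            "pca": {
                "eigenvalues": list(self.pca_eigenvalues),
                "n_eigen_gt_1": self.n_eigen_gt_1,
                "cumulative_variance_top_k": self.cumulative_variance_top_k,
            },
            "nutrient_correlations": {
                k: {"r": v[0], "p": v[1]} for k, v in self.nutrient_correlations.items()
            },
        }


def subscore_matrix(results: Iterable[CPDIResult]) -> pd.DataFrame:
    """Subjects x components DataFrame of subscores, indexed by subject id."""
    rows = {}
    for res in results:
        rows[res.subject_id] = {cs.component_id: cs.score for cs in res.component_scores}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def categorize(totals: Sequence[float]) -> CategorizedCohort:
    """Split totals into low (< P25), medium (P25..P75 inclusive), high (> P75).

    Percentiles are the empirical linear-interpolation quantiles of the
    supplied totals. With fewer than 4 subjects quartiles are not
    meaningful and an :class:`InsufficientDataError` is raised.
    """
    arr = np.asarray(list(totals), dtype=float)
    if arr.size < 4:
        raise InsufficientDataError(f"categorization needs >= 4 subjects, got {arr.size}")
    p25, p75 = np.percentile(arr, [25, 75])
    cats = tuple(
        QualityCategory.LOW if t < p25
        else QualityCategory.HIGH if t > p75
        else QualityCategory.MEDIUM
        for t in arr
    )
    return CategorizedCohort(cats, float(p25), float(p75))


def nutrient_adequacy_ratio(actual, recommended):
    """NAR = actual daily intake / recommended amount, truncated at 1.

    Accepts scalars or arrays; ``recommended`` must be positive.
    """
    actual_arr = np.asarray(actual, dtype=float)
    rec_arr = np.asarray(recommended, dtype=float)
    if np.any(rec_arr <= 0):
        raise ValueError("recommended intake must be > 0")
    if np.any(actual_arr < 0):
        raise ValueError("actual intake must be >= 0")
    nar = np.minimum(actual_arr / rec_arr, 1.0)
    return float(nar) if nar.ndim == 0 else nar


def item_rest_correlations(m: pd.DataFrame) -> ItemRestResult:
    """Spearman r of each subscore against the total minus that subscore.

    Also returns the pairwise Spearman matrix of all components. A
    zero-variance column yields an undefined (NaN) correlation and is
    flagged rather than fabricated.
    """
    if m.shape[0] < 3 or m.shape[1] < 2:
        raise InsufficientDataError(
            f"item-rest needs >= 3 subjects and >= 2 components, got {m.shape}"
        )
    totals = m.sum(axis=1)
    rs, ps, undefined = {}, {}, []
    for col in m.columns:
        rest = totals - m[col]
        if m[col].nunique() < 2 or rest.nunique() < 2:
            rs[col], ps[col] = float("nan"), float("nan")
            undefined.append(col)
            continue
        r, p = stats.spearmanr(m[col], rest)
        rs[col], ps[col] = float(r), float(p)
    pairwise = m.corr(method="spearman")
    return ItemRestResult(
        item_rest=pd.Series(rs, name="item_rest_spearman"),
        item_rest_p=pd.Series(ps, name="p_value"),
        pairwise=pairwise,
        undefined=tuple(undefined),
    )


def cronbach_alpha(m: pd.DataFrame, standardized: bool = False) -> float:
    """Internal-consistency reliability of the component subscores.

    Raw form: alpha = k/(k-1) * (1 - sum(item variances) / var(total)).
    Standardized form: alpha = k*rbar / (1 + (k-1)*rbar), with rbar the
    mean pairwise Pearson correlation between items.

    Variances are sample variances (ddof=1); the two forms coincide when
    all items share one variance.
    """
    if m.shape[1] < 2 or m.shape[0] < 3:
        raise InsufficientDataError(
            f"alpha needs >= 2 components and >= 3 subjects, got {m.shape}"
        )
    k = m.shape[1]
    if standardized:
        corr = m.corr(method="pearson").to_numpy()
        iu = np.triu_indices(k, 1)
        rbar = float(np.nanmean(corr[iu]))
        return k * rbar / (1.0 + (k - 1) * rbar)
    total_var = float(m.sum(axis=1).var(ddof=1))
    if total_var == 0:
        raise InsufficientDataError("total score has zero variance; alpha undefined")
    item_var = float(m.var(ddof=1).sum())
    return k / (k - 1) * (1.0 - item_var / total_var)


def pca_dimensions(m: pd.DataFrame) -> PCAResult:
    """Eigen-structure of the subscore correlation matrix.

    Constant columns are dropped with a warning (their correlations are
    undefined). Returns eigenvalues in descending order, the count with
    eigenvalue > 1 (Kaiser's rule), and the cumulative share of variance
    those components explain. Eigenvalues of a correlation matrix sum to
    the number of retained components.
    """
    constant = [c for c in m.columns if m[c].nunique() < 2]
    if constant:
        import warnings

        warnings.warn(
            f"dropping constant subscore columns before PCA: {constant}", stacklevel=2
        )
        m = m.drop(columns=constant)
    if m.shape[0] < m.shape[1] + 1:
        raise InsufficientDataError(
            f"PCA needs more subjects than components, got {m.shape}"
        )
    corr = m.corr(method="pearson").to_numpy()
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)  # clip tiny negative round-off
    n_gt_1 = int(np.sum(eig > 1.0))
    cum = float(eig[:n_gt_1].sum() / eig.sum()) if n_gt_1 else 0.0
    return PCAResult(
        eigenvalues=tuple(float(v) for v in eig),
        n_eigen_gt_1=n_gt_1,
        cumulative_variance_top_k=cum,
        dropped_components=tuple(constant),
    )


def correlate_with_nutrients(
    totals: pd.Series, nutrient_table: pd.DataFrame
) -> pd.DataFrame:
    """Spearman r and two-sided p of the total score against each nutrient column.

    ``totals`` and ``nutrient_table`` must be indexed by the same subjects.
    """
    if not totals.index.sort_values().equals(nutrient_table.index.sort_values()):
        raise ValueError("totals and nutrient table cover different subjects")
    nutrient_table = nutrient_table.loc[totals.index]
    out = {}
    for col in nutrient_table.columns:
        r, p = stats.spearmanr(totals, nutrient_table[col])
        out[col] = {"r": float(r), "p": float(p)}
    return pd.DataFrame.from_dict(out, orient="index")


def build_cohort_report(
    results: Sequence[CPDIResult],
    nutrient_table: pd.DataFrame | None = None,
) -> CohortReport:
    """Assemble the full cohort summary from scored subjects."""
    return report_from_subscores(subscore_matrix(results), nutrient_table)


def report_from_subscores(
    m: pd.DataFrame,
    nutrient_table: pd.DataFrame | None = None,
) -> CohortReport:
    """Assemble the cohort summary from a subjects x components subscore matrix."""
    totals = m.sum(axis=1)
    cat = categorize(totals.to_numpy())
    item = item_rest_correlations(m)
    pca = pca_dimensions(m)
    medians = {
        col: tuple(float(v) for v in np.percentile(m[col], [50, 25, 75]))
        for col in m.columns
    }
    nutrients: dict[str, tuple[float, float]] = {}
    if nutrient_table is not None:
        corr = correlate_with_nutrients(totals, nutrient_table)
        nutrients = {idx: (row["r"], row["p"]) for idx, row in corr.iterrows()}
    return CohortReport(
        n_subjects=m.shape[0],
        mean_total=float(totals.mean()),
        sd_total=float(totals.std(ddof=1)),
        median_total=float(totals.median()),
        p25=cat.p25,
        p75=cat.p75,
        category_counts=cat.counts(),
        component_medians=medians,
        alpha_raw=cronbach_alpha(m, standardized=False),
        alpha_standardized=cronbach_alpha(m, standardized=True),
        item_rest={k: float(v) for k, v in item.item_rest.items()},
        pca_eigenvalues=pca.eigenvalues,
        n_eigen_gt_1=pca.n_eigen_gt_1,
        cumulative_variance_top_k=pca.cumulative_variance_top_k,
        nutrient_correlations=nutrients,
    )
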