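"""Patient-characteristics statistics: subgroup proportions and association
tests for the cohort table (sex/location/stage by MSI status, etc.)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError, round_half_up


@dataclass
class ProportionResult:
    count: int
    total: int
    percent: float  # full precision
    percent_display: int  # half-up integer rounding

    @property
    def undefined(self) -> bool:
        return self.total == 0


def group_proportion(mask_condition, mask_subgroup=None) -> ProportionResult:
    """Percentage of a subgroup meeting a condition.

    Both arguments are boolean masks over the same units (typically one row
    per person).  ``mask_subgroup=None`` means the whole collection.  An
    empty subgroup yields an undefined-flagged result (percent NaN).
    """
    cond = np.asarray(mask_condition, dtype=bool)
    sub = np.ones_like(cond) if mask_subgroup is None else np.asarray(mask_subgroup, dtype=bool)
    if cond.shape != sub.shape:
        raise ValidationError("condition and subgroup masks must be the same length")
    total = int(sub.sum())
    count = int((cond & sub).sum())
    if total == 0:
        return ProportionResult(0, 0, float("nan"), 0)
    pct = 100.0 * count / total
    return ProportionResult(count, total, pct, int(round_half_up(pct)))


def persons_table(sheet: pd.DataFrame) -> pd.DataFrame:
    """One row per person (person-level covariates are constant within person)."""
    return sheet.drop_duplicates("person_id").reset_index(drop=True)


@dataclass
class AssociationResult:
    statistic: float | None
    p: float
    method: str
    flags: list

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags


def association_test(table, method: str = "pearson") -> AssociationResult:
    """Association test on an r x c count table.

    ``pearson`` is the uncorrected chi-square, ``yates`` the
    continuity-corrected chi-square (2x2 only), ``fisher`` the exact test
    (2x2 only).  A zero row/column margin flags the result degenerate
    (statistic 0, p 1).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValidationError("counts must be non-negative integers")
    if t.sum() == 0:
        raise ValidationError("contingency table total must be positive")
    if method not in ("pearson", "yates", "fisher"):
        raise ValidationError(f"unknown method {method!r}")
    if method in ("yates", "fisher") and t.shape != (2, 2):
        raise ValidationError(f"{method} test supports 2x2 tables only")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return AssociationResult(0.0, 1.0, method, ["degenerate"])

    if method == "fisher":
        _, p = stats.fisher_exact(t.astype(int))
        return AssociationResult(None, float(p), method, [])
    chi2, p, _, _ = stats.chi2_contingency(t, correction=(method == "yates"))
    return AssociationResult(float(chi2), float(p), method, [])


def continuous_group_test(values, groups) -> tuple[float, float, list]:
    """One-way ANOVA of a continuous variable across groups (F, p, flags).

    For two groups, F equals the squared pooled-variance two-sample t.
    Groups with fewer than 2 values flag the result rather than raising.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    arrays = [values[groups == g] for g in pd.unique(groups)]
    if len(arrays) < 2:
        raise ValidationError("need at least 2 groups")
    flags = []
    if any(len(a) < 2 for a in arrays):
        flags.append("small_group")
        return float("nan"), float("nan"), flags
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p), flags


def cohort_table(sheet: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Patient-characteristics report: counts by MSI status with a p-value
    per characteristic (association test for categoricals, one-way ANOVA
    for age)."""
    persons = persons_table(sheet)
    msi = persons["msi_status"] == "MSI"
    rows = []
    for char, col in (("Sex", "sex"), ("Location", "location"), ("Stage", "stage")):
        counts = pd.crosstab(persons[col], msi)
        counts = counts.reindex(columns=[False, True], fill_value=0)
        res = association_test(counts.to_numpy(), method=method)
        for k, level in enumerate(counts.index):
            rows.append(
                {
                    "characteristic": char,
                    "category": str(level),
                    "MSS": int(counts.iloc[k, 0]),
                    "MSI": int(counts.iloc[k, 1]),
                    "p": res.p if k == 0 else np.nan,
                    "method": res.method if k == 0 else "",
                }
            )
    f, p, _ = continuous_group_test(persons["age"], msi)
    rows.append(
        {
            "characteristic": "Age",
            "category": "mean (SD)",
            "MSS": round(float(persons.loc[~msi, "age"].mean()), 2),
            "MSI": round(float(persons.loc[msi, "age"].mean()), 2),
            "p": p,
            "method": "anova",
        }
    )
    return pd.DataFrame(rows)
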