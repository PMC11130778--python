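"""Demographic association screens.

Per assessment: Spearman rank correlation against age and against years
of education (education levels mapped to years via a documented,
overridable table), and two-sided Wilcoxon rank-sum tests for the gender
(male vs female) and race (White vs people of color) dichotomies.
Participants outside a dichotomy and declined responses are dropped
pairwise.  Significance is judged at α = .05 with no multiple-comparison
correction, matching the exploratory design of the reference study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import StudyDataset
from .descriptives import is_person_of_color
from .errors import ConfigError
from .registry import Registry

ALPHA = 0.05

#: Highest-level-attained -> years of schooling.  The mapping is a design
#: choice (the reference study does not print one); override by passing
#: your own dict to education_to_years.
EDUCATION_YEARS = {
    "never_attended": 0.0,
    "kindergarten": 1.0,
    "elementary": 6.0,
    "middle_school": 8.0,
    "high_school_or_ged": 12.0,
    "some_college": 13.0,
    "associate_or_vocational": 14.0,
    "bachelor": 16.0,
    "master": 18.0,
    "doctoral_or_professional": 20.0,
}

#: combined group size at or below which the rank-sum null distribution is
#: enumerated exactly (ties permitting) rather than normal-approximated.
EXACT_RANKSUM_MAX_N = 25


@dataclass(frozen=True)
class AssociationResult:
    assessment: str
    covariate: str  # age | education_years | gender | race
    test: str       # spearman | wilcoxon_rank_sum
    statistic: float
    p_value: float
    n: int
    significant: bool
    evaluable: bool = True
    note: str = ""


def education_to_years(level: str, mapping: dict | None = None) -> float:
    """Map an education level to years of schooling; declined -> NaN."""
    mapping = mapping or EDUCATION_YEARS
    if level == "declined":
        return math.nan
    try:
        return float(mapping[level])
    except KeyError:
        raise ConfigError(f"unknown education level {level!r}") from None


def _not_evaluable(assessment, covariate, test, n, note) -> AssociationResult:
    return AssociationResult(
        assessment=assessment, covariate=covariate, test=test,
        statistic=math.nan, p_value=math.nan, n=n,
        significant=False, evaluable=False, note=note,
    )


def rank_correlation_screen(
    dataset: StudyDataset,
    covariate: str,
    alpha: float = ALPHA,
    min_n: int = 10,
    registry: Registry | None = None,
) -> list[AssociationResult]:
    """Spearman ρ of score vs a numeric covariate, per assessment."""
    if covariate not in ("age", "education_years"):
        raise ConfigError(f"rank_correlation_screen covariate must be age or education_years, got {covariate!r}")
    if covariate == "age":
        values = {p.participant_id: float(p.age_years) for p in dataset.participants}
    else:
        values = {p.participant_id: education_to_years(p.education_level) for p in dataset.participants}

    out = []
    names = registry.names if registry is not None else sorted(dataset.results["assessment"].unique())
    for name in names:
        sub = dataset.results[dataset.results["assessment"] == name]
        x = sub["participant_id"].map(values).to_numpy(dtype=float)
        y = sub["score"].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        n = len(x)
        if n < min_n:
            out.append(_not_evaluable(name, covariate, "spearman", n, f"fewer than {min_n} pairs"))
            continue
        if np.all(x == x[0]) or np.all(y == y[0]):
            out.append(_not_evaluable(name, covariate, "spearman", n, "degenerate ranks (constant input)"))
            continue
        rho, p = stats.spearmanr(x, y)
        out.append(
            AssociationResult(
                assessment=name, covariate=covariate, test="spearman",
                statistic=float(rho), p_value=float(p), n=n,
                significant=bool(p < alpha),
            )
        )
    return out


def _dichotomy(dataset: StudyDataset, grouping: str) -> dict:
    """participant_id -> group label (0/1), omitting out-of-dichotomy cases."""
    groups = {}
    for p in dataset.participants:
        if grouping == "gender":
            if p.gender == "female":
                groups[p.participant_id] = 0
            elif p.gender == "male":
                groups[p.participant_id] = 1
        elif grouping == "race":
            poc = is_person_of_color(p.race)
            if poc is not None:
                groups[p.participant_id] = 1 if poc else 0
        else:
            raise ConfigError(f"rank_sum_screen grouping must be gender or race, got {grouping!r}")
    return groups


def rank_sum_p(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) statistic and p.

    The exact null distribution is used for small untied samples
    (combined n ≤ 25); otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_RANKSUM_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rank_sum_screen(
    dataset: StudyDataset,
    grouping: str,
    alpha: float = ALPHA,
    registry: Registry | None = None,
) -> list[AssociationResult]:
    """Wilcoxon rank-sum screen for the gender or race dichotomy."""
    groups = _dichotomy(dataset, grouping)
    out = []
    names = registry.names if registry is not None else sorted(dataset.results["assessment"].unique())
    for name in names:
        sub = dataset.results[dataset.results["assessment"] == name]
        g = sub["participant_id"].map(groups)
        y = sub["score"].to_numpy(dtype=float)
        keep = g.notna().to_numpy() & np.isfinite(y)
        g, y = g.to_numpy(dtype=float)[keep], y[keep]
        a, b = y[g == 0], y[g == 1]
        n = len(y)
        if len(a) == 0 or len(b) == 0:
            out.append(_not_evaluable(name, grouping, "wilcoxon_rank_sum", n, "a group is empty"))
            continue
        u, p = rank_sum_p(a, b)
        out.append(
            AssociationResult(
                assessment=name, covariate=grouping, test="wilcoxon_rank_sum",
                statistic=u, p_value=p, n=n, significant=bool(p < alpha),
            )
        )
    return out


def association_screen(
    dataset: StudyDataset,
    alpha: float = ALPHA,
    registry: Registry | None = None,
) -> pd.DataFrame:
    """All four demographic screens as one long table."""
    results = []
    results += rank_correlation_screen(dataset, "age", alpha, registry=registry)
    results += rank_correlation_screen(dataset, "education_years", alpha, registry=registry)
    results += rank_sum_screen(dataset, "gender", alpha, registry=registry)
    results += rank_sum_screen(dataset, "race", alpha, registry=registry)
    return pd.DataFrame([r.__dict__ for r in results])
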