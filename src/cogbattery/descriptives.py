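"""Descriptive statistics, ceiling/floor flagging, completion and demographic summaries.

Reproduces the reference study's usability tables: per-assessment central
tendency and distribution shape, the share of takers pinned at a score
bound (a ceiling/floor effect is flagged when ≥10% of takers sit at
either bound), completion-rate bins, and the demographic questionnaire
summary with its derived groupings (degree holders, people of color).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DEGREE_LEVELS, POC_OPTIONS, ParticipantProfile, StudyDataset
from .errors import InsufficientDataError
from .registry import AssessmentSpec, Registry

CEILING_FLOOR_THRESHOLD_PCT = 10.0


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the printed tables;
    Python's built-in round is banker's rounding)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class DescriptiveRow:
    assessment: str
    n: int
    mean: float
    sd: float
    median: float
    iqr: float
    mode: float
    skew: float
    kurtosis: float  # excess kurtosis
    n_highest: int
    pct_highest: float
    n_lowest: int
    pct_lowest: float
    mean_time_min: float
    sd_time_min: float
    ceiling_floor_flag: bool = False
    flag_side: tuple[str, ...] = field(default=())


def _mode_on_grid(scores: np.ndarray, spec: AssessmentSpec) -> float:
    """Most frequent score after snapping to the staircase step grid.

    Additive dimensions land on a half-unit grid; multiplicative ones on
    the geometric grid score_min · step^k.  Ties break to the smaller value.
    """
    if spec.multiplicative:
        step = math.log(1.2)
        k = np.round((np.log(scores) - math.log(spec.score_min)) / step)
        snapped = spec.score_min * np.exp(k * step)
        snapped = np.round(snapped, 6)
    else:
        snapped = np.round(scores * 2.0) / 2.0
    counts = Counter(snapped.tolist())
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return float(best[0])


def summarize_assessment(
    scores, spec: AssessmentSpec, durations=None
) -> DescriptiveRow:
    """One descriptive-table row for one assessment's score vector."""
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    n = len(scores)
    if n < 2:
        raise InsufficientDataError(f"{spec.name}: need >= 2 scores, got {n}")
    if durations is not None:
        durations = np.asarray(durations, dtype=float)
        if len(durations) != n:
            raise InsufficientDataError(f"{spec.name}: durations not aligned with scores")

    sd = float(np.std(scores, ddof=1))
    degenerate = sd == 0.0
    q75, q25 = np.percentile(scores, [75, 25])
    n_hi = int(np.sum(np.isclose(scores, spec.score_max, rtol=0, atol=1e-9)))
    n_lo = int(np.sum(np.isclose(scores, spec.score_min, rtol=0, atol=1e-9)))
    return DescriptiveRow(
        assessment=spec.name,
        n=n,
        mean=float(np.mean(scores)),
        sd=sd,
        median=float(np.median(scores)),
        iqr=float(q75 - q25),
        mode=_mode_on_grid(scores, spec),
        skew=math.nan if degenerate else float(stats.skew(scores, bias=False)),
        kurtosis=math.nan if degenerate else float(stats.kurtosis(scores, fisher=True, bias=False)),
        n_highest=n_hi,
        pct_highest=100.0 * n_hi / n,
        n_lowest=n_lo,
        pct_lowest=100.0 * n_lo / n,
        mean_time_min=float(np.mean(durations)) if durations is not None else math.nan,
        sd_time_min=float(np.std(durations, ddof=1)) if durations is not None else math.nan,
    )


def flag_ceiling_floor(
    row: DescriptiveRow, threshold_pct: float = CEILING_FLOOR_THRESHOLD_PCT
) -> DescriptiveRow:
    """Apply the inclusive ≥ threshold rule to either bound percentage."""
    sides = []
    if row.pct_highest >= threshold_pct:
        sides.append("highest_bound")
    if row.pct_lowest >= threshold_pct:
        sides.append("lowest_bound")
    return replace(row, ceiling_floor_flag=bool(sides), flag_side=tuple(sides))


def descriptives_table(
    dataset: StudyDataset,
    registry: Registry,
    threshold_pct: float = CEILING_FLOOR_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Descriptive rows (flag applied) for every assessment with >= 2 scores."""
    rows = []
    for spec in registry:
        sub = dataset.results[dataset.results["assessment"] == spec.name]
        if len(sub) < 2:
            continue
        row = summarize_assessment(sub["score"], spec, sub["duration_min"])
        rows.append(flag_ceiling_floor(row, threshold_pct))
    frame = pd.DataFrame([r.__dict__ for r in rows])
    if len(frame):
        frame["flag_side"] = ["+".join(s) for s in frame["flag_side"]]
    return frame


# --------------------------------------------------------------------------
# completion

@dataclass(frozen=True)
class CompletionSummary:
    n_registered: int
    n_completed_any: int
    n_completed_all: int
    bin_counts: tuple[int, ...]  # over bins 1-5, 6-10, 11-15, 16-20, 21-25, 26-29
    n_contacted: int | None = None
    bins: tuple = ((1, 5), (6, 10), (11, 15), (16, 20), (21, 25), (26, 29))

    def __post_init__(self):
        if sum(self.bin_counts) != self.n_completed_any:
            raise InsufficientDataError("completion bins must partition completers")
        if not self.n_completed_all <= self.n_completed_any <= self.n_registered:
            raise InsufficientDataError("completion counts must nest")

    @property
    def pct_completed_any(self) -> float:
        return 100.0 * self.n_completed_any / self.n_registered if self.n_registered else 0.0

    @property
    def pct_completed_all(self) -> float:
        return 100.0 * self.n_completed_all / self.n_registered if self.n_registered else 0.0

    @property
    def bin_pcts(self) -> tuple[float, ...]:
        """Bin shares among participants who completed at least one."""
        d = self.n_completed_any
        return tuple(100.0 * c / d if d else 0.0 for c in self.bin_counts)

    @property
    def registration_rate_pct(self) -> float | None:
        if not self.n_contacted:
            return None
        return 100.0 * self.n_registered / self.n_contacted

    def as_dict(self) -> dict:
        return {
            "n_contacted": self.n_contacted,
            "n_registered": self.n_registered,
            "n_completed_any": self.n_completed_any,
            "n_completed_all": self.n_completed_all,
            "registration_rate_pct": self.registration_rate_pct,
            "pct_completed_any": self.pct_completed_any,
            "pct_completed_all": self.pct_completed_all,
            "bins": ["%d-%d" % b for b in self.bins],
            "bin_counts": list(self.bin_counts),
            "bin_pcts": list(self.bin_pcts),
        }


def completion_summary(
    dataset: StudyDataset, registry: Registry, n_contacted: int | None = None
) -> CompletionSummary:
    """Bin the per-participant completion counts."""
    counts = dataset.results.groupby("participant_id").size() if len(dataset.results) else pd.Series(dtype=int)
    per_participant = [int(counts.get(p.participant_id, 0)) for p in dataset.participants]
    bins = ((1, 5), (6, 10), (11, 15), (16, 20), (21, 25), (26, 29))
    bin_counts = [0] * len(bins)
    for c in per_participant:
        for i, (lo, hi) in enumerate(bins):
            if lo <= c <= hi:
                bin_counts[i] += 1
                break
    return CompletionSummary(
        n_registered=len(dataset.participants),
        n_completed_any=sum(1 for c in per_participant if c >= 1),
        n_completed_all=sum(1 for c in per_participant if c >= len(registry)),
        bin_counts=tuple(bin_counts),
        n_contacted=n_contacted,
    )


# --------------------------------------------------------------------------
# demographics

def is_person_of_color(race: tuple[str, ...]) -> bool | None:
    """True if any selected option is a person-of-color category (including
    multiracial selections that exclude White); None when declined."""
    if race == ("declined",):
        return None
    return any(r in POC_OPTIONS for r in race)


def demographics_summary(participants: list[ParticipantProfile]) -> dict:
    """Per-question counts/percentages plus the derived groupings used in
    the reference study's abstract (degree holders, people of color)."""
    n = len(participants)

    def tally(values) -> dict:
        counts = Counter(values)
        return {
            k: {"n": c, "pct": 100.0 * c / n if n else 0.0}
            for k, c in sorted(counts.items(), key=lambda kv: -kv[1])
        }

    ages = np.array([p.age_years for p in participants], dtype=float)
    decade_bins = [(13, 19), (20, 29), (30, 39), (40, 49), (50, 59),
                   (60, 69), (70, 79), (80, 89), (90, 99), (100, 109)]
    age_bin_counts = {
        "%d-%d" % b: int(np.sum((ages >= b[0]) & (ages <= b[1]))) for b in decade_bins
    }

    race_option_counts = Counter()
    n_poc = n_race_declined = 0
    for p in participants:
        poc = is_person_of_color(p.race)
        if poc is None:
            n_race_declined += 1
            continue
        n_poc += int(poc)
        if poc and len(p.race) > 1:
            race_option_counts["multiracial_excluding_white"] += 1
        else:
            race_option_counts[p.race[0]] += 1

    n_degree = sum(1 for p in participants if p.education_level in DEGREE_LEVELS)
    n_edu_declined = sum(1 for p in participants if p.education_level == "declined")

    return {
        "n": n,
        "age": {
            "mean": float(ages.mean()) if n else math.nan,
            "sd": float(ages.std(ddof=1)) if n > 1 else math.nan,
            "range": (float(ages.min()), float(ages.max())) if n else (math.nan, math.nan),
            "bins": age_bin_counts,
        },
        "gender": tally(p.gender for p in participants),
        "education": tally(p.education_level for p in participants),
        "race": {
            k: {"n": c, "pct": 100.0 * c / n if n else 0.0}
            for k, c in race_option_counts.most_common()
        },
        "degree_holders": {"n": n_degree, "pct": 100.0 * n_degree / n if n else 0.0},
        "people_of_color": {"n": n_poc, "pct": 100.0 * n_poc / n if n else 0.0},
        "declined": {"race": n_race_declined, "education": n_edu_declined},
    }


def demographics_frame(participants: list[ParticipantProfile]) -> pd.DataFrame:
    """Flat table mirroring the demographic summary (one row per option)."""
    summary = demographics_summary(participants)
    rows = []
    for question in ("gender", "education", "race"):
        for option, v in summary[question].items():
            rows.append((question, option, v["n"], v["pct"]))
    for name in ("degree_holders", "people_of_color"):
        v = summary[name]
        rows.append(("derived", name, v["n"], v["pct"]))
    return pd.DataFrame(rows, columns=["question", "option", "n", "pct"])
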