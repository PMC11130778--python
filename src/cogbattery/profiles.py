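"""z-scores, composites and the a-priori four-class cognitive profiles.

Completers (participants with a score on all 29 assessments) are the
reference population: each assessment column is standardized over them.
Two direction policies exist.  ``aligned_higher_better`` flips the sign
of lower-is-better columns after standardizing, so a positive z always
means better-than-average performance — required for composites and
profiles to be interpretable.  ``raw_orientation`` keeps the numeric
orientation, which reproduces the published factor-loading sign pattern
and is the factor stage's default input.

Profile labels, in precedence order: high performer (composite z > 0.40),
low performer (composite z < −0.40), auditory- or visual-strong (mean
auditory z and mean visual z differing by at least half an SD, 0.5 in z
units), else unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import StudyDataset
from .errors import ConfigError, InsufficientDataError
from .registry import Registry

DIRECTION_POLICIES = ("raw_orientation", "aligned_higher_better")


@dataclass(frozen=True)
class ZScoreTable:
    """Completers × assessments z-score matrix with its direction policy."""

    values: pd.DataFrame
    direction_policy: str
    reference_population: str = "completers"

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ProfileThresholds:
    high: float = 0.40
    low: float = -0.40
    modality_gap: float = 0.5  # half an SD in z units


@dataclass(frozen=True)
class CognitiveProfile:
    participant_id: str
    composite_z: float
    auditory_mean_z: float
    visual_mean_z: float
    label: str  # high | low | auditory_strong | visual_strong | unclassified
    modality_gap: float


@dataclass(frozen=True)
class CompositeSummary:
    mean: float
    sd: float
    range: tuple[float, float]
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]
    bin_pcts: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "range": list(self.range),
            "bin_edges": list(self.bin_edges),
            "bin_counts": list(self.bin_counts),
            "bin_pcts": list(self.bin_pcts),
        }


def select_completers(dataset: StudyDataset, registry: Registry) -> list[str]:
    """Participants with exactly one result row per registry assessment."""
    if not len(dataset.results):
        return []
    have = dataset.results.groupby("participant_id")["assessment"].agg(set)
    full = set(registry.names)
    order = [p.participant_id for p in dataset.participants]
    complete = {pid for pid, s in have.items() if s >= full}
    return [pid for pid in order if pid in complete]


def completer_score_matrix(dataset: StudyDataset, registry: Registry) -> pd.DataFrame:
    """Wide completers × assessments raw-score matrix (registry column order)."""
    ids = select_completers(dataset, registry)
    sub = dataset.results[dataset.results["participant_id"].isin(ids)]
    wide = sub.pivot(index="participant_id", columns="assessment", values="score")
    return wide.loc[ids, registry.names]


def zscore_transform(
    wide: pd.DataFrame,
    registry: Registry,
    direction_policy: str = "aligned_higher_better",
) -> ZScoreTable:
    """Column-standardize a complete wide score matrix (sample SD, ddof=1)."""
    if direction_policy not in DIRECTION_POLICIES:
        raise ConfigError(f"unknown direction policy {direction_policy!r}")
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise InsufficientDataError(f"missing cells in columns: {bad}")
    sds = wide.std(ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise InsufficientDataError(f"zero-variance columns: {zero}")
    z = (wide - wide.mean()) / sds
    if direction_policy == "aligned_higher_better":
        for spec in registry:
            if spec.name in z.columns and not spec.higher_better:
                z[spec.name] = -z[spec.name]
    return ZScoreTable(values=z, direction_policy=direction_policy)


def composite_scores(ztable: ZScoreTable) -> tuple[pd.Series, CompositeSummary]:
    """Unweighted mean of each completer's z-scores, summarized in
    0.10-wide bins anchored at the minimum composite (the layout of the
    published composite table)."""
    composites = ztable.values.mean(axis=1)
    n = len(composites)
    lo, hi = float(composites.min()), float(composites.max())
    start = lo
    n_bins = max(1, int(math.ceil((hi - start) / 0.10 - 1e-9)))
    edges = [start + 0.10 * i for i in range(n_bins + 1)]
    counts = []
    for i in range(n_bins):
        left, right = edges[i], edges[i + 1]
        inclusive_right = i == n_bins - 1
        c = np.sum((composites >= left) & ((composites <= right) if inclusive_right else (composites < right)))
        counts.append(int(c))
    summary = CompositeSummary(
        mean=float(composites.mean()),
        sd=float(composites.std(ddof=1)) if n > 1 else math.nan,
        range=(lo, hi),
        bin_edges=tuple(round(e, 10) for e in edges),
        bin_counts=tuple(counts),
        bin_pcts=tuple(100.0 * c / n for c in counts),
    )
    return composites, summary


def modality_mean_z(ztable: ZScoreTable, registry: Registry) -> pd.DataFrame:
    """Per-completer mean z over auditory and over visual assessments."""
    if ztable.direction_policy != "aligned_higher_better":
        raise ConfigError("modality means require the aligned_higher_better policy")
    aud = [n for n in registry.modality_names("auditory") if n in ztable.values.columns]
    vis = [n for n in registry.modality_names("visual") if n in ztable.values.columns]
    return pd.DataFrame(
        {
            "auditory_mean_z": ztable.values[aud].mean(axis=1),
            "visual_mean_z": ztable.values[vis].mean(axis=1),
        }
    )


def classify_profile(
    participant_id: str,
    composite_z: float,
    auditory_mean_z: float,
    visual_mean_z: float,
    thresholds: ProfileThresholds = ProfileThresholds(),
) -> CognitiveProfile:
    """Assign one of the four a-priori profile classes (or unclassified).

    High/low use strict inequalities (a composite of exactly 0.40 falls
    through to the modality rule); the modality gap rule is inclusive
    (≥ half an SD).  High/low take precedence over the modality labels.
    """
    for v in (composite_z, auditory_mean_z, visual_mean_z):
        if not math.isfinite(v):
            raise ConfigError("profile inputs must be finite")
    gap = auditory_mean_z - visual_mean_z
    if composite_z > thresholds.high:
        label = "high"
    elif composite_z < thresholds.low:
        label = "low"
    elif abs(gap) >= thresholds.modality_gap:
        label = "auditory_strong" if gap > 0 else "visual_strong"
    else:
        label = "unclassified"
    return CognitiveProfile(
        participant_id=participant_id,
        composite_z=composite_z,
        auditory_mean_z=auditory_mean_z,
        visual_mean_z=visual_mean_z,
        label=label,
        modality_gap=gap,
    )


def profile_table(
    ztable: ZScoreTable,
    registry: Registry,
    thresholds: ProfileThresholds = ProfileThresholds(),
) -> pd.DataFrame:
    """One profile row per completer."""
    composites, _ = composite_scores(ztable)
    modal = modality_mean_z(ztable, registry)
    rows = [
        classify_profile(
            pid,
            float(composites[pid]),
            float(modal.loc[pid, "auditory_mean_z"]),
            float(modal.loc[pid, "visual_mean_z"]),
            thresholds,
        ).__dict__
        for pid in ztable.values.index
    ]
    return pd.DataFrame(rows)
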