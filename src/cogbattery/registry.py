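"""Static catalog of the 29 adaptive brain-health assessments.

Each assessment adjusts a single stimulus dimension (exposure duration,
set size, stimulus similarity, or sweep speed) from trial to trial, and
the reported score is the threshold reached on that dimension.  The
registry records, per assessment: the sensory modality used for the
modality-split analyses, the score direction (whether numerically higher
scores mean better performance), the reportable score bounds, calibration
targets for the simulator (score mean/SD/median and assessment duration),
a 4-vector of generative factor loadings, whether performance is
age-sensitive in the reference study, and whether problematic score
bounds could be modified.

The catalog ships as a packaged CSV so the classification choices (most
importantly the auditory/visual split, which is partly a judgment call
for five mixed-modality tasks) are reviewable data rather than code.
A user-supplied CSV with the same header can be loaded instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import RegistryError

MODALITIES = ("auditory", "visual")
DIRECTIONS = ("higher_better", "lower_better")
ADAPTIVE_KINDS = ("exposure_duration_ms", "set_size", "similarity", "speed")
BOUNDS_MODIFIABLE = ("modifiable", "unmodifiable_diagnostic", "unmodifiable_deprecate", "none")

#: adaptive dimensions whose staircase moves multiplicatively (they span
#: orders of magnitude); set sizes and similarity steps move additively.
MULTIPLICATIVE_KINDS = frozenset({"exposure_duration_ms", "speed"})

N_ASSESSMENTS = 29
N_FACTORS = 4


@dataclass(frozen=True)
class ReferenceStats:
    """Printed per-assessment results from the reference deployment.

    Kept separate from the simulator calibration fields: these are
    observed study outcomes (sample size, ceiling/floor tallies,
    demographic-screen significance), used as fixtures for rule
    reproduction, never as generator inputs.
    """

    n: int
    n_highest: int
    pct_highest: float
    n_lowest: int
    pct_lowest: float
    sig_gender: bool
    sig_education: bool
    sig_race: bool


@dataclass(frozen=True)
class AssessmentSpec:
    name: str
    modality: str
    ambiguous_modality: bool
    direction: str
    adaptive_kind: str
    score_min: float
    score_max: float
    calib_mean: float
    calib_sd: float
    calib_median: float
    duration_mean_min: float
    duration_sd_min: float
    trial_seconds: float
    factor_loadings: tuple[float, float, float, float]
    age_sensitive: bool
    bounds_modifiable: str
    study: ReferenceStats = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise RegistryError(f"{self.name}: bad modality {self.modality!r}")
        if self.direction not in DIRECTIONS:
            raise RegistryError(f"{self.name}: bad direction {self.direction!r}")
        if self.adaptive_kind not in ADAPTIVE_KINDS:
            raise RegistryError(f"{self.name}: bad adaptive_kind {self.adaptive_kind!r}")
        if self.bounds_modifiable not in BOUNDS_MODIFIABLE:
            raise RegistryError(f"{self.name}: bad bounds_modifiable {self.bounds_modifiable!r}")
        if not self.score_min < self.score_max:
            raise RegistryError(f"{self.name}: score_min must be < score_max")
        if len(self.factor_loadings) != N_FACTORS:
            raise RegistryError(f"{self.name}: factor_loadings must have length {N_FACTORS}")

    @property
    def higher_better(self) -> bool:
        return self.direction == "higher_better"

    @property
    def best_bound(self) -> float:
        """Score bound corresponding to best possible performance."""
        return self.score_max if self.higher_better else self.score_min

    @property
    def worst_bound(self) -> float:
        return self.score_min if self.higher_better else self.score_max

    @property
    def direction_sign(self) -> float:
        """+1 when numerically higher raw scores mean better performance."""
        return 1.0 if self.higher_better else -1.0

    @property
    def score_range(self) -> float:
        return self.score_max - self.score_min

    @property
    def multiplicative(self) -> bool:
        return self.adaptive_kind in MULTIPLICATIVE_KINDS


_BOOL = {"true": True, "false": False}


def _parse_bool(raw: str, context: str) -> bool:
    try:
        return _BOOL[raw.strip().lower()]
    except KeyError:
        raise RegistryError(f"{context}: expected boolean, got {raw!r}") from None


def _parse_row(row: dict) -> AssessmentSpec:
    name = row["name"]
    try:
        study = ReferenceStats(
            n=int(row["study_n"]),
            n_highest=int(row["study_n_highest"]),
            pct_highest=float(row["study_pct_highest"]),
            n_lowest=int(row["study_n_lowest"]),
            pct_lowest=float(row["study_pct_lowest"]),
            sig_gender=_parse_bool(row["study_sig_gender"], name),
            sig_education=_parse_bool(row["study_sig_education"], name),
            sig_race=_parse_bool(row["study_sig_race"], name),
        )
        return AssessmentSpec(
            name=name,
            modality=row["modality"],
            ambiguous_modality=_parse_bool(row["ambiguous_modality"], name),
            direction=row["direction"],
            adaptive_kind=row["adaptive_kind"],
            score_min=float(row["score_min"]),
            score_max=float(row["score_max"]),
            calib_mean=float(row["calib_mean"]),
            calib_sd=float(row["calib_sd"]),
            calib_median=float(row["calib_median"]),
            duration_mean_min=float(row["duration_mean_min"]),
            duration_sd_min=float(row["duration_sd_min"]),
            trial_seconds=float(row["trial_seconds"]),
            factor_loadings=tuple(float(row[f"loading_f{i}"]) for i in range(1, 5)),
            age_sensitive=_parse_bool(row["age_sensitive"], name),
            bounds_modifiable=row["bounds_modifiable"],
            study=study,
        )
    except (KeyError, ValueError) as exc:
        raise RegistryError(f"corrupt registry row for {name!r}: {exc}") from exc


class Registry:
    """Ordered, name-indexed collection of :class:`AssessmentSpec`."""

    def __init__(self, specs: list[AssessmentSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise RegistryError("duplicate assessment names in registry")
        self._specs = list(specs)
        self._by_name = {s.name: s for s in specs}

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self) -> Iterator[AssessmentSpec]:
        return iter(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> AssessmentSpec:
        return self.get_spec(name)

    def get_spec(self, name: str) -> AssessmentSpec:
        try:
            return self._by_name[name]
        except KeyError:
            valid = ", ".join(self.names)
            raise RegistryError(f"unknown assessment {name!r}; valid names: {valid}") from None

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._specs]

    def loading_matrix(self) -> np.ndarray:
        """29 x 4 generative loading matrix in registry order."""
        return np.array([s.factor_loadings for s in self._specs])

    def modality_names(self, modality: str) -> list[str]:
        if modality not in MODALITIES:
            raise RegistryError(f"unknown modality {modality!r}")
        return [s.name for s in self._specs if s.modality == modality]


def load_registry(path: str | Path | None = None, strict: bool = True) -> Registry:
    """Load the packaged assessment catalog (or a user CSV with the same header).

    With ``strict`` (the default) the registry must contain exactly the
    29 standard assessments; pass ``strict=False`` to load a customized
    subset or variant catalog.
    """
    if path is None:
        source = resources.files("cogbattery.data").joinpath("assessments.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is None or "name" not in reader.fieldnames:
        raise RegistryError("registry CSV has no header row with a 'name' column")
    specs = [_parse_row(row) for row in reader]
    registry = Registry(specs)
    if strict and len(registry) != N_ASSESSMENTS:
        raise RegistryError(f"expected {N_ASSESSMENTS} assessments, found {len(registry)}")
    return registry


def get_spec(name: str, registry: Registry | None = None) -> AssessmentSpec:
    """Look up one assessment by exact name from the default registry."""
    if registry is None:
        registry = load_registry()
    return registry.get_spec(name)
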