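"""Synthetic study cohort: demographics, latent abilities, engagement, dataset.

The generator emulates the statistical structure of a remote, unsupervised
deployment of the 29-assessment battery to self-registered volunteers:

* demographics drawn from the reference study's questionnaire marginals
  (age decade bins spanning 13-107, gender, education level, race);
* a 4-factor latent ability model whose generative weights are the
  published rotated loadings, plus an auditory-minus-visual skill offset
  and a linear age effect on the age-sensitive tasks;
* an engagement process that stops each participant partway through a
  counterbalanced assessment sequence, calibrated to the published
  completion bins (46.6% of those who start finish 1-5 assessments,
  29.4% finish 26-29, ...);
* the staircase engine producing one observed score per attempted
  assessment.

Everything is driven by one seeded generator, so a dataset is fully
reproducible from ``(seed, config)``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .registry import AssessmentSpec, Registry, load_registry
from .staircase import AssessmentRun, EngineConfig, ObserverModel, run_assessment

GENDERS = ("female", "male", "nonbinary", "other", "declined")

EDUCATION_LEVELS = (
    "never_attended",
    "kindergarten",
    "elementary",
    "middle_school",
    "high_school_or_ged",
    "some_college",
    "associate_or_vocational",
    "bachelor",
    "master",
    "doctoral_or_professional",
    "declined",
)

#: education levels counting as "holds a degree"
DEGREE_LEVELS = frozenset(
    {"associate_or_vocational", "bachelor", "master", "doctoral_or_professional"}
)

RACE_OPTIONS = (
    "american_indian_or_alaska_native",
    "asian",
    "black_or_african_american",
    "hispanic_or_latino",
    "native_hawaiian_or_other_pacific_islander",
    "white",
)
POC_OPTIONS = frozenset(RACE_OPTIONS) - {"white"}

# --- reference-study marginals (counts out of 414 registrants) -------------

AGE_BIN_COUNTS: tuple[tuple[tuple[int, int], int], ...] = (
    ((13, 19), 5),
    ((20, 29), 5),
    ((30, 39), 18),
    ((40, 49), 46),
    ((50, 59), 74),
    ((60, 69), 121),
    ((70, 79), 105),
    ((80, 89), 34),
    ((90, 99), 5),
    ((100, 107), 1),
)

GENDER_COUNTS = {
    "female": 265,
    "male": 144,
    "nonbinary": 2,
    "other": 1,
    "declined": 2,
}

EDUCATION_COUNTS = {
    "bachelor": 132,
    "master": 114,
    "some_college": 45,
    "doctoral_or_professional": 42,
    "associate_or_vocational": 41,
    "high_school_or_ged": 26,
    "never_attended": 8,
    "middle_school": 3,
    "elementary": 3,
    "kindergarten": 0,
    "declined": 0,
}

# single-selection race categories plus the two special outcomes
RACE_COUNTS = {
    "white": 349,
    "asian": 20,
    "hispanic_or_latino": 13,
    "black_or_african_american": 10,
    "american_indian_or_alaska_native": 1,
    "native_hawaiian_or_other_pacific_islander": 0,
    "multiracial_excluding_white": 4,
    "declined": 17,
}

#: P(completed 0 assessments | registered) and completion-bin mixture for
#: participants who started: bins over number of assessments completed.
P_COMPLETED_NONE = 47.0 / 414.0
COMPLETION_BINS: tuple[tuple[int, int], ...] = ((1, 5), (6, 10), (11, 15), (16, 20), (21, 25), (26, 29))
COMPLETION_BIN_PROBS: tuple[float, ...] = (0.466, 0.112, 0.065, 0.049, 0.014, 0.294)
#: P(completed all 29 | in the 26-29 bin).  The reference counts (108 in
#: the top bin, of whom 104 finished everything) show the top bin is not
#: uniform: participants who get that far almost always finish.
P_FULL_GIVEN_TOP_BIN = 104.0 / 108.0


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    age_years: int
    gender: str
    education_level: str
    race: tuple[str, ...]  # selected options, or ("declined",)
    engagement_propensity: float

    def __post_init__(self):
        if not 13 <= self.age_years <= 107:
            raise ConfigError(f"age {self.age_years} outside [13, 107]")
        if not 0.0 <= self.engagement_propensity <= 1.0:
            raise ConfigError("engagement_propensity must be in [0, 1]")


@dataclass(frozen=True)
class LatentAbility:
    """Generative per-participant ability state (simulation ground truth)."""

    factor_scores: tuple[float, float, float, float]
    modality_offset: float  # auditory-minus-visual skill, SD units
    age_effect_scale: float
    uniqueness: dict  # assessment name -> standard-normal idiosyncratic draw


@dataclass
class CohortConfig:
    """All knobs of the synthetic-cohort generator.

    Defaults are the reference study's stated world: n=414 registrants,
    its demographic marginals, its completion-bin mixture, an age effect
    of 0.03 SD of ability per year on the age-sensitive tasks, and a
    0.3 SD spread of auditory-vs-visual skill.
    """

    n_participants: int = 414
    seed: int = 0
    age_bin_counts: tuple = AGE_BIN_COUNTS
    gender_counts: dict = field(default_factory=lambda: dict(GENDER_COUNTS))
    education_counts: dict = field(default_factory=lambda: dict(EDUCATION_COUNTS))
    race_counts: dict = field(default_factory=lambda: dict(RACE_COUNTS))
    age_effect_per_year: float = 0.03
    age_reference: float = 60.0
    modality_offset_sd: float = 0.3
    min_uniqueness_var: float = 0.05
    observer_slope_additive: float = 1.5
    observer_slope_log: float = 6.0
    observer_guess: float = 0.0
    observer_lapse: float = 0.02
    p_completed_none: float = P_COMPLETED_NONE
    completion_bins: tuple = COMPLETION_BINS
    completion_bin_probs: tuple = COMPLETION_BIN_PROBS
    p_full_given_top_bin: float = P_FULL_GIVEN_TOP_BIN
    rotation_offsets: tuple = (0, 7, 15, 22)
    normalize_ability_variance: bool = True

    def __post_init__(self):
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if not 0.0 <= self.p_completed_none <= 1.0:
            raise ConfigError("p_completed_none must be a probability")
        probs = np.asarray(self.completion_bin_probs, dtype=float)
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
            raise ConfigError("completion_bin_probs must be non-negative and sum to 1")
        for name, counts in (
            ("gender_counts", self.gender_counts),
            ("education_counts", self.education_counts),
            ("race_counts", self.race_counts),
        ):
            if any(v < 0 for v in counts.values()) or sum(counts.values()) <= 0:
                raise ConfigError(f"{name} must be non-negative with positive total")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyDataset:
    """Participants plus the long-format assessment results table.

    ``results`` columns: participant_id, assessment, score, duration_min,
    exit_reason, n_trials, n_reversals and (for synthetic data) the
    planted true_theta80.
    """

    participants: list
    results: pd.DataFrame
    seed: int | None = None
    config_hash: str | None = None

    RESULT_COLUMNS = (
        "participant_id",
        "assessment",
        "score",
        "duration_min",
        "exit_reason",
        "n_trials",
        "n_reversals",
        "true_theta80",
    )

    def participants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "age_years": [p.age_years for p in self.participants],
                "gender": [p.gender for p in self.participants],
                "education_level": [p.education_level for p in self.participants],
                "race": ["|".join(p.race) for p in self.participants],
                "engagement_propensity": [p.engagement_propensity for p in self.participants],
            }
        )

    def validate(self) -> None:
        ids = {p.participant_id for p in self.participants}
        if len(ids) != len(self.participants):
            raise ConfigError("duplicate participant ids")
        if len(self.results):
            unknown = set(self.results["participant_id"]) - ids
            if unknown:
                raise ConfigError(f"results reference unknown participants: {sorted(unknown)[:5]}")
            dup = self.results.duplicated(["participant_id", "assessment"]).any()
            if dup:
                raise ConfigError("more than one result row per (participant, assessment)")

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.participants_frame().to_csv(path / "participants.csv", index=False)
        self.results.to_csv(path / "results.csv", index=False)
        (path / "provenance.json").write_text(
            json.dumps({"seed": self.seed, "config_hash": self.config_hash}, indent=2)
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "StudyDataset":
        path = Path(path)
        pf = pd.read_csv(path / "participants.csv", comment="#", float_precision="round_trip")
        results = pd.read_csv(path / "results.csv", comment="#", float_precision="round_trip")
        if "true_theta80" not in results.columns:
            results["true_theta80"] = np.nan
        participants = [
            ParticipantProfile(
                participant_id=str(r.participant_id),
                age_years=int(r.age_years),
                gender=str(r.gender),
                education_level=str(r.education_level),
                race=tuple(str(r.race).split("|")),
                engagement_propensity=float(r.engagement_propensity),
            )
            for r in pf.itertuples()
        ]
        meta = {}
        prov = path / "provenance.json"
        if prov.exists():
            meta = json.loads(prov.read_text())
        ds = cls(participants, results, seed=meta.get("seed"), config_hash=meta.get("config_hash"))
        ds.validate()
        return ds


# --------------------------------------------------------------------------
# sampling

def _age_variance(config: CohortConfig) -> float:
    """Population variance of age under the configured decade-bin marginals
    (uniform within bin)."""
    counts = np.array([c for _, c in config.age_bin_counts], dtype=float)
    probs = counts / counts.sum()
    mids = np.array([(lo + hi) / 2.0 for (lo, hi), _ in config.age_bin_counts])
    within = np.array([((hi - lo + 1) ** 2 - 1) / 12.0 for (lo, hi), _ in config.age_bin_counts])
    mu = float(probs @ mids)
    return float(probs @ (within + (mids - mu) ** 2))


def _categorical(counts: dict, rng: np.random.Generator) -> str:
    names = list(counts)
    probs = np.array([counts[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    return names[rng.choice(len(names), p=probs)]


def sample_demographics(
    n: int, config: CohortConfig | None = None, rng: np.random.Generator | None = None
) -> list[ParticipantProfile]:
    """Independent draws from the configured demographic marginals.

    Age is drawn by decade bin, then uniformly (integer years) within the
    bin, matching how the reference study tabulates age.
    """
    config = config or CohortConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bins = [b for b, _ in config.age_bin_counts]
    bin_probs = np.array([c for _, c in config.age_bin_counts], dtype=float)
    if bin_probs.sum() <= 0 or np.any(bin_probs < 0):
        raise ConfigError("age bin counts must be non-negative with positive total")
    bin_probs /= bin_probs.sum()

    out = []
    width = max(4, len(str(max(n, 1))))
    for i in range(n):
        lo, hi = bins[rng.choice(len(bins), p=bin_probs)]
        age = int(rng.integers(lo, hi + 1))
        gender = _categorical(config.gender_counts, rng)
        education = _categorical(config.education_counts, rng)
        race_cat = _categorical(config.race_counts, rng)
        if race_cat == "multiracial_excluding_white":
            picks = rng.choice(sorted(POC_OPTIONS), size=2, replace=False)
            race = tuple(sorted(picks))
        else:
            race = (race_cat,)
        out.append(
            ParticipantProfile(
                participant_id=f"P{i:0{width}d}",
                age_years=age,
                gender=gender,
                education_level=education,
                race=race,
                engagement_propensity=float(rng.random()),
            )
        )
    return out


def sample_latent_abilities(
    profile: ParticipantProfile,
    registry: Registry,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[LatentAbility, dict]:
    """Draw a participant's latent ability state and per-assessment theta80.

    For assessment j with generative loadings Λⱼ (kept in raw printed
    orientation so simulated raw z-scores reproduce the published sign
    structure), direction sign dⱼ (+1 higher-better) and modality sign sⱼ
    (+1/2 auditory, −1/2 visual):

        uⱼ = Λⱼ·f + dⱼ·(sⱼ·m − β·(age − 60)·[age-sensitive]) + √ψⱼ·εⱼ
        theta80ⱼ = calib_mean + calib_sd · uⱼ

    f ~ N(0, I₄), m ~ N(0, modality_offset_sd²), εⱼ ~ N(0, 1) and
    ψⱼ = max(1 − ‖Λⱼ‖², min_uniqueness_var).  The age term is signed so
    that older participants perform worse on age-sensitive tasks.  With
    ``normalize_ability_variance`` (the default) uⱼ is divided by its
    closed-form population SD, so the theta80 SD calibrates to the
    published per-assessment score SD.
    """
    f = rng.standard_normal(4)
    m = rng.normal(0.0, config.modality_offset_sd)
    beta = config.age_effect_per_year
    age_dev = profile.age_years - config.age_reference
    var_age = _age_variance(config)

    uniq = {}
    thetas = {}
    for spec in registry:
        lam = np.asarray(spec.factor_loadings)
        psi = max(1.0 - float(lam @ lam), config.min_uniqueness_var)
        eps = float(rng.standard_normal())
        uniq[spec.name] = eps
        s = 0.5 if spec.modality == "auditory" else -0.5
        better = s * m - (beta * age_dev if spec.age_sensitive else 0.0)
        u = float(lam @ f) + spec.direction_sign * better + math.sqrt(psi) * eps
        if config.normalize_ability_variance:
            var_u = (
                float(lam @ lam) + psi + 0.25 * config.modality_offset_sd ** 2
                + (beta ** 2 * var_age if spec.age_sensitive else 0.0)
            )
            u = u / math.sqrt(var_u)
        thetas[spec.name] = spec.calib_mean + spec.calib_sd * u
    ability = LatentAbility(
        factor_scores=tuple(f),
        modality_offset=m,
        age_effect_scale=beta,
        uniqueness=uniq,
    )
    return ability, thetas


def completion_count(propensity: float, config: CohortConfig) -> int:
    """Number of assessments completed, as a deterministic monotone map
    of the engagement propensity (the propensity acts as the mixture
    quantile, so engagement is independent of ability by default)."""
    if propensity < config.p_completed_none:
        return 0
    v = (propensity - config.p_completed_none) / (1.0 - config.p_completed_none)
    v = min(v, 1.0 - 1e-12)
    last = len(config.completion_bins) - 1
    cum = 0.0
    for i, ((lo, hi), p) in enumerate(zip(config.completion_bins, config.completion_bin_probs)):
        if p <= 0:
            continue
        if v < cum + p:
            frac = (v - cum) / p
            if i == last and hi - lo >= 1:
                # top bin: mass p_full_given_top_bin on the full battery,
                # the rest uniform over lo..hi-1
                p_rest = 1.0 - config.p_full_given_top_bin
                if frac >= p_rest:
                    return hi
                return lo + int(frac / p_rest * (hi - lo)) if p_rest > 0 else hi
            return lo + int(frac * (hi - lo + 1))
        cum += p
    return config.completion_bins[-1][1]


def simulate_engagement(
    profile: ParticipantProfile,
    registry: Registry,
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Assessments this participant attempts: the first m entries of one
    of the four counterbalanced rotations of the registry order."""
    m = completion_count(profile.engagement_propensity, config)
    offset = int(config.rotation_offsets[rng.integers(len(config.rotation_offsets))])
    names = registry.names
    sequence = names[offset:] + names[:offset]
    return sequence[:m]


def build_observer(spec: AssessmentSpec, theta80: float, config: CohortConfig) -> ObserverModel:
    """Observer for one assessment.

    Discriminability is expressed on the ability scale: for additive
    dimensions the logistic slope is ``observer_slope_additive`` per
    population SD of the trait (IRT-style discrimination), converted to
    per-unit by dividing by the assessment's calibrated score SD.  For
    multiplicative dimensions the slope is per log-unit.
    """
    if spec.multiplicative:
        slope = config.observer_slope_log
        # keep log-scale theta meaningful: clamp away from zero
        theta80 = max(theta80, spec.score_min * 1e-3)
    else:
        slope = config.observer_slope_additive / spec.calib_sd
    return ObserverModel(
        theta80=theta80,
        slope=slope,
        guess_rate=config.observer_guess,
        lapse_rate=config.observer_lapse,
    )


def generate_study_dataset(
    config: CohortConfig | None = None,
    registry: Registry | None = None,
    engine_config: EngineConfig = EngineConfig(),
) -> StudyDataset:
    """Simulate the full study: registration, engagement, assessment runs."""
    config = config or CohortConfig()
    registry = registry or load_registry()
    rng = np.random.default_rng(config.seed)

    participants = sample_demographics(config.n_participants, config, rng)
    rows = []
    for profile in participants:
        _, thetas = sample_latent_abilities(profile, registry, config, rng)
        attempted = simulate_engagement(profile, registry, config, rng)
        for name in attempted:
            spec = registry[name]
            observer = build_observer(spec, thetas[name], config)
            run: AssessmentRun = run_assessment(
                spec, observer, rng, engine_config, participant_id=profile.participant_id
            )
            rows.append(
                (
                    profile.participant_id,
                    name,
                    run.score,
                    run.duration_min,
                    run.exit_reason,
                    run.n_trials,
                    run.n_reversals,
                    thetas[name],
                )
            )
    results = pd.DataFrame(rows, columns=list(StudyDataset.RESULT_COLUMNS))
    dataset = StudyDataset(
        participants, results, seed=config.seed, config_hash=config.config_hash()
    )
    dataset.validate()
    return dataset


def simulate_completer_zscores(
    n: int,
    config: CohortConfig | None = None,
    registry: Registry | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Latent-route z-score table for ``n`` synthetic completers.

    Draws demographics and latent abilities from the default generative
    configuration and standardizes the resulting theta80 values per
    column — i.e. the score table an errorless measurement of ability
    would produce.  Used to study the factor stage without staircase
    measurement noise.
    """
    config = config or CohortConfig()
    registry = registry or load_registry()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    profiles = sample_demographics(n, config, rng)
    rows = [sample_latent_abilities(p, registry, config, rng)[1] for p in profiles]
    wide = pd.DataFrame(rows, index=[p.participant_id for p in profiles])[registry.names]
    z = (wide - wide.mean()) / wide.std(ddof=1)
    return z
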