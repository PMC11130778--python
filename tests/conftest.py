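import numpy as np
import pandas as pd
import pytest

import cogbattery as cb


@pytest.fixture(scope="session")
def registry():
    return cb.load_registry()


@pytest.fixture(scope="session")
def study_dataset():
    """Default-size simulated study (414 registrants), shared read-only."""
    return cb.generate_study_dataset(cb.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def completer_ztable(study_dataset, registry):
    wide = cb.completer_score_matrix(study_dataset, registry)
    return cb.zscore_transform(wide, registry, "aligned_higher_better")


def make_dataset(registry, scores_by_assessment, ages=None, genders=None,
                 educations=None, races=None):
    """Hand-build a StudyDataset from per-assessment score dicts.

    ``scores_by_assessment``: {assessment: {participant_id: score}}.
    Demographic vectors are keyed by participant id; defaults are benign.
    """
    pids = sorted({pid for scores in scores_by_assessment.values() for pid in scores})
    ages = ages or {}
    genders = genders or {}
    educations = educations or {}
    races = races or {}
    participants = [
        cb.ParticipantProfile(
            participant_id=pid,
            age_years=int(ages.get(pid, 60)),
            gender=genders.get(pid, "female"),
            education_level=educations.get(pid, "bachelor"),
            race=races.get(pid, ("white",)),
            engagement_propensity=0.5,
        )
        for pid in pids
    ]
    rows = []
    for name, scores in scores_by_assessment.items():
        for pid, score in scores.items():
            rows.append((pid, name, float(score), 3.0, "asymptote", 30, 8, np.nan))
    results = pd.DataFrame(rows, columns=list(cb.StudyDataset.RESULT_COLUMNS))
    ds = cb.StudyDataset(participants, results)
    ds.validate()
    return ds
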