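import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import cogbattery as cb
from cogbattery.cohort import _age_variance, completion_count
from cogbattery.errors import ConfigError


class TestDemographics:
    def test_empty_cohort(self):
        assert cb.sample_demographics(0) == []

    def test_same_seed_identical_cohorts(self):
        a = cb.sample_demographics(50, cb.CohortConfig(seed=3))
        b = cb.sample_demographics(50, cb.CohortConfig(seed=3))
        assert a == b
        c = cb.sample_demographics(50, cb.CohortConfig(seed=4))
        assert a != c

    def test_marginals_concentrate_on_reference_proportions(self):
        cohort = cb.sample_demographics(20000, cb.CohortConfig(seed=0))
        frac_female = np.mean([p.gender == "female" for p in cohort])
        assert abs(frac_female - 0.64) < 0.02
        frac_degree = np.mean([p.education_level in cb.cohort.DEGREE_LEVELS for p in cohort])
        assert abs(frac_degree - 0.795) < 0.02
        ages = np.array([p.age_years for p in cohort])
        assert ages.min() >= 13 and ages.max() <= 107
        assert abs(np.mean((ages >= 60) & (ages <= 69)) - 121 / 414) < 0.02

    def test_invalid_marginals_rejected(self):
        with pytest.raises(ConfigError):
            cb.CohortConfig(gender_counts={"female": -1, "male": 2})
        with pytest.raises(ConfigError):
            cb.CohortConfig(completion_bin_probs=(0.5, 0.1, 0.1, 0.1, 0.1, 0.2))


class TestEngagement:
    def test_propensity_one_attempts_everything(self, registry):
        cfg = cb.CohortConfig()
        assert completion_count(1.0, cfg) == 29
        p = cb.ParticipantProfile("a", 60, "female", "bachelor", ("white",), 1.0)
        attempted = cb.simulate_engagement(p, registry, cfg, np.random.default_rng(0))
        assert len(attempted) == 29 and set(attempted) == set(registry.names)

    def test_full_completion_mixture_mass(self, registry):
        cfg = cb.CohortConfig(
            p_completed_none=0.0,
            completion_bin_probs=(0, 0, 0, 0, 0, 1.0),
            p_full_given_top_bin=1.0,
        )
        for u in (0.0, 0.3, 0.999):
            assert completion_count(u, cfg) == 29

    def test_bin_frequencies_match_mixture(self):
        """10,000 engagement draws reproduce the published completion
        distribution: 88.6% start, 25.1% finish everything, and the six
        conditional bins match the configured mixture within 3 binomial SEs."""
        cfg = cb.CohortConfig()
        u = np.random.default_rng(8).random(10000)
        m = np.array([completion_count(v, cfg) for v in u])
        assert abs(np.mean(m >= 1) - 0.886) < 0.015
        assert abs(np.mean(m == 29) - 0.251) < 0.015
        started = m[m >= 1]
        for (lo, hi), p in zip(cfg.completion_bins, cfg.completion_bin_probs):
            frac = np.mean((started >= lo) & (started <= hi))
            se = np.sqrt(p * (1 - p) / len(started))
            assert abs(frac - p) < 3 * se + 1e-3

    def test_attempted_set_is_prefix_of_a_rotation(self, registry):
        cfg = cb.CohortConfig()
        rng = np.random.default_rng(2)
        p = cb.ParticipantProfile("a", 60, "female", "bachelor", ("white",), 0.7)
        attempted = cb.simulate_engagement(p, registry, cfg, rng)
        names = registry.names
        rotations = [names[o:] + names[:o] for o in cfg.rotation_offsets]
        assert any(attempted == rot[: len(attempted)] for rot in rotations)


class TestLatentAbilities:
    def test_reference_age_contributes_nothing(self, registry):
        """A 60-year-old's thresholds are identical whether or not an age
        effect exists (the age term is centered at 60), and only the
        age-sensitive tasks move when the age changes."""
        cfg_eff = cb.CohortConfig(age_effect_per_year=0.03, normalize_ability_variance=False)
        cfg_null = cb.CohortConfig(age_effect_per_year=0.0, normalize_ability_variance=False)
        p60 = cb.ParticipantProfile("a", 60, "female", "bachelor", ("white",), 0.5)
        p80 = cb.ParticipantProfile("a", 80, "female", "bachelor", ("white",), 0.5)
        t_eff = cb.sample_latent_abilities(p60, registry, cfg_eff, np.random.default_rng(9))[1]
        t_null = cb.sample_latent_abilities(p60, registry, cfg_null, np.random.default_rng(9))[1]
        t_old = cb.sample_latent_abilities(p80, registry, cfg_eff, np.random.default_rng(9))[1]
        for name in registry.names:
            spec = registry[name]
            assert t_eff[name] == pytest.approx(t_null[name], abs=1e-12)
            if spec.age_sensitive:
                # older is worse: raw score moves by -d * beta * 20 ability SDs
                expected = t_eff[name] - spec.direction_sign * 0.03 * 20 * spec.calib_sd
                assert t_old[name] == pytest.approx(expected, abs=1e-9)
            else:
                assert t_old[name] == pytest.approx(t_eff[name], abs=1e-12)

    def test_age_insensitive_task_independent_of_age(self, registry):
        """Syllable Stacks (age-insensitive) shows no age gradient in the
        planted thresholds, while an age-sensitive task does."""
        cfg = cb.CohortConfig(seed=0)
        rng = np.random.default_rng(0)
        profiles = cb.sample_demographics(3000, cfg, rng)
        rows = [cb.sample_latent_abilities(p, registry, cfg, rng)[1] for p in profiles]
        ages = np.array([p.age_years for p in profiles])
        stacks = np.array([r["Syllable Stacks"] for r in rows])
        scene = np.array([r["Scene Crasher"] for r in rows])
        assert abs(spearmanr(ages, stacks)[0]) < 0.05
        assert spearmanr(ages, scene)[0] < -0.3  # higher-better, older worse

    def test_correlation_sign_pattern_matches_loading_structure(self, registry):
        """With age and modality effects off, the planted thresholds'
        correlation matrix reproduces the sign pattern of ΛΛᵀ (closed-form
        oracle for the linear generative model)."""
        cfg = cb.CohortConfig(age_effect_per_year=0.0, modality_offset_sd=0.0, seed=1)
        rng = np.random.default_rng(1)
        profiles = cb.sample_demographics(5000, cfg, rng)
        rows = [cb.sample_latent_abilities(p, registry, cfg, rng)[1] for p in profiles]
        thetas = pd.DataFrame(rows)[registry.names].to_numpy()
        emp = np.corrcoef(thetas, rowvar=False)
        L = registry.loading_matrix()
        pop = L @ L.T
        strong = (np.abs(pop) >= 0.15) & ~np.eye(29, dtype=bool)
        agree = np.sign(emp[strong]) == np.sign(pop[strong])
        assert agree.mean() > 0.98


class TestStudyDataset:
    def test_schema_and_invariants(self, study_dataset, registry):
        study_dataset.validate()
        res = study_dataset.results
        assert list(res.columns) == list(cb.StudyDataset.RESULT_COLUMNS)
        assert len(res) <= 414 * 29
        assert not res.duplicated(["participant_id", "assessment"]).any()
        for spec in registry:
            sub = res[res["assessment"] == spec.name]
            assert sub["score"].between(spec.score_min, spec.score_max).all()

    def test_determinism_and_seed_sensitivity(self):
        cfg = cb.CohortConfig(n_participants=60, seed=21)
        a = cb.generate_study_dataset(cfg)
        b = cb.generate_study_dataset(cb.CohortConfig(n_participants=60, seed=21))
        pd.testing.assert_frame_equal(a.results, b.results)
        assert a.participants == b.participants
        c = cb.generate_study_dataset(cb.CohortConfig(n_participants=60, seed=22))
        assert not a.results.equals(c.results)

    def test_serialization_roundtrip(self, tmp_path):
        cfg = cb.CohortConfig(n_participants=40, seed=5)
        ds = cb.generate_study_dataset(cfg)
        ds.to_dir(tmp_path / "run")
        back = cb.StudyDataset.from_dir(tmp_path / "run")
        assert back.participants == ds.participants
        pd.testing.assert_frame_equal(
            back.results.reset_index(drop=True), ds.results.reset_index(drop=True),
            check_dtype=False,
        )
        assert back.seed == 5 and back.config_hash == cfg.config_hash()

    def test_scores_calibrate_to_reference_targets(self, study_dataset, registry):
        """For tasks without strong bound effects the simulated score mean
        and SD sit near the published calibration targets."""
        res = study_dataset.results
        for name in ("Fine Tuning", "Scene Crasher", "Juggle Factor", "Syllable Stacks"):
            spec = registry[name]
            sub = res[res["assessment"] == name]["score"]
            assert abs(sub.mean() - spec.calib_mean) < 0.5 * spec.calib_sd
            assert 0.6 * spec.calib_sd < sub.std() < 1.4 * spec.calib_sd

    def test_planted_thresholds_recovered_by_observed_scores(self, study_dataset, registry):
        """Parameter recovery: Spearman(planted theta80, observed score)
        is high for every assessment with enough takers."""
        res = study_dataset.results
        for spec in registry:
            sub = res[res["assessment"] == spec.name]
            if len(sub) >= 80:
                rho = spearmanr(sub["true_theta80"], sub["score"])[0]
                assert rho > 0.8, spec.name

    def test_age_variance_helper_matches_marginals(self):
        cfg = cb.CohortConfig()
        ages = np.array([p.age_years for p in cb.sample_demographics(40000, cfg)])
        assert _age_variance(cfg) == pytest.approx(ages.var(), rel=0.05)
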