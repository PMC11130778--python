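import numpy as np
import pandas as pd
import pytest

import cogbattery as cb
from cogbattery.errors import ConfigError, FactorInputError, FactorRetentionError
from cogbattery.factors import varimax

PAPER_CORE_14 = {
    "Scene Crasher", "Syllable Stacks", "To-Do List Training", "Double Decision",
    "Divided Attention", "Eye For Detail", "Face Facts", "Face To Face",
    "Fine Tuning", "Mixed Signals", "Optic Flow", "Recognition",
    "Sound Sweeps", "Target Tracker",
}


def orthogonal_data(n, p, seed=0):
    """Data whose sample correlation matrix is exactly the identity."""
    x = np.random.default_rng(seed).standard_normal((n, p))
    q, _ = np.linalg.qr(x - x.mean(axis=0))
    return pd.DataFrame(q, columns=[f"v{i}" for i in range(p)])


def clean_factor_data(k, n, seed, p=29, loading=0.6):
    rng = np.random.default_rng(seed)
    L = np.zeros((p, k))
    for j in range(p):
        L[j, j % k] = loading
    psi = 1 - (L ** 2).sum(axis=1)
    x = rng.standard_normal((n, k)) @ L.T + rng.standard_normal((n, p)) * np.sqrt(psi)
    return pd.DataFrame(x, columns=[f"v{i}" for i in range(p)]), L


class TestSuitability:
    def test_identity_correlation_gives_zero_bartlett(self):
        frame = orthogonal_data(100, 6)
        s = cb.suitability_stats(frame)
        assert s.bartlett_chi2 == pytest.approx(0.0, abs=1e-8)
        assert s.bartlett_df == 15
        # KMO degenerates with no off-diagonal correlation
        assert np.isnan(s.kmo_overall) or s.kmo_overall < 0.6

    def test_kmo_matches_direct_formula_evaluation(self):
        """Overall KMO recomputed by hand from Σr² / (Σr² + Σq²) with the
        partial correlations taken from the inverse correlation matrix."""
        frame = pd.DataFrame(
            np.random.default_rng(5).standard_normal((60, 3)) @ np.array(
                [[1.0, 0.4, 0.0], [0.0, 1.0, 0.5], [0.0, 0.0, 1.0]]
            ),
            columns=list("abc"),
        )
        s = cb.suitability_stats(frame)
        R = np.corrcoef(frame.to_numpy(), rowvar=False)
        Rinv = np.linalg.inv(R)
        d = np.sqrt(np.diag(Rinv))
        q = -Rinv / np.outer(d, d)
        off = ~np.eye(3, dtype=bool)
        expected = np.sum(R[off] ** 2) / (np.sum(R[off] ** 2) + np.sum(q[off] ** 2))
        assert s.kmo_overall == pytest.approx(expected, abs=1e-12)

    def test_four_factor_data_is_factorable(self):
        frame, _ = clean_factor_data(4, 500, seed=2)
        s = cb.suitability_stats(frame)
        assert s.bartlett_p < 0.001
        assert s.kmo_overall > 0.6

    def test_singular_matrix_advises_pruning(self):
        x = np.random.default_rng(0).standard_normal((50, 3))
        frame = pd.DataFrame(np.column_stack([x, x[:, 0]]), columns=list("abcd"))
        with pytest.raises(FactorInputError, match="prune"):
            cb.suitability_stats(frame)


class TestVarimax:
    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_preserves_communalities(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(0, 0.5, size=(20, 4))
        rotated = varimax(L)
        assert np.allclose((rotated ** 2).sum(axis=1), (L ** 2).sum(axis=1), atol=1e-8)

    def test_rotation_recovers_simple_structure(self):
        # rotate an orthogonally mixed simple structure back to simplicity
        L = np.zeros((12, 2))
        L[:6, 0] = 0.7
        L[6:, 1] = 0.7
        angle = 0.6
        T = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        rotated = varimax(L @ T)
        assert cb.tucker_congruence(rotated, L) > 0.999


class TestRetention:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_parallel_analysis_recovers_planted_factor_count(self, k):
        for seed in range(5):
            frame, _ = clean_factor_data(k, 500, seed=seed)
            sol = cb.fit_factor_solution(frame, retention="parallel")
            assert sol.k_retained == k, (k, seed)

    def test_kaiser_option_and_fixed_count(self):
        frame, _ = clean_factor_data(3, 500, seed=0)
        sol = cb.fit_factor_solution(frame, retention=4)
        assert sol.k_retained == 4 and sol.retention == "fixed:4"
        kaiser = cb.fit_factor_solution(frame, retention="kaiser")
        assert kaiser.k_retained >= 3  # Kaiser never under-factors here

    def test_identity_correlation_retains_nothing(self):
        frame = orthogonal_data(200, 8)
        with pytest.raises(FactorRetentionError):
            cb.fit_factor_solution(frame, retention="kaiser")

    def test_unknown_rules_rejected(self):
        frame, _ = clean_factor_data(2, 100, seed=0)
        with pytest.raises(ConfigError):
            cb.fit_factor_solution(frame, retention="scree")
        with pytest.raises(ConfigError):
            cb.fit_factor_solution(frame, rotation="promax")


class TestLoadingsAndFlags:
    def test_signed_flag_rule_ignores_large_negative_loadings(self):
        """A variable loading -0.6 on an otherwise-positive factor stays
        unflagged under the signed rule but is flagged in absolute mode."""
        rng = np.random.default_rng(3)
        L = np.zeros((12, 2))
        L[:6, 0] = 0.65
        L[5, 0] = -0.65  # the contrarian variable
        L[6:, 1] = 0.65
        psi = 1 - (L ** 2).sum(axis=1)
        x = rng.standard_normal((2000, 2)) @ L.T + rng.standard_normal((2000, 12)) * np.sqrt(psi)
        frame = pd.DataFrame(x, columns=[f"v{i}" for i in range(12)])
        sol = cb.fit_factor_solution(frame, retention=2)
        assert sol.loadings.loc["v5"].min() < -0.4
        assert not sol.flags.loc["v5"].any()
        assert sol.flags.loc["v0"].any()
        sol_abs = cb.fit_factor_solution(frame, retention=2, signed_flags=False)
        assert sol_abs.flags.loc["v5"].any()

    def test_rotated_loadings_recover_planted_values(self):
        frame, L = clean_factor_data(4, 3000, seed=1)
        sol = cb.fit_factor_solution(frame, retention=4)
        assert cb.tucker_congruence(sol.loadings.to_numpy(), L) > 0.95
        anchors = sol.loadings.max(axis=1)
        assert (anchors > 0.4).mean() > 0.9  # planted 0.6 loadings flagged


class TestSelection:
    def test_reference_fixtures_reproduce_published_core_battery(self, registry):
        inputs = cb.reference_selection_inputs(registry)
        report = cb.select_core_battery(inputs)
        assert set(report.retained) == PAPER_CORE_14
        assert len(report.retained) == 14

    def test_auditory_ace_excluded_with_both_reasons(self, registry):
        report = cb.select_core_battery(cb.reference_selection_inputs(registry))
        reasons = report.exclusion_reasons("Auditory Ace")
        assert any("unmodifiable" in r for r in reasons)
        assert any("education" in r for r in reasons)
        assert "Auditory Ace" not in report.retained

    def test_empty_inputs_give_empty_report(self):
        empty = pd.DataFrame(columns=list(cb.factors.SELECTION_COLUMNS))
        report = cb.select_core_battery(empty)
        assert report.retained == []

    def test_relaxing_criteria_never_shrinks_retained_set(self, registry):
        inputs = cb.reference_selection_inputs(registry)
        base = set(cb.select_core_battery(inputs, cb.SelectionCriteria()).retained)
        relaxed = cb.SelectionCriteria(
            age_scaling_overrides=tuple(registry.names),
            usable_bounds_overrides=tuple(registry.names),
            distinct_factor_overrides=tuple(registry.names),
        )
        widened = set(cb.select_core_battery(inputs, relaxed).retained)
        assert base <= widened
        # partial relaxations, one criterion at a time
        for kwargs in (
            {"age_scaling_overrides": tuple(registry.names)},
            {"usable_bounds_overrides": tuple(registry.names)},
            {"distinct_factor_overrides": tuple(registry.names)},
        ):
            mid = set(cb.select_core_battery(inputs, cb.SelectionCriteria(**kwargs)).retained)
            assert base <= mid <= widened

    def test_mismatched_inputs_rejected(self, study_dataset, registry):
        desc = cb.descriptives_table(study_dataset, registry)
        assoc = cb.association_screen(study_dataset, registry=registry)
        wide = cb.completer_score_matrix(study_dataset, registry)
        z = cb.zscore_transform(wide, registry, "raw_orientation")
        sol = cb.fit_factor_solution(z, retention=4)
        inputs = cb.build_selection_inputs(desc, assoc, sol, registry)
        assert set(inputs.index) == set(registry.names)
        with pytest.raises(ConfigError, match="mismatch"):
            cb.build_selection_inputs(desc[desc["assessment"] != "Hawk Eye"], assoc, sol, registry)

    def test_full_pipeline_selection_respects_conjunction(self, study_dataset, registry):
        desc = cb.descriptives_table(study_dataset, registry)
        assoc = cb.association_screen(study_dataset, registry=registry)
        wide = cb.completer_score_matrix(study_dataset, registry)
        z = cb.zscore_transform(wide, registry, "raw_orientation")
        sol = cb.fit_factor_solution(z, retention=4)
        inputs = cb.build_selection_inputs(desc, assoc, sol, registry)
        report = cb.select_core_battery(inputs)
        t = report.table
        assert (t["retained"] == (
            t["usable_bounds"] & t["age_scaling"]
            & t["demographic_agnostic"] & t["distinct_factor"]
        )).all()
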