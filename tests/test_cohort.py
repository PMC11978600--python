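"""Synthetic cohort generator: structure, moments, and seed contracts."""

import numpy as np
import pandas as pd
import pytest

from cogtraj.cohort import (
    ARCHETYPE_NAMES,
    ArchetypeSpec,
    CohortConfig,
    ConfigurationError,
    DEFAULT_ARCHETYPES,
    DEFAULT_RISK_TABLE,
    apply_missingness,
    default_loading_matrix,
    default_score_names,
    direction_flags,
    generate_cohort,
    generate_cognitive_scores,
    generate_mri,
    generate_risk_factors,
)


class TestCohortStructure:
    def test_default_config_yields_582_unique_participants(self, default_cohort):
        assert len(default_cohort.participants) == 582
        assert default_cohort.truth.index.nunique() == 582

    def test_wave_membership_counts_match_overlap_arithmetic(self, default_cohort):
        from collections import Counter
        counts = Counter(p.wave_membership for p in default_cohort.participants)
        assert counts[(1, 2, 3)] == 99
        assert counts[(1, 2)] == 37
        assert counts[(1, 3)] == 10
        assert counts[(1,)] == 65
        assert counts[(2,)] == 367
        assert counts[(3,)] == 4

    def test_visit_ages_increasing_within_range_and_windows(self, default_cohort):
        cfg = default_cohort.config
        for p in default_cohort.participants:
            ages = np.array(p.visit_ages)
            assert 1 <= len(ages) <= 3
            assert len(ages) == len(p.wave_membership)
            assert (np.diff(ages) > 0).all()
            assert (ages >= cfg.age_range[0]).all() and (ages <= cfg.age_range[1]).all()

    def test_inconsistent_wave_arithmetic_raises_with_explanation(self):
        cfg = CohortConfig(n_participants=500)  # true count is 582
        with pytest.raises(ConfigurationError, match="582"):
            cfg.validate()

    def test_minimal_single_wave_cohort(self):
        cfg = CohortConfig(n_participants=1, wave_sizes=(1, 0, 0),
                           wave_overlaps=(0, 0, 0), n_cognitive_scores=5,
                           loading_matrix_rank=2)
        cohort = generate_cohort(cfg)
        assert len(cohort.participants) == 1
        assert len(cohort.participants[0].visit_ages) >= 1

    def test_same_seed_reproduces_cohort_different_seed_changes_it(self, small_config):
        import dataclasses
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        pd.testing.assert_frame_equal(a.cognitive, b.cognitive)
        pd.testing.assert_series_equal(a.truth, b.truth)
        c = generate_cohort(dataclasses.replace(small_config, seed=8))
        assert not a.truth.equals(c.truth)

    def test_stimulation_frequency_above_nyquist_rejected(self):
        cfg = CohortConfig(eeg_sampling_hz=60.0)
        with pytest.raises(ConfigurationError, match="Nyquist"):
            cfg.validate()


class TestArchetypes:
    def test_default_archetype_invariants(self):
        by = {s.name: s for s in DEFAULT_ARCHETYPES}
        assert set(by) == set(ARCHETYPE_NAMES)
        assert abs(sum(s.mixing_weight for s in DEFAULT_ARCHETYPES) - 1) < 1e-9
        low = max(by["low_stable"].baseline_level, by["low_declining"].baseline_level)
        high = min(by["high_upper"].baseline_level, by["high_lower"].baseline_level)
        assert low < high
        assert min(DEFAULT_ARCHETYPES, key=lambda s: s.slope_per_year).name == "low_declining"

    def test_bad_mixing_weights_rejected(self):
        bad = tuple(
            ArchetypeSpec(s.name, s.baseline_level, s.slope_per_year, 0.3)
            for s in DEFAULT_ARCHETYPES
        )
        with pytest.raises(ConfigurationError, match="weights"):
            CohortConfig(archetypes=bad).validate()


class TestCognitiveScores:
    def test_noiseless_identity_loading_reproduces_latent(self, small_cohort):
        cfg = small_cohort.config
        L = np.zeros((cfg.n_cognitive_scores, cfg.loading_matrix_rank))
        L[:, 0] = 1.0
        table = generate_cognitive_scores(small_cohort, loading_matrix=L, noise_sd=0.0,
                                          intercepts=np.zeros(cfg.n_cognitive_scores))
        by = {s.name: s for s in cfg.archetypes}
        # all scores at one visit equal the (scalar) latent value
        wide = table.pivot(index=["participant_id", "visit_index"],
                           columns="variable", values="value")
        spread = wide.max(axis=1) - wide.min(axis=1)
        assert float(spread.max()) < 1e-12
        # and the latent tracks level + slope * (age - 57) up to the intercept
        p = small_cohort.participants[0]
        spec = by[p.archetype]
        vals = wide.loc[p.id].iloc[:, 0].to_numpy()
        expected_shape = np.array(
            [spec.baseline_level + spec.slope_per_year * (a - 57) for a in p.visit_ages]
        )
        offset = vals - expected_shape
        assert np.allclose(offset, offset[0], atol=1e-12)  # constant participant intercept

    def test_flagged_latency_test_increases_for_decliner(self):
        cfg = CohortConfig(seed=3)
        cohort = generate_cohort(cfg)
        flags = direction_flags(default_score_names(cfg.n_cognitive_scores))
        flagged = flags[flags].index[0]
        decliners = [p.id for p in cohort.participants
                     if p.archetype == "low_declining" and len(p.visit_ages) == 3]
        sub = cohort.cognitive.query("variable == @flagged and participant_id in @decliners")
        slopes = [np.polyfit(g["age"], g["value"], 1)[0]
                  for _, g in sub.groupby("participant_id")]
        assert np.mean(slopes) > 0  # worse (higher) over time on average

    def test_score_covariance_matches_loading_algebra(self):
        # single archetype, one narrow-age visit: analytic covariance is
        # intercept_sd^2 * a a' + B B' + noise_sd^2 I
        arch = (
            ArchetypeSpec("low_stable", -1.0, 0.0, 0.0),
            ArchetypeSpec("high_upper", 1.0, 0.0, 1.0),
            ArchetypeSpec("low_declining", -0.5, -0.1, 0.0),
            ArchetypeSpec("high_lower", 0.5, -0.05, 0.0),
        )
        n = 5000
        cfg = CohortConfig(
            n_participants=n, wave_sizes=(n, 0, 0), wave_overlaps=(0, 0, 0),
            wave_age_windows=((57.0, 57.01), (61, 67), (66, 68)),
            n_cognitive_scores=12, loading_matrix_rank=4, archetypes=arch, seed=5,
        )
        cohort = generate_cohort(cfg)
        L, intercepts = default_loading_matrix(cfg)
        X = cohort.cognitive.pivot(index=["participant_id", "visit_index"],
                                   columns="variable", values="value")
        X = X[default_score_names(12)].to_numpy()
        emp = np.cov(X, rowvar=False)
        a = L[:, 0]
        B = L[:, 1:]
        analytic = (cfg.intercept_sd**2) * np.outer(a, a) + B @ B.T \
            + cfg.noise_sd**2 * np.eye(12)
        # entrywise 3-standard-error bound for covariance estimates
        se = np.sqrt((np.outer(np.diag(analytic), np.diag(analytic)) + analytic**2) / n)
        assert (np.abs(emp - analytic) < 3.5 * se + 1e-3).all()


class TestMRI:
    def test_ventricles_grow_for_all_archetypes(self, default_cohort):
        mri = default_cohort.mri
        vent = mri[mri["variable"] == "lateral_ventricle"]
        arch = {p.id: p.archetype for p in default_cohort.participants}
        for archetype in ARCHETYPE_NAMES:
            ids = [i for i, a in arch.items() if a == archetype]
            sub = vent[vent["participant_id"].isin(ids)]
            slopes = [np.polyfit(g["age"], g["value"], 1)[0]
                      for _, g in sub.groupby("participant_id") if len(g) >= 2]
            assert np.mean(slopes) > 0

    def test_zero_atrophy_zero_noise_constant_volumes(self, small_cohort):
        table, _ = generate_mri(small_cohort, atrophy_scale=0.0, noise_sd=0.0)
        per = table.groupby(["participant_id", "variable"])["value"].nunique()
        assert (per == 1).all()

    def test_decliners_atrophy_neocortex_faster_than_high_performers(self):
        n = 2000
        cfg = CohortConfig(
            n_participants=n, wave_sizes=(n, n, n), wave_overlaps=(n, n, 0),
            n_cognitive_scores=5, loading_matrix_rank=2, seed=21,
        )
        cohort = generate_cohort(cfg)
        table = cohort.mri
        sub = table[table["variable"] == "frontal_cortex"]
        arch = {p.id: p.archetype for p in cohort.participants}
        slopes = {"low_declining": [], "high_upper": []}
        for pid, g in sub.groupby("participant_id"):
            if arch[pid] in slopes and len(g) >= 2:
                base = g["value"].mean()
                slopes[arch[pid]].append(np.polyfit(g["age"], g["value"] / base, 1)[0])
        from scipy import stats as sst
        t = sst.ttest_ind(slopes["low_declining"], slopes["high_upper"])
        assert np.mean(slopes["low_declining"]) < np.mean(slopes["high_upper"])
        assert t.pvalue < 1e-6

    def test_icv_positive_and_constant_per_participant(self, small_cohort):
        assert (small_cohort.icv > 0).all()
        assert small_cohort.icv.index.is_unique


class TestRiskFactors:
    def test_certain_prevalence_yields_all_yes(self, small_cohort):
        table = {"binary": {"always": {a: 1.0 for a in ARCHETYPE_NAMES}}}
        risk = generate_risk_factors(small_cohort, table)
        assert (risk["always"] == "yes").all()

    def test_invalid_probability_rejected(self, small_cohort):
        table = {"binary": {"bad": {a: 1.2 for a in ARCHETYPE_NAMES}}}
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            generate_risk_factors(small_cohort, table)

    def test_alcohol_prevalence_and_iq_ordering_at_large_n(self):
        n = 5000
        cfg = CohortConfig(n_participants=n, wave_sizes=(n, 0, 0),
                           wave_overlaps=(0, 0, 0), n_cognitive_scores=5,
                           loading_matrix_rank=2, seed=13)
        cohort = generate_cohort(cfg)
        risk = cohort.risk_factors
        arch = cohort.truth
        hl = risk[arch == "high_lower"]
        frac = (hl["alcohol_use"] == "yes").mean()
        assert abs(frac - 128 / 136) < 0.03
        iq = risk.groupby(arch)["iq_score"].mean()
        assert iq["high_upper"] > iq["high_lower"]
        assert iq["high_lower"] > max(iq["low_stable"], iq["low_declining"])

    def test_default_risk_table_probabilities_valid(self):
        for factor, per in DEFAULT_RISK_TABLE["binary"].items():
            for p in per.values():
                assert 0 <= p <= 1


class TestMissingness:
    def test_zero_rate_is_identity(self, small_cohort):
        out = apply_missingness(small_cohort.cognitive, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, small_cohort.cognitive)

    def test_rate_concentrates_on_target(self, default_cohort):
        table = default_cohort.cognitive
        n_cells = table[["participant_id", "visit_index"]].drop_duplicates().shape[0]
        out = apply_missingness(table, 0.3, seed=2)
        kept = out[["participant_id", "visit_index"]].drop_duplicates().shape[0]
        removed_frac = 1 - kept / n_cells
        assert abs(removed_frac - 0.3) < 0.05  # 827 cells: ~3 SE

    def test_same_seed_same_pattern_and_input_untouched(self, small_cohort):
        before = small_cohort.cognitive.copy()
        a = apply_missingness(small_cohort.cognitive, 0.4, seed=9)
        b = apply_missingness(small_cohort.cognitive, 0.4, seed=9)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(small_cohort.cognitive, before)
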