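"""Generator behaviour: calibration, stratification, judge mechanics."""

import numpy as np
import pytest

from clinlens import (
    CUE_NAMES,
    EcologyConfig,
    JudgePolicy,
    JudgePopulationSpec,
    ScenarioSet,
    StratumShortageError,
    generate_ecology,
    sample_scenario_set,
    simulate_judge,
    simulate_study,
)
from clinlens.synthetic import CONTINUOUS_CUES, DEFAULT_CRITERION_COEFS
from scipy.special import expit


def cue_matrix(cases):
    return np.vstack([c.cues() for c in cases])


class TestGenerateEcology:
    def test_deterministic_given_seed(self):
        cfg = EcologyConfig(n_cases=50, seed=7)
        assert generate_ecology(cfg) == generate_ecology(cfg)

    def test_marginal_moments_match_calibration(self, big_case_pool):
        """At n=10^4 the sample moments sit within 3 standard errors of the
        configured vital-sign distributions and consciousness frequencies."""
        x = cue_matrix(big_case_pool)
        n = len(big_case_pool)
        cfg = EcologyConfig()
        for j, name in enumerate(CONTINUOUS_CUES):
            mean, sd = cfg.cue_means[name], cfg.cue_sds[name]
            assert abs(x[:, j].mean() - mean) < 3 * sd / np.sqrt(n)
            # SE of the SD for a normal sample is about sd/sqrt(2n)
            assert abs(x[:, j].std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * n)
        freqs = np.bincount(x[:, 4].astype(int), minlength=3) / n
        for p_obs, p_target in zip(freqs, (0.65, 0.25, 0.10)):
            assert abs(p_obs - p_target) < 3 * np.sqrt(p_target * (1 - p_target) / n)

    def test_cue_intercorrelations_match_target(self, big_case_pool):
        x = cue_matrix(big_case_pool)[:, :4]
        sample = np.corrcoef(x, rowvar=False)
        target = EcologyConfig().cue_corr[:4, :4]
        assert np.max(np.abs(sample - target)) < 0.05

    def test_independent_cues_give_near_zero_correlations(self):
        cfg = EcologyConfig(n_cases=10_000, cue_corr=np.eye(5), seed=5)
        x = cue_matrix(generate_ecology(cfg))
        sample = np.corrcoef(x, rowvar=False)
        assert np.max(np.abs(sample - np.diag(np.diag(sample)))) < 0.05

    def test_null_criterion_coefs_give_half_prevalence(self):
        cfg = EcologyConfig(
            n_cases=10_000,
            criterion_coefs={c: 0.0 for c in (*CUE_NAMES, "intercept")},
            seed=9,
        )
        prevalence = np.mean([c.criterion for c in generate_ecology(cfg)])
        assert abs(prevalence - 0.5) < 0.02

    def test_non_positive_definite_corr_rejected(self):
        bad = np.full((5, 5), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99
        with pytest.raises(Exception, match="cue_corr"):
            EcologyConfig(cue_corr=bad)


class TestScenarioSampling:
    def test_default_structure(self, big_case_pool):
        ss = sample_scenario_set(big_case_pool, seed=3)
        assert ss.n_presentations == 25
        assert len(ss.unique_cases) == 20
        assert len(ss.repeat_map) == 5
        assert sum(c.criterion for c in ss.unique_cases) == 10
        # repeats: 3 at-risk and 2 not-at-risk cases
        repeated = [ss.case(ss.presentations[i]) for i in ss.repeat_map]
        assert sum(c.criterion for c in repeated) == 3
        # every repeat pair shows the same case twice
        for first, later in ss.repeat_pairs():
            assert ss.presentations[first] == ss.presentations[later]

    def test_minimal_sample_has_no_repeats(self, big_case_pool):
        ss = sample_scenario_set(big_case_pool, 1, 1, 0, 0, seed=0)
        assert ss.n_presentations == 2
        assert ss.repeat_map == {}

    def test_stratum_shortage_names_stratum(self, big_case_pool):
        small_pool = [c for c in big_case_pool if c.criterion == 1][:5] + [
            c for c in big_case_pool if c.criterion == 0
        ][:15]
        with pytest.raises(StratumShortageError, match="at-risk stratum holds 5"):
            sample_scenario_set(small_pool, n_risk=10, n_norisk=10, seed=0)


class TestSimulateJudge:
    def test_noise_free_deterministic_judge_is_repeat_consistent(self, big_case_pool):
        cfg = EcologyConfig()
        ss = sample_scenario_set(big_case_pool, seed=1)
        policy = JudgePolicy(weights=DEFAULT_CRITERION_COEFS, deterministic=True)
        js = simulate_judge(policy, ss, seed=0, standardizer=cfg.standardizer())
        for first, later in ss.repeat_pairs():
            assert js.judgements[first] == js.judgements[later]

    def test_judge_sharing_ecology_policy_attains_bruteforce_achievement(self):
        """A noise-free deterministic judge using the ecology's own policy
        reaches exactly the achievement computed by direct evaluation of
        both models on the whole case pool."""
        cfg = EcologyConfig(n_cases=2000, seed=21)
        cases = generate_ecology(cfg)
        ss = ScenarioSet.from_cases(cases)
        policy = JudgePolicy(weights=cfg.criterion_coefs, deterministic=True)
        js = simulate_judge(policy, ss, seed=0, standardizer=cfg.standardizer())

        # oracle: evaluate the generating model on every case directly
        std = cfg.standardizer()
        x = std.transform(ss.cue_matrix())
        w = np.array([cfg.criterion_coefs[c] for c in CUE_NAMES])
        p = expit(cfg.criterion_coefs["intercept"] + x @ w)
        oracle_judgements = (p > 0.5).astype(int)
        assert np.array_equal(js.as_array(), oracle_judgements)
        ye = ss.criterion()
        r_a = np.corrcoef(ye, js.as_array())[0, 1]
        assert np.isclose(r_a, np.corrcoef(ye, oracle_judgements)[0, 1])

    def test_infinite_temperature_limit_destroys_achievement(self):
        cfg = EcologyConfig(n_cases=400, seed=2)
        cases = generate_ecology(cfg)
        ss = ScenarioSet.from_cases(cases)
        ye = ss.criterion()
        policy = JudgePolicy(weights=DEFAULT_CRITERION_COEFS, response_temperature=1e9)
        r_as = []
        for seed in range(40):
            js = simulate_judge(policy, ss, seed=seed, standardizer=cfg.standardizer())
            r_as.append(np.corrcoef(ye, js.as_array())[0, 1])
        assert abs(np.mean(r_as)) < 0.03


class TestSimulateStudy:
    def test_study_shape(self):
        study = simulate_study(n_judges=97, seed=4)
        assert len(study.judgements) == 97 * 2
        assert all(len(js.judgements) == 25 for js in study.judgements)
        assert len(study.by_condition("paper")) == 97
        assert len(study.by_condition("physical")) == 97

    def test_equal_noise_gives_no_mean_achievement_difference(self):
        diffs = []
        for seed in range(6):
            study = simulate_study(
                n_judges=30,
                condition_noise={"a": 0.4, "b": 0.4},
                seed=seed,
            )
            ye = study.scenario_set.criterion()
            per_cond = {}
            for cond in study.conditions:
                r = [
                    np.corrcoef(ye, js.as_array())[0, 1]
                    for js in study.by_condition(cond)
                    if js.as_array().min() != js.as_array().max()
                ]
                per_cond[cond] = np.mean(r)
            diffs.append(per_cond["a"] - per_cond["b"])
        assert abs(np.mean(diffs)) < 0.04

    def test_mean_policy_matching_non_increasing_in_perception_noise(self):
        """Averaged over 20 seeds, the mean policy-matching G of the noisy
        arm never rises as the perception-noise level grows."""
        from clinlens.lens import lens_decomposition
        from clinlens.policy import fit_logistic

        levels = (0.0, 1.0, 2.5)
        mean_g = []
        for level in levels:
            g_all = []
            for seed in range(20):
                study = simulate_study(
                    judge_population_spec=JudgePopulationSpec(deterministic=True),
                    n_judges=30,
                    condition_noise={"a": level, "b": level},
                    seed=700 + seed,
                )
                idx = [CUE_NAMES.index(c) for c in CONTINUOUS_CUES]
                x = study.scenario_set.cue_matrix()[:, idx]
                ye = study.scenario_set.criterion()
                eco = fit_logistic(x, ye, cue_names=CONTINUOUS_CUES)
                for js in study.by_condition("a"):
                    ys = js.as_array()
                    if ys.min() == ys.max():
                        continue
                    judge = fit_logistic(x, ys, cue_names=CONTINUOUS_CUES)
                    g_all.append(lens_decomposition(eco, judge, ye, ys).G)
            mean_g.append(np.mean(g_all))
        assert mean_g[0] >= mean_g[1] >= mean_g[2]
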