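"""Lens model equation decomposition and relative weights."""

import numpy as np
import pytest
from scipy.special import expit

from _util import random_logistic_instance
from clinlens import (
    CUE_NAMES,
    DegenerateDataError,
    EcologyConfig,
    JudgePolicy,
    ScenarioSet,
    fit_logistic,
    generate_ecology,
    lens_decomposition,
    linear_lens_decomposition,
    relative_weights,
    simulate_judge,
)
from clinlens.synthetic import CONTINUOUS_CUES


def random_system_pair(rng, n=25, p=3):
    """Random cues, criterion, judgements and the two fitted models."""
    x, ye = random_logistic_instance(rng, n=n, p=p, corr=0.3)
    while True:
        ys = (rng.random(n) < expit(x @ rng.uniform(-1, 1, p))).astype(float)
        if ys.min() != ys.max():
            break
    return x, ye, ys, fit_logistic(x, ye), fit_logistic(x, ys)


class TestLogisticDecomposition:
    def test_identical_systems(self, rng):
        x, ye = random_logistic_instance(rng, n=40, p=3)
        fit = fit_logistic(x, ye)
        lp = lens_decomposition(fit, fit, ye, ye)
        assert lp.r_a == pytest.approx(1.0, abs=1e-12)
        assert lp.G == pytest.approx(1.0, abs=1e-12)
        assert lp.C1 == pytest.approx(1.0, abs=1e-12)
        assert lp.sd_ratio_Ye == pytest.approx(lp.sd_ratio_Ys, abs=1e-12)
        assert lp.sd_ratio_Ze == pytest.approx(lp.sd_ratio_Zs, abs=1e-12)
        assert abs(lp.identity_residual) <= 1e-12

    def test_random_judgements_carry_no_achievement(self, rng):
        """Monte-Carlo null: outcome-independent judges achieve r_a near 0
        on every draw, and G (whose single-draw value is an arbitrary
        correlation between random directions in the cue span) is zero in
        expectation over judges."""
        cases = generate_ecology(EcologyConfig(n_cases=10_000, seed=8))
        ss = ScenarioSet.from_cases(cases)
        idx = [CUE_NAMES.index(c) for c in CONTINUOUS_CUES]
        x = ss.cue_matrix()[:, idx]
        ye = ss.criterion()
        eco = fit_logistic(x, ye)
        g_values = []
        for _ in range(30):
            ys = (rng.random(len(ye)) < 0.5).astype(float)
            lp = lens_decomposition(eco, fit_logistic(x, ys), ye, ys)
            assert abs(lp.r_a) < 0.05
            g_values.append(lp.G)
        assert abs(np.mean(g_values)) < 0.10

    def test_four_term_identity_reproduces_achievement(self, rng):
        """The right-hand side equals an independently computed Pearson
        correlation of criterion and judgements, to 1e-10, because
        Y = prediction + residual exactly."""
        for _ in range(30):
            x, ye, ys, eco, judge = random_system_pair(rng)
            lp = lens_decomposition(eco, judge, ye, ys)
            oracle_r = np.corrcoef(ye, ys)[0, 1]
            assert abs(lp.rhs - oracle_r) <= 1e-10
            assert abs(lp.identity_residual) <= 1e-10

    def test_swap_symmetry(self, rng):
        x, ye, ys, eco, judge = random_system_pair(rng, n=40)
        lp = lens_decomposition(eco, judge, ye, ys)
        swapped = lens_decomposition(judge, eco, ys, ye)
        assert swapped.r_a == pytest.approx(lp.r_a, abs=1e-12)
        assert swapped.G == pytest.approx(lp.G, abs=1e-12)
        assert swapped.C2 == pytest.approx(lp.C3, abs=1e-12)
        assert swapped.C3 == pytest.approx(lp.C2, abs=1e-12)

    def test_constant_vectors_rejected_with_name(self, rng):
        x, ye, ys, eco, judge = random_system_pair(rng)
        with pytest.raises(DegenerateDataError, match="judgements"):
            lens_decomposition(eco, judge, ye, np.ones_like(ys))
        with pytest.raises(DegenerateDataError, match="criterion"):
            lens_decomposition(eco, judge, np.zeros_like(ye), ys)


class TestLinearDecomposition:
    def test_perfect_judge(self, rng):
        x = rng.standard_normal((30, 3))
        ye = x @ np.array([1.0, -0.5, 0.2]) + 0.3 * rng.standard_normal(30)
        lp = linear_lens_decomposition(x, ye, ye)
        assert lp.r_a == pytest.approx(1.0, abs=1e-10)
        assert lp.G == pytest.approx(1.0, abs=1e-10)
        assert lp.Re == pytest.approx(lp.Rs, abs=1e-12)

    def test_cross_terms_vanish_and_classical_identity_holds(self, rng):
        """OLS residuals are orthogonal to the shared cue space, so C2 and
        C3 vanish and the classical two-term equation reproduces the
        achievement correlation."""
        for _ in range(20):
            x = rng.standard_normal((30, 3))
            ye = x @ rng.uniform(-1, 1, 3) + rng.standard_normal(30)
            ys = x @ rng.uniform(-1, 1, 3) + rng.standard_normal(30)
            lp = linear_lens_decomposition(x, ye, ys)
            assert abs(lp.C2) <= 1e-10
            assert abs(lp.C3) <= 1e-10
            classical = lp.G * lp.Re * lp.Rs + lp.C1 * np.sqrt(
                (1 - lp.Re**2) * (1 - lp.Rs**2)
            )
            assert classical == pytest.approx(np.corrcoef(ye, ys)[0, 1], abs=1e-10)
            # in the linear mode the SD ratios coincide with Re and Rs
            assert lp.sd_ratio_Ye == pytest.approx(lp.Re, abs=1e-10)
            assert lp.sd_ratio_Ys == pytest.approx(lp.Rs, abs=1e-10)


class TestRelativeWeights:
    def _policy(self, coefs, sds, included=None, candidates=None, **kw):
        from clinlens.policy import FittedPolicy

        candidates = candidates or tuple(coefs)
        included = included if included is not None else tuple(coefs)
        return FittedPolicy(
            candidate_cues=candidates,
            included_cues=included,
            coefficients=coefs,
            intercept=0.0,
            standard_errors={"intercept": 0.1, **{c: 0.1 for c in included}},
            fitted_probs=np.full(4, 0.5),
            residuals=np.zeros(4),
            converged=True,
            separation=False,
            log_likelihood=0.0,
            n_iter=1,
            cue_sds=sds,
        )

    def test_single_cue_gets_unit_weight(self):
        rw = relative_weights(self._policy({"a": 2.3}, {"a": 1.0, "b": 3.0},
                                           candidates=("a", "b"), included=("a",)))
        assert rw.weights == {"a": 1.0, "b": 0.0}
        assert rw.excluded_cues == ("b",)

    def test_sign_restoration_and_symmetry(self):
        rw = relative_weights(self._policy({"a": 1.0, "b": -1.0}, {"a": 2.0, "b": 2.0}))
        assert rw.weights["a"] == pytest.approx(0.5)
        assert rw.weights["b"] == pytest.approx(-0.5)

    def test_standardization_by_cue_sd(self):
        rw = relative_weights(
            self._policy({"a": 2.0, "b": 1.0, "c": 1.0}, {"a": 1.0, "b": 2.0, "c": 2.0})
        )
        assert rw.as_array() == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_absolute_weights_sum_to_one(self, rng):
        for _ in range(20):
            x, y = random_logistic_instance(rng, n=60, p=4)
            fit = fit_logistic(x, y)
            rw = relative_weights(fit)
            if not rw.all_zero:
                assert sum(abs(w) for w in rw.weights.values()) == pytest.approx(1.0)

    def test_invariant_to_cue_rescaling(self, rng):
        x, y = random_logistic_instance(rng, n=200, p=3)
        rw1 = relative_weights(fit_logistic(x, y))
        x2 = x.copy()
        x2[:, 0] *= 1000.0  # change of units
        rw2 = relative_weights(fit_logistic(x2, y))
        assert rw1.as_array() == pytest.approx(rw2.as_array(), abs=1e-6)

    def test_zero_sd_rejected(self):
        with pytest.raises(Exception, match="'a'"):
            relative_weights(self._policy({"a": 1.0}, {"a": 0.0}))


class TestWeightRecovery:
    def test_recovers_known_standardized_weights(self):
        """Judges simulated from known standardized weights, no perception
        noise, n=5000 cases: the fitted relative weights land within 0.05
        (L-infinity) of the normalized truth in >= 9/10 replicates."""
        cfg = EcologyConfig(n_cases=5000, seed=77)
        cases = generate_ecology(cfg)
        ss = ScenarioSet.from_cases(cases)
        idx = [CUE_NAMES.index(c) for c in CONTINUOUS_CUES]
        x = ss.cue_matrix()[:, idx]
        hits = 0
        master = np.random.default_rng(123)
        for rep in range(10):
            w = master.uniform(0.3, 1.5, 4) * master.choice([-1, 1], 4)
            policy = JudgePolicy(
                weights={**dict(zip(CONTINUOUS_CUES, w)), "intercept": 0.0}
            )
            js = simulate_judge(policy, ss, seed=master, standardizer=cfg.standardizer())
            rw = relative_weights(fit_logistic(x, js.as_array(), cue_names=CONTINUOUS_CUES))
            truth = w / np.sum(np.abs(w))
            hits += np.max(np.abs(rw.as_array() - truth)) <= 0.05
        assert hits >= 9
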