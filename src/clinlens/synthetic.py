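"""Synthetic ecologies, scenario sets, and simulated judges.

The package analyses *double-system* judgement data: a set of patient
scenarios with a known dichotomous outcome (the ecology) and repeated
dichotomous risk judgements made on those scenarios by many participants
under two presentation conditions.  This module generates such data with
fully known ground truth so every downstream stage — policy capturing,
the lens model decomposition, consistency and cross-condition inference —
can be exercised and validated end to end.

The generative model
--------------------
Cases are drawn from a latent multivariate normal: four continuous vital
signs (systolic blood pressure, heart rate, respiration rate, temperature)
get configured marginal means/SDs, and the level of consciousness (alert /
reacting to voice / reacting to pain) is obtained by thresholding its
latent coordinate at the cumulative-probability cutpoints of the configured
category frequencies.  The dichotomous criterion ("at risk" of acute
deterioration) is Bernoulli with a logistic probability in the standardized
cues; its coefficients are the ground-truth ecological policy.

Simulated judges apply their own logistic policy to *perceived* cues:
the true standardized cues plus Gaussian perception noise whose magnitude
models the fidelity of the presentation condition (small for written case
vignettes, larger for a physical patient simulator).  Response stochasticity
is controlled separately, by a temperature on the linear predictor or by a
deterministic threshold, so cue-perception fidelity and response consistency
are independent dials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigurationError, StratumShortageError

CUE_NAMES: tuple[str, ...] = ("sbp", "hr", "rr", "temp", "consciousness")
CONTINUOUS_CUES: tuple[str, ...] = ("sbp", "hr", "rr", "temp")
CONSCIOUSNESS_LEVELS: tuple[str, ...] = ("A", "V", "P")  # alert, voice, pain

#: Default marginal moments of the continuous cues (natural units:
#: mmHg, beats/min, breaths/min, degrees Celsius).
DEFAULT_CUE_MEANS: dict[str, float] = {"sbp": 127.0, "hr": 93.0, "rr": 24.2, "temp": 37.08}
DEFAULT_CUE_SDS: dict[str, float] = {"sbp": 31.0, "hr": 22.0, "rr": 7.9, "temp": 0.90}

#: Default consciousness frequencies (A, V, P).
DEFAULT_CONSCIOUSNESS_PROBS: tuple[float, float, float] = (0.65, 0.25, 0.10)

#: Default cue intercorrelation matrix (order: sbp, hr, rr, temp,
#: consciousness-latent).  Six pairs sit in the 0.48-0.60 band — four of
#: them at or above 0.50 — and the remaining four pairs are mild, matching
#: the intercorrelation regime of acute-admission vital-sign data.
DEFAULT_CUE_CORR: np.ndarray = np.array(
    [
        [1.00, 0.52, 0.48, 0.30, 0.55],
        [0.52, 1.00, 0.58, 0.35, 0.48],
        [0.48, 0.58, 1.00, 0.25, 0.60],
        [0.30, 0.35, 0.25, 1.00, 0.20],
        [0.55, 0.48, 0.60, 0.20, 1.00],
    ]
)

#: Default ground-truth ecological policy on standardized cues.
#: Respiration rate dominates, consistent with its status as the most
#: informative single vital sign for deterioration risk.
DEFAULT_CRITERION_COEFS: dict[str, float] = {
    "sbp": 0.4,
    "hr": 0.5,
    "rr": 1.4,
    "temp": 0.3,
    "consciousness": 0.8,
    "intercept": 0.0,
}

DEFAULT_CONDITIONS: tuple[str, str] = ("paper", "physical")

#: Default per-cue perception-noise SDs (in units of each cue's generating
#: SD) for the two presentation conditions: near-faithful for written case
#: vignettes, substantially degraded for the physical simulator.
DEFAULT_CONDITION_NOISE: dict[str, float] = {"paper": 0.1, "physical": 0.8}

NoiseScope = Literal["presentation", "case"]


def _coef_vector(coefs: Mapping[str, float]) -> tuple[np.ndarray, float]:
    """Split a name->coefficient mapping into (cue-ordered weights, intercept)."""
    w = np.array([float(coefs.get(name, 0.0)) for name in CUE_NAMES])
    return w, float(coefs.get("intercept", 0.0))


@dataclass(frozen=True)
class CueStandardizer:
    """Generating means and SDs used to standardize cues inside policies.

    Ground-truth policies are defined on standardized cues; standardizing
    by the *generating* moments (not sample statistics) keeps those weights
    well-defined for recovery tests.  Consciousness is coded ordinally
    (A=0, V=1, P=2) and standardized by the moments implied by its category
    frequencies.
    """

    means: np.ndarray  # aligned with CUE_NAMES
    sds: np.ndarray

    def transform(self, cues: np.ndarray) -> np.ndarray:
        return (cues - self.means) / self.sds


@dataclass(frozen=True)
class EcologyConfig:
    """Configuration of the synthetic patient ecology."""

    n_cases: int = 200
    cue_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CUE_MEANS))
    cue_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CUE_SDS))
    cue_corr: np.ndarray = field(default_factory=lambda: DEFAULT_CUE_CORR.copy())
    consciousness_probs: tuple[float, float, float] = DEFAULT_CONSCIOUSNESS_PROBS
    criterion_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CRITERION_COEFS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.cue_corr, dtype=float)
        if corr.shape != (5, 5):
            raise ConfigurationError(f"cue_corr must be 5x5, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigurationError("cue_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ConfigurationError("cue_corr must have unit diagonal")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ConfigurationError(
                "cue_corr is not positive definite; supply a valid correlation matrix"
            ) from None
        probs = np.asarray(self.consciousness_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs <= 0) or abs(probs.sum() - 1.0) > 1e-8:
            raise ConfigurationError(
                "consciousness_probs must be 3 positive values summing to 1"
            )
        for name in CONTINUOUS_CUES:
            if self.cue_sds[name] <= 0:
                raise ConfigurationError(f"cue_sds[{name!r}] must be > 0")
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")

    @property
    def consciousness_moments(self) -> tuple[float, float]:
        """Mean and SD of the ordinal consciousness coding implied by its
        category frequencies."""
        p = np.asarray(self.consciousness_probs)
        levels = np.arange(3.0)
        mean = float(p @ levels)
        sd = float(np.sqrt(p @ levels**2 - mean**2))
        return mean, sd

    def standardizer(self) -> CueStandardizer:
        c_mean, c_sd = self.consciousness_moments
        means = np.array([*(self.cue_means[n] for n in CONTINUOUS_CUES), c_mean])
        sds = np.array([*(self.cue_sds[n] for n in CONTINUOUS_CUES), c_sd])
        return CueStandardizer(means=means, sds=sds)


@dataclass(frozen=True)
class CaseRecord:
    """One patient scenario: cue vector plus dichotomous criterion."""

    case_id: int
    sbp: float
    hr: float
    rr: float
    temp: float
    consciousness: int  # ordinal: A=0, V=1, P=2
    criterion: int  # 1 = at risk

    def cues(self) -> np.ndarray:
        """Cue vector aligned with :data:`CUE_NAMES` (ordinal consciousness)."""
        return np.array([self.sbp, self.hr, self.rr, self.temp, float(self.consciousness)])

    @property
    def consciousness_label(self) -> str:
        return CONSCIOUSNESS_LEVELS[self.consciousness]


@dataclass(frozen=True)
class ScenarioSet:
    """Ordered presentation list over a pool of unique cases.

    ``presentations`` holds one case id per presentation; ``repeat_map``
    maps the presentation index of each duplicate to the presentation index
    of its first occurrence, enabling repeat-consistency analysis.
    """

    presentations: tuple[int, ...]
    repeat_map: Mapping[int, int]
    unique_cases: tuple[CaseRecord, ...]

    def __post_init__(self) -> None:
        ids = {c.case_id for c in self.unique_cases}
        if not set(self.presentations) <= ids:
            raise ConfigurationError("presentations reference unknown case ids")
        for later, first in self.repeat_map.items():
            if not (0 <= first < later < len(self.presentations)):
                raise ConfigurationError("repeat_map indices out of order or range")
            if self.presentations[later] != self.presentations[first]:
                raise ConfigurationError("repeat_map links presentations of different cases")

    @property
    def n_presentations(self) -> int:
        return len(self.presentations)

    def case(self, case_id: int) -> CaseRecord:
        return self._index()[case_id]

    def _index(self) -> dict[int, CaseRecord]:
        return {c.case_id: c for c in self.unique_cases}

    def cue_matrix(self) -> np.ndarray:
        """(n_presentations x 5) matrix of cue values in natural units."""
        idx = self._index()
        return np.vstack([idx[cid].cues() for cid in self.presentations])

    def criterion(self) -> np.ndarray:
        """Criterion value per presentation (repeats inherit their case's)."""
        idx = self._index()
        return np.array([idx[cid].criterion for cid in self.presentations], dtype=int)

    def repeat_pairs(self) -> list[tuple[int, int]]:
        """(first occurrence, repeat) presentation-index pairs."""
        return sorted((first, later) for later, first in self.repeat_map.items())

    @classmethod
    def from_cases(cls, cases: Sequence[CaseRecord]) -> "ScenarioSet":
        """A plain one-presentation-per-case set with no repeats."""
        return cls(
            presentations=tuple(c.case_id for c in cases),
            repeat_map={},
            unique_cases=tuple(cases),
        )


@dataclass(frozen=True)
class JudgePolicy:
    """Ground-truth judgement policy of one simulated participant.

    ``weights`` act on standardized perceived cues; ``perception_sd`` is the
    per-cue SD of additive Gaussian noise on the standardized cue values
    (modelling presentation fidelity); ``response_temperature`` scales the
    linear predictor down before the Bernoulli draw (response consistency);
    ``deterministic`` replaces the draw with a threshold at p = 0.5.
    """

    weights: Mapping[str, float]
    perception_sd: Mapping[str, float] | float = 0.0
    response_temperature: float = 1.0
    deterministic: bool = False

    def __post_init__(self) -> None:
        if self.response_temperature <= 0:
            raise ConfigurationError("response_temperature must be > 0")
        if np.any(self.perception_sd_vector() < 0):
            raise ConfigurationError("perception_sd must be >= 0 elementwise")

    def perception_sd_vector(self) -> np.ndarray:
        if isinstance(self.perception_sd, Mapping):
            return np.array([float(self.perception_sd.get(n, 0.0)) for n in CUE_NAMES])
        return np.full(len(CUE_NAMES), float(self.perception_sd))


@dataclass(frozen=True)
class JudgementSet:
    """Dichotomous judgements of one participant in one condition,
    aligned with a scenario set's presentation order."""

    participant_id: int
    condition: str
    judgements: tuple[int, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.judgements, dtype=int)


@dataclass(frozen=True)
class JudgePopulationSpec:
    """Distribution from which individual judge policies are drawn.

    Each judge's standardized-cue weights are Gaussian around
    ``weight_mean`` with between-judge SD ``weight_sd`` (the intercept
    likewise).  By default the population is centred on the ecology's
    ground-truth policy — participants broadly know which vital signs
    matter — with substantial individual variation.
    """

    weight_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CRITERION_COEFS)
    )
    weight_sd: float = 0.3
    intercept_sd: float = 0.2
    #: 0.5 sharpens responses enough that pooled repeat-agreement phi lands
    #: in the moderately-high band typical of trained clinical raters.
    response_temperature: float = 0.5
    deterministic: bool = False


@dataclass(frozen=True)
class StudyData:
    """A complete simulated two-condition study."""

    cases: tuple[CaseRecord, ...]
    scenario_set: ScenarioSet
    judgements: tuple[JudgementSet, ...]  # one per participant x condition
    policies: tuple[JudgePolicy, ...]  # ground truth, one per participant
    conditions: tuple[str, str]
    standardizer: CueStandardizer

    def by_condition(self, condition: str) -> list[JudgementSet]:
        return [j for j in self.judgements if j.condition == condition]


def generate_ecology(config: EcologyConfig) -> list[CaseRecord]:
    """Draw a pool of patient cases from the configured ecology.

    Continuous cues come from a correlated multivariate normal with the
    configured marginal moments; consciousness from thresholding its latent
    coordinate at the cumulative cutpoints of ``consciousness_probs``; the
    criterion from a Bernoulli with logistic probability in the
    standardized cues.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    corr = np.asarray(config.cue_corr, dtype=float)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((config.n_cases, 5)) @ chol.T

    values = np.empty_like(z)
    for j, name in enumerate(CONTINUOUS_CUES):
        values[:, j] = config.cue_means[name] + config.cue_sds[name] * z[:, j]

    cuts = norm.ppf(np.cumsum(config.consciousness_probs)[:2])
    consciousness = np.digitize(z[:, 4], cuts)  # 0=A, 1=V, 2=P
    c_mean, c_sd = config.consciousness_moments

    # Standardized cues for the criterion model: the latent coordinates for
    # the continuous cues (identical to (value - mean)/sd) and the
    # standardized ordinal coding for consciousness.
    x_std = z.copy()
    x_std[:, 4] = (consciousness - c_mean) / c_sd
    w, intercept = _coef_vector(config.criterion_coefs)
    p_risk = expit(intercept + x_std @ w)
    criterion = (rng.random(config.n_cases) < p_risk).astype(int)

    return [
        CaseRecord(
            case_id=i,
            sbp=float(values[i, 0]),
            hr=float(values[i, 1]),
            rr=float(values[i, 2]),
            temp=float(values[i, 3]),
            consciousness=int(consciousness[i]),
            criterion=int(criterion[i]),
        )
        for i in range(config.n_cases)
    ]


def sample_scenario_set(
    cases: Sequence[CaseRecord],
    n_risk: int = 10,
    n_norisk: int = 10,
    repeats_risk: int = 3,
    repeats_norisk: int = 2,
    seed: int | np.random.Generator = 0,
) -> ScenarioSet:
    """Stratified scenario sample with consistency repeats.

    Draws ``n_risk`` at-risk and ``n_norisk`` not-at-risk cases without
    replacement, re-presents ``repeats_risk`` + ``repeats_norisk`` of them
    (chosen uniformly within their strata) a second time, and randomizes
    the presentation order.  The defaults give the 25-presentation /
    20-unique-case structure with 3 at-risk and 2 not-at-risk repeats.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    risk_pool = [c for c in cases if c.criterion == 1]
    norisk_pool = [c for c in cases if c.criterion == 0]
    for label, pool, want in (("at-risk", risk_pool, n_risk), ("not-at-risk", norisk_pool, n_norisk)):
        if len(pool) < want:
            raise StratumShortageError(
                f"{label} stratum holds {len(pool)} cases but {want} were requested"
            )
    if repeats_risk > n_risk or repeats_norisk > n_norisk:
        raise ConfigurationError("cannot repeat more cases than were sampled in a stratum")

    risk = [risk_pool[i] for i in rng.choice(len(risk_pool), size=n_risk, replace=False)]
    norisk = [norisk_pool[i] for i in rng.choice(len(norisk_pool), size=n_norisk, replace=False)]
    unique = risk + norisk

    repeated = [risk[i] for i in rng.choice(n_risk, size=repeats_risk, replace=False)] if repeats_risk else []
    repeated += [norisk[i] for i in rng.choice(n_norisk, size=repeats_norisk, replace=False)] if repeats_norisk else []

    ids = [c.case_id for c in unique] + [c.case_id for c in repeated]
    order = rng.permutation(len(ids))
    presentations = tuple(ids[i] for i in order)

    repeat_map: dict[int, int] = {}
    seen: dict[int, int] = {}
    for idx, cid in enumerate(presentations):
        if cid in seen:
            repeat_map[idx] = seen[cid]
        else:
            seen[cid] = idx

    return ScenarioSet(
        presentations=presentations,
        repeat_map=repeat_map,
        unique_cases=tuple(unique),
    )


def _perceived_cues(
    policy: JudgePolicy,
    scenarios: ScenarioSet,
    standardizer: CueStandardizer,
    rng: np.random.Generator,
    noise_scope: NoiseScope,
) -> np.ndarray:
    """Standardized cue matrix per presentation, after perception noise.

    With ``noise_scope='presentation'`` the noise is redrawn independently
    for every presentation, so a repeated case may be perceived differently
    the second time.  With ``'case'`` the judge mis-reads each unique case
    in a stable way within the condition: both presentations of a repeated
    case share the same perceived cues.
    """
    x = standardizer.transform(scenarios.cue_matrix())
    sd = policy.perception_sd_vector()
    if noise_scope == "presentation":
        noise = rng.standard_normal(x.shape) * sd
    elif noise_scope == "case":
        case_ids = sorted({c.case_id for c in scenarios.unique_cases})
        per_case = {cid: rng.standard_normal(len(CUE_NAMES)) * sd for cid in case_ids}
        noise = np.vstack([per_case[cid] for cid in scenarios.presentations])
    else:  # pragma: no cover - guarded by Literal type
        raise ConfigurationError(f"unknown noise_scope {noise_scope!r}")
    return x + noise


def simulate_judge(
    policy: JudgePolicy,
    scenarios: ScenarioSet,
    seed: int | np.random.Generator,
    standardizer: CueStandardizer,
    participant_id: int = 0,
    condition: str = "paper",
    noise_scope: NoiseScope = "presentation",
) -> JudgementSet:
    """Simulate one participant's judgements over a scenario set.

    Each presentation's cues are perturbed by perception noise, the policy's
    logistic probability is computed on the perceived standardized cues with
    the linear predictor divided by ``response_temperature``, and the
    judgement is a Bernoulli draw (or a threshold at p = 0.5 when the policy
    is deterministic).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = _perceived_cues(policy, scenarios, standardizer, rng, noise_scope)
    w, intercept = _coef_vector(policy.weights)
    p = expit((intercept + x @ w) / policy.response_temperature)
    if policy.deterministic:
        judgements = (p > 0.5).astype(int)
    else:
        judgements = (rng.random(len(p)) < p).astype(int)
    return JudgementSet(
        participant_id=participant_id,
        condition=condition,
        judgements=tuple(int(v) for v in judgements),
    )


def simulate_study(
    ecology_config: EcologyConfig | None = None,
    judge_population_spec: JudgePopulationSpec | None = None,
    n_judges: int = 97,
    condition_noise: Mapping[str, float | Mapping[str, float]] | None = None,
    seed: int = 0,
    noise_scope: NoiseScope = "case",
    scenario_kwargs: Mapping[str, int] | None = None,
) -> StudyData:
    """Simulate a full two-condition study.

    One scenario set (default: 25 presentations over 20 unique cases) is
    shared by all judges; each judge draws a single policy from the
    population and judges the set once per condition, with the condition's
    perception-noise level.  All randomness flows from ``seed`` through a
    per-stage seed split, so outputs are bit-identical across runs.

    The study-level default is ``noise_scope='case'``: a judge mis-reads
    each unique case in a stable way within a condition, so perception
    fidelity degrades what the judgements can track (achievement and
    policy matching) without touching repeat consistency — the separation
    the two-condition design is built to detect.  Pass
    ``noise_scope='presentation'`` to redraw the noise on every
    presentation instead, which makes consistency itself noise-dependent.
    """
    if n_judges < 1:
        raise ConfigurationError("n_judges must be >= 1")
    eco = ecology_config if ecology_config is not None else EcologyConfig()
    pop = judge_population_spec if judge_population_spec is not None else JudgePopulationSpec()
    noise = dict(DEFAULT_CONDITION_NOISE) if condition_noise is None else dict(condition_noise)
    conditions = tuple(noise)
    if len(conditions) != 2:
        raise ConfigurationError("condition_noise must name exactly two conditions")

    root = np.random.SeedSequence(seed)
    eco_seed, scen_seed, judge_seed = root.spawn(3)
    eco = replace(eco, seed=int(eco_seed.generate_state(1)[0] % (2**31)))
    cases = generate_ecology(eco)
    standardizer = eco.standardizer()
    scenario_set = sample_scenario_set(
        cases, seed=np.random.default_rng(scen_seed), **(dict(scenario_kwargs or {}))
    )

    w_mean, i_mean = _coef_vector(pop.weight_mean)
    judgement_sets: list[JudgementSet] = []
    policies: list[JudgePolicy] = []
    for pid, child in enumerate(judge_seed.spawn(n_judges)):
        rng = np.random.default_rng(child)
        w = w_mean + pop.weight_sd * rng.standard_normal(len(CUE_NAMES))
        intercept = i_mean + pop.intercept_sd * rng.standard_normal()
        for condition in conditions:
            policy = JudgePolicy(
                weights={**dict(zip(CUE_NAMES, w)), "intercept": intercept},
                perception_sd=noise[condition],
                response_temperature=pop.response_temperature,
                deterministic=pop.deterministic,
            )
            if condition == conditions[0]:
                policies.append(policy)  # same weights in both conditions
            judgement_sets.append(
                simulate_judge(
                    policy,
                    scenario_set,
                    seed=rng,
                    standardizer=standardizer,
                    participant_id=pid,
                    condition=condition,
                    noise_scope=noise_scope,
                )
            )

    return StudyData(
        cases=tuple(cases),
        scenario_set=scenario_set,
        judgements=tuple(judgement_sets),
        policies=tuple(policies),
        conditions=conditions,  # type: ignore[arg-type]
        standardizer=standardizer,
    )
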