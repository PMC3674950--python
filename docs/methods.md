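# Methods

## The double-system model

`clinlens` analyses judgement data in which a set of patient scenarios
carries both a dichotomous ecological criterion (the patient truly was
"at risk": died, was admitted to intensive/high-dependency care, or was
resuscitated) and dichotomous judgements by many participants, each
assessing every scenario in two presentation conditions. Five cues carry
the information: systolic blood pressure (mmHg), heart rate (beats/min),
respiration rate (breaths/min), temperature (°C), and level of
consciousness (alert / reacting to voice / reacting to pain, coded
ordinally 0/1/2).

Two logistic regressions over the same presentation series — criterion on
cues, and judgements on cues — yield predicted probabilities Ỹe, Ỹs and
raw residuals Z̃ = Y − Ỹ. Because the split Y = Ỹ + Z̃ is exact,
bilinearity of covariance makes the four-term decomposition of the
achievement correlation r_a = corr(Ye, Ys) an algebraic identity, not an
approximation; the implementation computes the identity residual on every
decomposition and rejects anything above 1e−10. All SDs and correlations
use the n−1 convention; the identity is invariant to that choice as long
as it is applied uniformly. In the linear mode (ordinary least squares on
a shared cue set) residuals are orthogonal to both prediction vectors, so
C2 = C3 = 0 and the equation collapses to the classical two-term form
with Re and Rs.

Raw residuals (not deviance or Pearson residuals) are used throughout:
they are the quantity whose sum with the prediction reconstructs Y, which
is what the identity requires.

Degenerate inputs are handled explicitly: constant criterion, judgement
or prediction vectors raise a degenerate-variance error naming the
offending vector (a participant who answers "yes" to everything has no
defined achievement); residual vectors with zero variance correlate as
zero, which is exact for the covariance they contribute.

## Fitting and guarding the policy models

The logistic fitter is Newton/IRLS with step halving, which makes the
log-likelihood non-decreasing at every accepted step (asserted each
iteration); convergence is declared when the largest coefficient change
falls below 1e−8, with a 100-iteration cap. Standard errors come from the
inverse observed information. With 25 dichotomous observations on
intercorrelated cues, quasi-complete separation is a practical hazard:
fits with any standardized-cue coefficient above 15 or standardized SE
above 5 are flagged and marked non-converged, but their predicted
probabilities are retained — correlations are scale-free, so a flagged
model still supports the decomposition even when its coefficients do not
support interpretation.

Relative cue weights instead require stable coefficients, so they come
from a forward-stepwise fit: cues enter by likelihood-ratio test at an
entry threshold drawn from the ladder (0.05, 0.10, 0.15, 0.20, 0.25),
and a candidate model is admissible only if it converges unflagged with
all standardized-coefficient SEs ≤ 5. If nothing can enter at one
threshold the next, more lenient one is tried; the guaranteed fallback is
the intercept-only model, in which every cue has weight exactly zero.
Candidates are examined in declared column order with ties broken by that
order, so the procedure is deterministic. Forward-only selection is used:
with at most four candidate cues and 25 cases, backward elimination adds
nothing but instability. The guard bounds (5 and 15 on standardized
coefficients) sit far outside plausible effect sizes for standardized
physiological cues and are configurable.

Weights follow β_i = B_i·SD(X_i) (the outcome-SD factor cancels in
normalization), RW_i = sign(β_i)·|β_i| / Σ_j |β_j|. The denominator uses
absolute values: a signed sum can be zero or negative, which would leave
the weights undefined or sign-flipped. |RW| sums to one whenever any
coefficient is nonzero, and the weights are invariant to changes of cue
units. Two model identities are recorded per participant — the full model
behind the lens parameters and the stepwise model behind the weights —
since the two legitimately differ.

The consciousness cue is excluded from both models by default: it is the
cue most intercorrelated with the others (lowest tolerance), and dropping
it keeps the 25-presentation fits stable enough to produce a complete
parameter set for every participant. `include_consciousness=True`
restores it. Tolerance (1 − R² of each cue on the rest) is reported as a
standing multicollinearity diagnostic.

## Consistency and cross-condition inference

Five of the 25 presentations repeat an earlier case. Each participant's
(first occurrence, repeat) pairs are pooled across participants into one
2×2 table per condition — five pairs per participant are too few for a
defined per-participant coefficient, though that mode exists — and
summarized by the phi coefficient, identical to the Pearson correlation
of the two 0/1 vectors. Conditions are compared by a parametric
bootstrap: each replicate resamples both tables from multinomials at the
observed totals and cell proportions (the minimal parametric model of a
2×2 table) and recomputes the phi difference; the SE is the n−1 SD over
B = 50 replicates by default, with replicates on which phi is undefined
redrawn so B is exact (the redraw count is logged).

Correlation-valued parameters (r_a, G) are compared between conditions
with a paired Student's t on Fisher-z transforms; every parameter also
gets a Wilcoxon matched-pairs signed-ranks test, which is the headline
test for the non-correlation parameters. The Wilcoxon drops zero
differences, midranks ties, enumerates the full sign-assignment
distribution for up to 15 nonzero differences (two-sided p as twice the
smaller tail, capped at 1), and otherwise uses the normal approximation
with tie correction and no continuity correction. Tests are two-sided
throughout, and no multiplicity correction is applied across the seven
parameters. Participants missing a condition are excluded from pairing;
within a parameter, pairs with an undefined value in either condition are
dropped, with counts logged.

The participant sample-size method treats paired correlations on the
Fisher-z scale: SD of within-pair differences = sd·√(2(1−r_pair)),
detectable difference = (z_{1−α/2} + z_{power})·SD_diff/√n,
back-transformed around atanh(mean r). Whether the input SD is on the
correlation scale (converted by the delta method, the default) or already
on the z scale is ambiguous in practice, so both conventions are
implemented behind a flag and both values are reported.

## What the generator emulates — and what it does not

The synthetic ecology draws continuous cues from a correlated
multivariate normal with marginal means/SDs of acute-admission vital
signs (SBP 127/31 mmHg, HR 93/22 bpm, RR 24.2/7.9 breaths/min, Temp
37.08/0.90 °C) and obtains consciousness by thresholding its latent
coordinate at the cumulative cutpoints of the (0.65, 0.25, 0.10) category
frequencies. The default correlation matrix places six cue pairs in the
0.48–0.60 band (four at or above 0.50) with the rest mild, matching the
intercorrelation regime such case series show. The criterion is Bernoulli
with a logistic probability in the standardized cues; the default
coefficients (0.4, 0.5, 1.4, 0.3, 0.8 with zero intercept) make
respiration rate the dominant risk cue. Scenario sets are stratified
exactly: 10 at-risk and 10 not-at-risk cases, with 3 + 2 repeats drawn
uniformly within strata and presentation order randomized.

Simulated judges apply a logistic policy to *perceived* standardized
cues: truth plus Gaussian noise whose per-cue SD (in units of the cue's
generating SD) models the fidelity of the presentation condition
(default 0.1 for written vignettes, 0.8 for the physical simulator).
Judge policies are drawn around the ecology's coefficients (between-judge
SD 0.3, intercept SD 0.2): participants broadly know which vital signs
matter but differ individually. Response consistency is a separate dial:
a temperature divides the linear predictor before the Bernoulli draw
(default 0.5, which puts pooled repeat-phi in the moderately high
0.7–0.85 band typical of trained raters), and a deterministic mode
thresholds at p = 0.5.

Perception-noise scope is the one genuinely open mechanism choice. At the
single-judge level the default redraws noise on every presentation, so a
repeated case can be perceived differently each time. At the study level
the default is stable mis-perception per judge × case × condition:
empirically, per-presentation redraw makes pooled phi fall steeply with
the noise level, entangling the two things the two-condition design is
meant to separate, whereas case-scoped noise degrades achievement and
policy matching while leaving repeat consistency exactly untouched — for
deterministic judges, phi stays at 1 in both arms at any noise level.
Standardization inside policies uses the generating moments, not sample
statistics, so ground-truth weights are well defined for recovery tests.

What passing tests on this generator show is that the *pipeline* is
correct: identities hold, known policies are recovered, consistency and
contrasts behave as constructed. What they cannot show is anything about
real nurses: the generator does not reproduce skewness or kurtosis of
real vital signs, models no learning, fatigue, order or familiarity
effects, no free-text or auditory cues, and its judges are logistic by
construction — real judgement policies need not be.

## Problem sizes and reproducibility

All randomness flows from explicit seeds through per-stage seed splits;
same seed, same config, bit-identical output at every stage. The test
suite validates the fitter against an independent coarse-to-fine
grid-search maximizer of the Bernoulli log-likelihood (20-case instances,
agreement to 1e−4) and against statsmodels GLM; weight recovery uses 50
replicates of 5000-case noise-free judges (within 0.05 L∞ in ≥ 90%); the
fidelity-contrast property uses 20 seeds of 97 deterministic judges with
perception SDs 0.1 vs 2.5; bootstrap calibration compares a 50-replicate
SE against a 10⁵-replicate reference; Wilcoxon calibration uses 1000
null replicates at n = 97. These sizes make the full suite run in well
under a minute while leaving Monte-Carlo margins comfortably wide.

## Known limitations

- The logistic models assume a linear-in-cues log-odds policy; curvilinear
  or configural judgement strategies are mis-captured by design.
- With 25 presentations per fit, per-participant parameters are noisy;
  the pipeline's aggregate contrasts are meaningful, single-participant
  values mostly are not.
- Phi is pooled across participants, so between-participant heterogeneity
  in consistency is invisible at the default scope.
- The stepwise entry-threshold ladder and SE guard are reproducible
  conventions, not estimates; other defensible ladders give different
  included-cue sets for borderline participants.
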