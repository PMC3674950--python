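"""Capture the ecology's policy and one participant's judgement policy.

Fits the logistic ecological model (criterion on the four vital-sign
cues) and a stepwise judgement model for one simulated participant, then
converts the stepwise coefficients into relative cue weights.
"""

from clinlens import fit_logistic, fit_stepwise, relative_weights, simulate_study
from clinlens.synthetic import CONTINUOUS_CUES, CUE_NAMES

study = simulate_study(n_judges=10, seed=1)
idx = [CUE_NAMES.index(c) for c in CONTINUOUS_CUES]
x = study.scenario_set.cue_matrix()[:, idx]
ye = study.scenario_set.criterion()

eco = fit_logistic(x, ye, cue_names=CONTINUOUS_CUES)
print("ecology model (criterion ~ cues):")
for cue in eco.included_cues:
    print(f"  {cue:>5}: B = {eco.coefficients[cue]:+.3f} "
          f"(SE {eco.standard_errors[cue]:.3f})")
print(f"  intercept = {eco.intercept:+.3f}, converged = {eco.converged}")

js = study.by_condition("paper")[0]
step = fit_stepwise(x, js.as_array(), cue_names=CONTINUOUS_CUES)
rw = relative_weights(step)
print(f"\nparticipant {js.participant_id} stepwise model "
      f"(entry threshold {step.entry_threshold_used}):")
print(f"  included cues: {', '.join(step.included_cues) or 'none'}")
print("  relative weights:",
      {c: round(w, 3) for c, w in rw.weights.items()})
print(f"  heaviest cue: {rw.heaviest_cue()}")

# Respiration rate carries the largest ground-truth weight in the default
# ecology, so it should dominate both the ecological model and most
# captured judgement policies.
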