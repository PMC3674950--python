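"""Decompose one participant's judgement accuracy with the lens model equation.

Achievement r_a — the correlation between the participant's judgements
and the true criterion — splits exactly into policy matching (G),
unmodelled knowledge (C1), two cross terms (C2, C3) and four SD ratios
(the logistic analogues of ecological predictability and cognitive
control).
"""

from clinlens import fit_logistic, lens_decomposition, simulate_study
from clinlens.synthetic import CONTINUOUS_CUES, CUE_NAMES

study = simulate_study(n_judges=5, seed=3)
idx = [CUE_NAMES.index(c) for c in CONTINUOUS_CUES]
x = study.scenario_set.cue_matrix()[:, idx]
ye = study.scenario_set.criterion()
eco = fit_logistic(x, ye, cue_names=CONTINUOUS_CUES)

js = study.by_condition("paper")[0]
judge = fit_logistic(x, js.as_array(), cue_names=CONTINUOUS_CUES)
lp = lens_decomposition(eco, judge, ye, js.as_array())

print(f"participant {js.participant_id}, condition {js.condition}:")
print(f"  achievement     r_a = {lp.r_a:+.3f}")
print(f"  policy matching G   = {lp.G:+.3f}")
print(f"  C1, C2, C3          = {lp.C1:+.3f}, {lp.C2:+.3f}, {lp.C3:+.3f}")
print(f"  ecology SD ratios   : pred {lp.sd_ratio_Ye:.3f}, resid {lp.sd_ratio_Ze:.3f}")
print(f"  judge SD ratios     : pred {lp.sd_ratio_Ys:.3f}, resid {lp.sd_ratio_Zs:.3f}")
print(f"  identity residual   = {lp.identity_residual:.1e}")

# The identity residual is the difference between r_a and the four-term
# right-hand side; it is zero to machine precision because judgements and
# criterion each split exactly into model prediction plus raw residual.
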