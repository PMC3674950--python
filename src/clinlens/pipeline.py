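"""End-to-end study drivers: simulate, analyze, report.

``analyze_study`` runs the full double-system analysis on a case pool,
a scenario set and a collection of per-participant judgement sets:

1. ecology model — logistic fit of the criterion on the analysis cue set
   over the presentation series (plus a stepwise fit for ecology weights);
2. per participant x condition — full logistic judgement model for the
   lens decomposition and a stepwise model for relative cue weights
   (the two may differ: a flagged full model still yields the predicted
   probabilities the correlations need, while weights require a model
   whose coefficients are stable);
3. repeat-judgement consistency per condition with a bootstrap comparison;
4. the cross-condition parameter summary with paired tests.

Every excluded participant or parameter is recorded exactly once in the
run log with a reason code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .agreement import (
    ConsistencyComparison,
    RepeatTable,
    bootstrap_phi_difference,
    consistency_phi,
)
from .errors import ConfigurationError, DegenerateDataError
from .inference import SUMMARY_PARAMETERS, ConditionSummary, summarize_conditions
from .lens import LensParameters, RelativeWeights, lens_decomposition, relative_weights
from .policy import (
    DEFAULT_ENTRY_THRESHOLDS,
    DEFAULT_SE_BOUND,
    CueDiagnostics,
    FittedPolicy,
    cue_diagnostics,
    fit_logistic,
    fit_stepwise,
)
from .synthetic import (
    CONTINUOUS_CUES,
    CUE_NAMES,
    CaseRecord,
    EcologyConfig,
    JudgePopulationSpec,
    JudgementSet,
    ScenarioSet,
    StudyData,
    simulate_study,
)


@dataclass(frozen=True)
class AnalysisOptions:
    """Options of the analysis stage.

    The consciousness cue is excluded from both models by default: it is
    the cue most intercorrelated with the others, and dropping it keeps
    the logistic fits on 25 presentations stable enough for a complete
    parameter set.  ``include_consciousness=True`` restores it.
    """

    include_consciousness: bool = False
    se_bound: float = DEFAULT_SE_BOUND
    entry_thresholds: tuple[float, ...] = DEFAULT_ENTRY_THRESHOLDS
    bootstrap_B: int = 50
    alpha: float = 0.05
    seed: int = 0

    @property
    def cue_set(self) -> tuple[str, ...]:
        return CUE_NAMES if self.include_consciousness else CONTINUOUS_CUES


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a simulated study run."""

    seed: int = 0
    ecology: EcologyConfig = field(default_factory=EcologyConfig)
    judges: JudgePopulationSpec = field(default_factory=JudgePopulationSpec)
    n_judges: int = 97
    condition_noise: Mapping[str, float] = field(
        default_factory=lambda: {"paper": 0.1, "physical": 0.8}
    )
    noise_scope: str = "case"
    scenario: Mapping[str, int] = field(
        default_factory=lambda: {
            "n_risk": 10,
            "n_norisk": 10,
            "repeats_risk": 3,
            "repeats_norisk": 2,
        }
    )
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)


def load_study_config(path) -> StudyConfig:
    """Read a study configuration from a YAML file (all keys optional)."""
    raw = io.load_yaml(path)
    eco_kwargs = dict(raw.get("ecology", {}))
    if "cue_corr" in eco_kwargs:
        eco_kwargs["cue_corr"] = np.asarray(eco_kwargs["cue_corr"], dtype=float)
    if "consciousness_probs" in eco_kwargs:
        eco_kwargs["consciousness_probs"] = tuple(eco_kwargs["consciousness_probs"])
    judge_kwargs = dict(raw.get("judges", {}))
    n_judges = int(judge_kwargs.pop("n_judges", 97))
    analysis_kwargs = dict(raw.get("analysis", {}))
    if "entry_thresholds" in analysis_kwargs:
        analysis_kwargs["entry_thresholds"] = tuple(analysis_kwargs["entry_thresholds"])
    return StudyConfig(
        seed=int(raw.get("seed", 0)),
        ecology=EcologyConfig(**eco_kwargs),
        judges=JudgePopulationSpec(**judge_kwargs),
        n_judges=n_judges,
        condition_noise=dict(raw.get("condition_noise", {"paper": 0.1, "physical": 0.8})),
        noise_scope=str(raw.get("noise_scope", "case")),
        scenario=dict(raw.get("scenario", StudyConfig().scenario)),
        analysis=AnalysisOptions(**analysis_kwargs),
    )


def run_simulation(config: StudyConfig) -> StudyData:
    """Simulate the study described by ``config``."""
    return simulate_study(
        ecology_config=config.ecology,
        judge_population_spec=config.judges,
        n_judges=config.n_judges,
        condition_noise=config.condition_noise,
        seed=config.seed,
        noise_scope=config.noise_scope,  # type: ignore[arg-type]
        scenario_kwargs=config.scenario,
    )


def write_simulation(study: StudyData, outdir, config: StudyConfig | None = None) -> None:
    """Write cases/presentations/judgements CSVs plus a run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_cases_csv(study.scenario_set.unique_cases, out / "cases.csv")
    io.write_presentations_csv(study.scenario_set, out / "presentations.csv")
    io.write_judgements_csv(study.judgements, out / "judgements.csv")
    manifest: dict[str, object] = {"n_judges": len(study.policies)}
    if config is not None:
        blob = json.dumps(io._jsonable(config), sort_keys=True)
        manifest["seed"] = config.seed
        manifest["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    io.write_json(manifest, out / "manifest.json")


@dataclass(frozen=True)
class AnalysisResult:
    """All artifacts of one analysis run."""

    cue_set: tuple[str, ...]
    ecology_model: FittedPolicy
    ecology_stepwise: FittedPolicy
    ecology_weights: RelativeWeights
    diagnostics: CueDiagnostics
    lens_records: pd.DataFrame
    weight_records: pd.DataFrame
    consistency: Mapping[str, tuple[float, RepeatTable]]
    comparison: ConsistencyComparison | None
    summary: ConditionSummary
    run_log: tuple[dict, ...]
    heaviest_counts: Mapping[str, Mapping[str, int]]


def _condition_order(judgement_sets: Sequence[JudgementSet]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for js in judgement_sets:
        seen.setdefault(js.condition, None)
    return tuple(seen)


def analyze_study(
    cases: Sequence[CaseRecord],
    scenario_set: ScenarioSet,
    judgement_sets: Sequence[JudgementSet],
    options: AnalysisOptions | None = None,
) -> AnalysisResult:
    """Run the full double-system analysis.

    ``cases`` is the case pool backing ``scenario_set``; both models are
    fitted over the presentation series (repeats included), so the
    ecology and every judgement model cover the same cases in the same
    order.
    """
    opts = options or AnalysisOptions()
    cue_set = opts.cue_set
    cue_idx = [CUE_NAMES.index(c) for c in cue_set]
    x = scenario_set.cue_matrix()[:, cue_idx]
    ye = scenario_set.criterion()
    if ye.min() == ye.max():
        raise DegenerateDataError("scenario criterion is constant")
    run_log: list[dict] = []

    diagnostics = cue_diagnostics(scenario_set.cue_matrix(), cue_names=CUE_NAMES)
    eco_full = fit_logistic(x, ye, cue_names=cue_set, se_bound=opts.se_bound)
    if not eco_full.converged:
        run_log.append(
            {"stage": "ecology", "reason": "separation_or_guard", "detail": "full model flagged"}
        )
    eco_step = fit_stepwise(
        x, ye, cue_names=cue_set,
        entry_thresholds=opts.entry_thresholds, se_bound=opts.se_bound,
    )
    eco_weights = relative_weights(eco_step)

    conditions = _condition_order(judgement_sets)
    by_key = {(js.participant_id, js.condition): js for js in judgement_sets}
    participants = sorted({js.participant_id for js in judgement_sets})

    lens_rows: list[dict] = []
    weight_rows: list[dict] = []
    for pid in participants:
        present = [c for c in conditions if (pid, c) in by_key]
        if len(present) < len(conditions):
            run_log.append(
                {"stage": "pairing", "participant_id": pid, "reason": "missing_condition",
                 "detail": f"present only in {present}"}
            )
            continue
        for condition in conditions:
            ys = by_key[(pid, condition)].as_array()
            if ys.min() == ys.max():
                run_log.append(
                    {"stage": "fit", "participant_id": pid, "condition": condition,
                     "reason": "constant_judgements",
                     "detail": "all-" + ("yes" if ys[0] else "no")}
                )
                continue
            judge_full = fit_logistic(x, ys, cue_names=cue_set, se_bound=opts.se_bound)
            try:
                lens = lens_decomposition(eco_full, judge_full, ye, ys)
            except DegenerateDataError as exc:
                run_log.append(
                    {"stage": "lens", "participant_id": pid, "condition": condition,
                     "reason": "degenerate_variance", "detail": str(exc)}
                )
                lens = None
            if lens is not None:
                lens_rows.append(
                    {
                        "participant_id": pid,
                        "condition": condition,
                        **{p: getattr(lens, p) for p in SUMMARY_PARAMETERS},
                        "sd_ratio_Ye": lens.sd_ratio_Ye,
                        "sd_ratio_Ze": lens.sd_ratio_Ze,
                        "identity_residual": lens.identity_residual,
                        "lens_model": "full_logistic",
                        "model_converged": judge_full.converged,
                    }
                )
            judge_step = fit_stepwise(
                x, ys, cue_names=cue_set,
                entry_thresholds=opts.entry_thresholds, se_bound=opts.se_bound,
            )
            rw = relative_weights(judge_step)
            weight_rows.append(
                {
                    "participant_id": pid,
                    "condition": condition,
                    "weights_model": "stepwise_logistic",
                    "entry_threshold_used": judge_step.entry_threshold_used,
                    "included_cues": ",".join(judge_step.included_cues),
                    "heaviest_cue": rw.heaviest_cue() or "",
                    **{f"rw_{c}": rw.weights[c] for c in cue_set},
                }
            )

    lens_records = pd.DataFrame(lens_rows)
    weight_records = pd.DataFrame(weight_rows)

    consistency: dict[str, tuple[float, RepeatTable]] = {}
    for condition in conditions:
        sets = [js for js in judgement_sets if js.condition == condition]
        consistency[condition] = consistency_phi(sets, scenario_set, scope="pooled")

    comparison = None
    if len(conditions) == 2:
        comparison = bootstrap_phi_difference(
            consistency[conditions[0]][1],
            consistency[conditions[1]][1],
            B=opts.bootstrap_B,
            seed=opts.seed,
        )

    if lens_records.empty:
        raise DegenerateDataError("no participant produced a usable lens decomposition")
    summary = summarize_conditions(lens_records, conditions=conditions)

    heaviest_counts: dict[str, dict[str, int]] = {}
    for condition in conditions:
        sub = weight_records[weight_records["condition"] == condition]
        counts = sub["heaviest_cue"].value_counts().to_dict()
        heaviest_counts[condition] = {c: int(counts.get(c, 0)) for c in cue_set}

    return AnalysisResult(
        cue_set=cue_set,
        ecology_model=eco_full,
        ecology_stepwise=eco_step,
        ecology_weights=eco_weights,
        diagnostics=diagnostics,
        lens_records=lens_records,
        weight_records=weight_records,
        consistency=consistency,
        comparison=comparison,
        summary=summary,
        run_log=tuple(run_log),
        heaviest_counts=heaviest_counts,
    )


def write_analysis(result: AnalysisResult, outdir) -> None:
    """Write one CSV/JSON artifact per analysis stage plus the run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.lens_records.to_csv(out / "lens_records.csv", index=False)
    result.weight_records.to_csv(out / "weights.csv", index=False)
    result.summary.table.to_csv(out / "summary.csv")
    io.write_json(
        {
            "cue_set": result.cue_set,
            "ecology": {
                "included_cues": result.ecology_model.included_cues,
                "coefficients": dict(result.ecology_model.coefficients),
                "intercept": result.ecology_model.intercept,
                "standard_errors": dict(result.ecology_model.standard_errors),
                "converged": result.ecology_model.converged,
            },
            "ecology_stepwise_included": result.ecology_stepwise.included_cues,
            "ecology_relative_weights": dict(result.ecology_weights.weights),
            "tolerance": dict(result.diagnostics.tolerance),
        },
        out / "ecology.json",
    )
    io.write_json(
        {
            "phi": {c: phi for c, (phi, _t) in result.consistency.items()},
            "tables": {
                c: {"a": t.a, "b": t.b, "c": t.c, "d": t.d, "total": t.total}
                for c, (_p, t) in result.consistency.items()
            },
            "comparison": result.comparison,
        },
        out / "consistency.json",
    )
    io.write_json(
        {
            "tests": {
                p: {k: (v if isinstance(v, str) else io._jsonable(v)) for k, v in entry.items()}
                for p, entry in result.summary.tests.items()
            },
            "n_participants": result.summary.n_participants,
            "exclusions": dict(result.summary.exclusions),
            "heaviest_counts": result.heaviest_counts,
        },
        out / "inference.json",
    )
    with open(out / "run_log.txt", "w") as fh:
        if not result.run_log:
            fh.write("no exclusions or fallbacks\n")
        for entry in result.run_log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def render_report(analysis_dir) -> str:
    """Render a human-readable report from a written analysis directory."""
    out = Path(analysis_dir)
    required = ["summary.csv", "consistency.json", "inference.json", "ecology.json"]
    for name in required:
        if not (out / name).exists():
            raise ConfigurationError(f"analysis artifact missing: {out / name}")
    summary = pd.read_csv(out / "summary.csv", index_col=0)
    consistency = json.loads((out / "consistency.json").read_text())
    inference = json.loads((out / "inference.json").read_text())
    ecology = json.loads((out / "ecology.json").read_text())

    lines = ["# Judgement analysis report", ""]
    lines.append(f"Participants in both conditions: {inference['n_participants']}")
    lines.append("")
    lines.append("## Lens model parameters by condition")
    lines.append("")
    lines.append(summary.round(3).to_string())
    lines.append("")
    lines.append("## Ecology model")
    rw = ecology["ecology_relative_weights"]
    if rw:
        top = max(rw, key=lambda c: abs(rw[c]))
        lines.append(
            f"Heaviest ecology cue: {top} (relative weight {rw[top]:.3f}); "
            f"included cues: {', '.join(ecology['ecology_stepwise_included']) or 'none'}"
        )
    lines.append("")
    lines.append("## Heaviest cue per participant model")
    for condition, counts in inference["heaviest_counts"].items():
        ordered = sorted(counts.items(), key=lambda kv: -kv[1])
        top_line = ", ".join(f"{c}: {n}" for c, n in ordered)
        lines.append(f"- {condition}: {top_line}")
        if "rr" in counts:
            lines.append(
                f"  (respiration rate heaviest for {counts['rr']} participants)"
            )
    lines.append("")
    lines.append("## Repeat-judgement consistency")
    for condition, phi in consistency["phi"].items():
        total = consistency["tables"][condition]["total"]
        lines.append(f"- {condition}: phi = {phi:.3f} over {total} repeat pairs")
    comp = consistency.get("comparison")
    if comp:
        lines.append(
            f"- difference {comp['difference']:.3f}, bootstrap SE {comp['bootstrap_se']:.3f} "
            f"(B = {comp['n_replications']}), z = {comp['z']:.2f}, p = {comp['p_value']:.3f}"
        )
    lines.append("")
    return "\n".join(lines)
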