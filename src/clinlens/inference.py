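"""Cross-condition inference on per-participant lens parameters.

Correlation-valued parameters (achievement r_a, policy matching G) are
compared between conditions with a paired Student's t test on their
Fisher-z transforms; every parameter is additionally compared with the
Wilcoxon matched-pairs signed-ranks test (exact sign-assignment
distribution for small samples, normal approximation with midranks and
tie correction otherwise).  The module also implements the paired
detectable-difference calculation used to size the participant sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError

#: The seven per-participant parameters summarized per condition.
SUMMARY_PARAMETERS: tuple[str, ...] = (
    "r_a",
    "G",
    "C1",
    "C2",
    "C3",
    "sd_ratio_Ys",
    "sd_ratio_Zs",
)
#: Parameters that are correlations, compared on the Fisher-z scale.
CORRELATION_PARAMETERS: tuple[str, ...] = ("r_a", "G")

_CLAMP = 1.0 - 1e-6


def fisher_z(r, on_boundary: str = "clamp"):
    """Fisher's variance-stabilizing transform z = atanh(r).

    Values with |r| >= 1 are clamped to +/-(1 - 1e-6) with a warning, or
    rejected when ``on_boundary='error'``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        if on_boundary == "error":
            raise ConfigurationError("|r| >= 1 cannot be Fisher-z transformed")
        warnings.warn("correlation at +/-1 clamped before Fisher-z", stacklevel=2)
        r = np.clip(r, -_CLAMP, _CLAMP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_value: float
    mean_difference: float
    degenerate: bool = False


def paired_t_on_z(r_condition_a, r_condition_b) -> PairedTResult:
    """Paired Student's t on Fisher-z transformed correlations.

    The two vectors must be participant-aligned.  Zero variance of the
    differences is handled as a limit: identical vectors give t = 0 and
    p = 1; an exact nonzero shift gives p = 0 with the ``degenerate``
    flag set.
    """
    za = np.atleast_1d(fisher_z(r_condition_a))
    zb = np.atleast_1d(fisher_z(r_condition_b))
    if za.shape != zb.shape:
        raise ConfigurationError("paired correlation vectors have different lengths")
    n = len(za)
    if n < 2:
        raise ConfigurationError("need at least 2 pairs")
    d = za - zb
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    # an exact shift leaves only rounding noise in the differences
    if sd <= 1e-12 * max(1.0, abs(md)):
        if md == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p_value=1.0, mean_difference=0.0, degenerate=True)
        return PairedTResult(
            t=float(np.inf) * np.sign(md), df=n - 1, p_value=0.0, mean_difference=md, degenerate=True
        )
    t = md / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PairedTResult(t=float(t), df=n - 1, p_value=p, mean_difference=md)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_nonzero: int
    method: str  # "exact" or "approx"
    z: float | None = None


#: Largest number of nonzero differences for which the exact
#: sign-assignment distribution is enumerated.
WILCOXON_EXACT_LIMIT = 15


def wilcoxon_signed_rank(a, b, exact_limit: int = WILCOXON_EXACT_LIMIT) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-ranks test (two-sided).

    Zero differences are dropped; absolute differences are ranked with
    midranks for ties.  With at most ``exact_limit`` nonzero differences
    the p-value comes from full enumeration of the 2^n equally likely
    sign assignments (two-sided as twice the smaller tail, capped at 1);
    otherwise from the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired vectors have different lengths")
    if len(a) < 2:
        raise ConfigurationError("need at least 2 pairs")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero; no information")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_limit:
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_dist = masks @ ranks
        p_low = float(np.mean(w_dist <= w_plus + 1e-12))
        p_high = float(np.mean(w_dist >= w_plus - 1e-12))
        p = min(1.0, 2.0 * min(p_low, p_high))
        return WilcoxonResult(statistic=w_plus, p_value=p, n_nonzero=n, method="exact")

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_plus - mu) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return WilcoxonResult(statistic=w_plus, p_value=p, n_nonzero=n, method="approx", z=float(z))


@dataclass(frozen=True)
class DetectableDifference:
    """Result of the paired detectable-difference calculation."""

    difference_r: float  # on the correlation scale, around mean_r
    difference_z: float  # on the Fisher-z scale
    multiplier: float  # z_{1-alpha/2} + z_{power}
    sd_scale: str


def detectable_difference(
    sd_r: float,
    mean_r: float,
    r_pair: float,
    n: int,
    alpha: float = 0.05,
    power: float = 0.90,
    sd_scale: str = "r",
) -> DetectableDifference:
    """Detectable mean difference in paired correlations (Bland's method).

    The SD of within-pair differences is sd * sqrt(2*(1 - r_pair)) and the
    detectable difference is (z_{1-alpha/2} + z_{power}) * SD_diff / sqrt(n),
    computed on the Fisher-z scale and back-transformed around
    atanh(mean_r).  ``sd_scale`` declares whether ``sd_r`` is the SD of
    the correlations themselves (``'r'``, converted by the delta method)
    or already on the Fisher-z scale (``'z'``).
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ConfigurationError("alpha and power must lie in (0, 1)")
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    if not -1 < r_pair <= 1:
        raise ConfigurationError("r_pair must lie in (-1, 1]")
    if sd_r < 0:
        raise ConfigurationError("sd_r must be >= 0")
    if sd_scale not in ("r", "z"):
        raise ConfigurationError("sd_scale must be 'r' or 'z'")

    z_mean = fisher_z(mean_r)
    sd_z = sd_r if sd_scale == "z" else sd_r / (1.0 - mean_r**2)
    sd_diff = sd_z * np.sqrt(2.0 * (1.0 - r_pair))
    multiplier = float(stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power))
    delta_z = multiplier * sd_diff / np.sqrt(n)
    delta_r = float(inverse_fisher_z(z_mean + delta_z) - inverse_fisher_z(z_mean))
    return DetectableDifference(
        difference_r=delta_r,
        difference_z=float(delta_z),
        multiplier=multiplier,
        sd_scale=sd_scale,
    )


@dataclass(frozen=True)
class ConditionSummary:
    """Per-parameter condition summary with paired tests."""

    conditions: tuple[str, str]
    n_participants: int
    table: pd.DataFrame  # rows: parameters; columns: mean/sd/median per condition
    tests: Mapping[str, Mapping[str, object]]
    exclusions: Mapping[str, int] = field(default_factory=dict)
    subgroup_means: pd.DataFrame | None = None


def summarize_conditions(
    lens_records: pd.DataFrame,
    conditions: Sequence[str] | None = None,
    subgroups: Mapping[int, str] | None = None,
) -> ConditionSummary:
    """Summarize per-participant lens parameters across two conditions.

    ``lens_records`` needs columns ``participant_id``, ``condition`` and
    the seven parameters in :data:`SUMMARY_PARAMETERS`.  Only participants
    present in both conditions contribute; within each parameter, pairs
    with a missing value in either condition are dropped (counts are
    recorded in ``exclusions``).  r_a and G are additionally compared with
    the paired t on Fisher-z; every parameter gets a Wilcoxon test, with
    an all-zero-difference parameter reported as ``'no difference'``.
    """
    df = pd.DataFrame(lens_records)
    required = {"participant_id", "condition", *SUMMARY_PARAMETERS}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"lens records missing columns: {sorted(missing)}")
    conds = tuple(conditions) if conditions is not None else tuple(
        pd.unique(df["condition"])
    )
    if len(conds) != 2:
        raise ConfigurationError("exactly two conditions are required")

    in_both = None
    for cond in conds:
        ids = set(df.loc[df["condition"] == cond, "participant_id"])
        in_both = ids if in_both is None else in_both & ids
    if not in_both:
        raise DegenerateDataError("no participant appears in both conditions")
    df = df[df["participant_id"].isin(in_both)]

    rows = []
    tests: dict[str, dict[str, object]] = {}
    exclusions: dict[str, int] = {}
    for param in SUMMARY_PARAMETERS:
        wide = df.pivot_table(
            index="participant_id", columns="condition", values=param, aggfunc="first"
        )[list(conds)]
        paired = wide.dropna()
        exclusions[param] = len(wide) - len(paired)
        row: dict[str, object] = {"parameter": param}
        for cond in conds:
            v = paired[cond].to_numpy()
            row[f"{cond}_mean"] = float(np.mean(v))
            row[f"{cond}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            row[f"{cond}_median"] = float(np.median(v))
        rows.append(row)

        entry: dict[str, object] = {}
        try:
            entry["wilcoxon"] = wilcoxon_signed_rank(
                paired[conds[0]].to_numpy(), paired[conds[1]].to_numpy()
            )
        except DegenerateDataError:
            entry["wilcoxon"] = "no difference"
        if param in CORRELATION_PARAMETERS:
            entry["paired_t_z"] = paired_t_on_z(
                paired[conds[0]].to_numpy(), paired[conds[1]].to_numpy()
            )
        tests[param] = entry

    subgroup_means = None
    if subgroups is not None:
        sub = df.copy()
        sub["subgroup"] = sub["participant_id"].map(dict(subgroups))
        subgroup_means = (
            sub.dropna(subset=["subgroup"])
            .groupby(["subgroup", "condition"])[list(SUMMARY_PARAMETERS)]
            .mean()
        )

    return ConditionSummary(
        conditions=conds,  # type: ignore[arg-type]
        n_participants=len(in_both),
        table=pd.DataFrame(rows).set_index("parameter"),
        tests=tests,
        exclusions=exclusions,
        subgroup_means=subgroup_means,
    )
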