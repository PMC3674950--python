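"""Lens model equation decomposition and relative cue weights.

The double-system design captures two logistic models over the same
cases: an ecological model predicting the true criterion Ye and a
judgement model predicting a participant's judgements Ys.  Writing each
dichotomous vector as model prediction plus raw residual,
``Y = Y~ + Z~``, the achievement correlation r_a = corr(Ye, Ys)
decomposes *exactly* into four terms:

    r_a = G * (sYe~/sYe)(sYs~/sYs) + C1 * (sZe~/sYe)(sZs~/sYs)
        + C2 * (sYe~/sYe)(sZs~/sYs) + C3 * (sZe~/sYe)(sYs~/sYs)

where G = corr(Ye~, Ys~) is policy matching (modelled knowledge),
C1 = corr(Ze~, Zs~) is unmodelled knowledge, C2 = corr(Ye~, Zs~) and
C3 = corr(Ze~, Ys~) are the cross terms, and the s-ratios are the
logistic analogues of ecological predictability (Re) and cognitive
control (Rs).  The identity holds by bilinearity of covariance for any
prediction/residual split with a consistent SD convention; the residual
of the identity is computed for every decomposition and required to be
below 1e-10.

In the classical linear mode both models are ordinary least squares on a
shared cue set, residuals are orthogonal to both prediction vectors, so
C2 = C3 = 0 and the equation collapses to the familiar two-term form
r_a = G*Re*Rs + C1*sqrt(1-Re^2)*sqrt(1-Rs^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ClinlensError, ConfigurationError, DegenerateDataError
from .policy import FittedPolicy, _as_matrix

IDENTITY_TOL = 1e-10


@dataclass(frozen=True)
class LensParameters:
    """The lens model equation decomposition for one system pair."""

    r_a: float
    G: float
    C1: float
    C2: float
    C3: float
    sd_ratio_Ye: float  # s(Ye~)/s(Ye)
    sd_ratio_Ze: float  # s(Ze~)/s(Ye)
    sd_ratio_Ys: float  # s(Ys~)/s(Ys)
    sd_ratio_Zs: float  # s(Zs~)/s(Ys)
    identity_residual: float
    n_cases: int
    mode: str = "logistic"
    Re: float | None = None  # linear mode only
    Rs: float | None = None

    def __post_init__(self) -> None:
        if abs(self.identity_residual) > IDENTITY_TOL:
            raise ClinlensError(
                f"lens identity violated: residual {self.identity_residual:.3e}"
            )

    @property
    def rhs(self) -> float:
        """The four-term right-hand side of the decomposition."""
        return (
            self.G * self.sd_ratio_Ye * self.sd_ratio_Ys
            + self.C1 * self.sd_ratio_Ze * self.sd_ratio_Zs
            + self.C2 * self.sd_ratio_Ye * self.sd_ratio_Zs
            + self.C3 * self.sd_ratio_Ze * self.sd_ratio_Ys
        )


@dataclass(frozen=True)
class RelativeWeights:
    """Signed, normalized standardized coefficients of a policy model.

    beta_i = B_i * SD_Xi (the outcome-SD factor cancels in normalization);
    RW_i = sign(beta_i) * |beta_i| / sum_j |beta_j|.  Cues excluded by the
    stepwise procedure carry exactly zero weight, and |RW| sums to one
    whenever any coefficient is nonzero.
    """

    cue_names: tuple[str, ...]
    weights: Mapping[str, float]  # RW per cue (0 for excluded)
    beta: Mapping[str, float]  # standardized coefficients (0 for excluded)
    excluded_cues: tuple[str, ...]
    all_zero: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[c] for c in self.cue_names])

    def heaviest_cue(self) -> str | None:
        """Cue with the largest absolute relative weight (None if all zero)."""
        if self.all_zero:
            return None
        return max(self.cue_names, key=lambda c: abs(self.weights[c]))


def _sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; zero-variance residual vectors correlate as 0
    (their covariance with anything is exactly zero)."""
    sa, sb = _sd(a), _sd(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    am = a - a.mean()
    bm = b - b.mean()
    return float((am @ bm) / ((len(a) - 1) * sa * sb))


def _check_vector(name: str, v: np.ndarray, n: int) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if len(v) != n:
        raise ConfigurationError(f"{name} has length {len(v)}, expected {n}")
    if _sd(v) == 0.0:
        raise DegenerateDataError(f"{name} is constant; decomposition undefined")
    return v


def _decompose(
    ye: np.ndarray,
    ys: np.ndarray,
    pred_e: np.ndarray,
    pred_s: np.ndarray,
    mode: str,
    Re: float | None = None,
    Rs: float | None = None,
) -> LensParameters:
    n = len(ye)
    ye = _check_vector("criterion (Ye)", ye, n)
    ys = _check_vector("judgements (Ys)", ys, n)
    pred_e = _check_vector("ecology fitted_probs", pred_e, n)
    pred_s = _check_vector("judge fitted_probs", pred_s, n)
    res_e = ye - pred_e
    res_s = ys - pred_s

    s_ye, s_ys = _sd(ye), _sd(ys)
    params = dict(
        r_a=_corr(ye, ys),
        G=_corr(pred_e, pred_s),
        C1=_corr(res_e, res_s),
        C2=_corr(pred_e, res_s),
        C3=_corr(res_e, pred_s),
        sd_ratio_Ye=_sd(pred_e) / s_ye,
        sd_ratio_Ze=_sd(res_e) / s_ye,
        sd_ratio_Ys=_sd(pred_s) / s_ys,
        sd_ratio_Zs=_sd(res_s) / s_ys,
    )
    rhs = (
        params["G"] * params["sd_ratio_Ye"] * params["sd_ratio_Ys"]
        + params["C1"] * params["sd_ratio_Ze"] * params["sd_ratio_Zs"]
        + params["C2"] * params["sd_ratio_Ye"] * params["sd_ratio_Zs"]
        + params["C3"] * params["sd_ratio_Ze"] * params["sd_ratio_Ys"]
    )
    return LensParameters(
        **params,
        identity_residual=params["r_a"] - rhs,
        n_cases=n,
        mode=mode,
        Re=Re,
        Rs=Rs,
    )


def lens_decomposition(
    eco: FittedPolicy,
    judge: FittedPolicy,
    criterion,
    judgements,
) -> LensParameters:
    """Logistic lens model equation decomposition for one participant.

    ``eco`` and ``judge`` must be fitted on the same cases in the same
    order; ``criterion`` and ``judgements`` are the corresponding 0/1
    vectors.  All correlations and SD ratios use the n-1 SD convention;
    the four-term identity is asserted to 1e-10.
    """
    ye = np.asarray(criterion, dtype=float)
    ys = np.asarray(judgements, dtype=float)
    if len(eco.fitted_probs) != len(judge.fitted_probs):
        raise ConfigurationError("ecology and judge models cover different case counts")
    return _decompose(ye, ys, eco.fitted_probs, judge.fitted_probs, mode="logistic")


def linear_lens_decomposition(
    cues,
    criterion,
    judgements,
    cue_names: Sequence[str] | None = None,
) -> LensParameters:
    """Classical linear lens model equation on a shared cue set.

    Both systems are ordinary least-squares regressions with intercept on
    the same cues, so the cross terms C2 and C3 vanish and
    r_a = G*Re*Rs + C1*sqrt(1-Re^2)*sqrt(1-Rs^2).
    """
    x, _ = _as_matrix(cues, cue_names)
    ye = np.asarray(criterion, dtype=float)
    ys = np.asarray(judgements, dtype=float)
    if len(ye) != x.shape[0] or len(ys) != x.shape[0]:
        raise ConfigurationError("cues, criterion and judgements have different lengths")
    design = np.hstack([np.ones((x.shape[0], 1)), x])
    pred_e = design @ np.linalg.lstsq(design, ye, rcond=None)[0]
    pred_s = design @ np.linalg.lstsq(design, ys, rcond=None)[0]
    return _decompose(
        ye,
        ys,
        pred_e,
        pred_s,
        mode="linear",
        Re=_corr(ye, pred_e),
        Rs=_corr(ys, pred_s),
    )


def relative_weights(
    policy: FittedPolicy,
    cue_sds: Mapping[str, float] | None = None,
) -> RelativeWeights:
    """Relative cue weights of a fitted policy.

    Standardizes each coefficient by its cue's sample SD and normalizes by
    the sum of absolute standardized coefficients, restoring each weight's
    sign.  Cues not included by the fit get weight exactly 0; if every
    coefficient is zero (intercept-only model) all weights are 0 and the
    ``all_zero`` flag is set.
    """
    sds = dict(cue_sds) if cue_sds is not None else dict(policy.cue_sds or {})
    for cue in policy.candidate_cues:
        if cue not in sds:
            raise ConfigurationError(f"no SD supplied for cue {cue!r}")
        if sds[cue] <= 0:
            raise ConfigurationError(f"cue {cue!r} has non-positive SD")

    beta = {
        c: (float(policy.coefficients[c] * sds[c]) if c in policy.included_cues else 0.0)
        for c in policy.candidate_cues
    }
    denom = sum(abs(b) for b in beta.values())
    if denom == 0.0:
        weights = {c: 0.0 for c in policy.candidate_cues}
        all_zero = True
    else:
        weights = {c: float(b / denom) for c, b in beta.items()}
        all_zero = False
    return RelativeWeights(
        cue_names=policy.candidate_cues,
        weights=weights,
        beta=beta,
        excluded_cues=tuple(
            c for c in policy.candidate_cues if c not in policy.included_cues
        ),
        all_zero=all_zero,
    )
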