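"""Logistic policy capturing.

Fits the two models of the double-system design — the ecological model
(criterion on cues) and each participant's judgement model (judgements on
the same cues) — by maximum-likelihood logistic regression, plus the
forward-stepwise variant with a standard-error guard used for relative
cue weights, and multicollinearity diagnostics for the cue set.

The fitter is a Newton/IRLS scheme with step halving, which makes the
log-likelihood provably non-decreasing across iterations; that invariant
is asserted on every fit.  Quasi-complete separation — a real hazard with
25 dichotomous observations and intercorrelated cues — is detected from
implausibly large standardized coefficients or standard errors, flagged,
and left for the caller to decide: a flagged model's predicted
probabilities remain usable for correlation-based lens statistics even
when its coefficients are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .errors import ConfigurationError, DegenerateDataError

#: Guard defaults, on standardized-cue coefficients.  Both sit far outside
#: plausible effect sizes for standardized physiological cues.
DEFAULT_SE_BOUND = 5.0
DEFAULT_SEPARATION_BOUND = 15.0
DEFAULT_ENTRY_THRESHOLDS: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)

_PROB_EPS = 1e-10


@dataclass(frozen=True)
class FittedPolicy:
    """A fitted logistic policy model.

    Coefficients are on the raw cue scale (log-odds units); ``residuals``
    are raw residuals Y - p-hat, the quantity the lens decomposition
    correlates across the two systems.  ``candidate_cues`` is the full cue
    set offered to the fitter; cues absent from ``included_cues`` carry
    zero weight downstream.
    """

    candidate_cues: tuple[str, ...]
    included_cues: tuple[str, ...]
    coefficients: Mapping[str, float]  # per included cue
    intercept: float
    standard_errors: Mapping[str, float]  # per included cue + "intercept"
    fitted_probs: np.ndarray
    residuals: np.ndarray
    converged: bool
    separation: bool
    log_likelihood: float
    n_iter: int
    entry_threshold_used: float | None = None
    cue_sds: Mapping[str, float] | None = None  # sample SDs (ddof=1) of candidates

    def coefficient_vector(self) -> np.ndarray:
        """Coefficients over ``candidate_cues`` with zeros for excluded cues."""
        return np.array([self.coefficients.get(c, 0.0) for c in self.candidate_cues])


@dataclass(frozen=True)
class CueDiagnostics:
    """Cue intercorrelations and tolerance (1 - R2 of each cue on the rest)."""

    cue_names: tuple[str, ...]
    intercorrelation: np.ndarray
    tolerance: Mapping[str, float]


def _as_matrix(cues, cue_names: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(cues, pd.DataFrame):
        names = tuple(cues.columns) if cue_names is None else tuple(cue_names)
        x = cues.loc[:, list(names)].to_numpy(dtype=float)
    else:
        x = np.asarray(cues, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = tuple(cue_names) if cue_names is not None else tuple(
            f"cue{i}" for i in range(x.shape[1])
        )
    if x.shape[1] != len(names):
        raise ConfigurationError("cue_names length does not match cue matrix width")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("cue matrix contains non-finite values")
    return x, names


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _PROB_EPS, 1 - _PROB_EPS)
    return float(y @ np.log(p) + (1 - y) @ np.log1p(-p))


def _irls(x: np.ndarray, y: np.ndarray, tol: float, max_iter: int):
    """Newton/IRLS for logistic regression with step halving.

    ``x`` already carries the intercept column.  Returns coefficients,
    standard errors (inverse observed information), final log-likelihood,
    iteration count and a convergence flag.  The log-likelihood is checked
    to be non-decreasing at every accepted step.
    """
    n, p_dim = x.shape
    beta = np.zeros(p_dim)
    ll = _log_likelihood(y, expit(x @ beta))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = np.clip(expit(x @ beta), _PROB_EPS, 1 - _PROB_EPS)
        w = p * (1 - p)
        score = x.T @ (y - p)
        info = (x * w[:, None]).T @ x
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, score, rcond=None)[0]
        # Step halving keeps the likelihood monotone even far from optimum.
        step = 1.0
        for _ in range(40):
            candidate = beta + step * delta
            ll_new = _log_likelihood(y, expit(x @ candidate))
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        if ll_new < ll - 1e-9:  # pragma: no cover - monotonicity invariant
            raise RuntimeError("log-likelihood decreased during IRLS")
        change = np.max(np.abs(candidate - beta))
        beta, ll = candidate, ll_new
        if change < tol:
            converged = True
            break
    p = np.clip(expit(x @ beta), _PROB_EPS, 1 - _PROB_EPS)
    w = p * (1 - p)
    info = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p_dim, np.inf)
    return beta, se, ll, it, converged


def fit_logistic(
    cues,
    outcome,
    cue_names: Sequence[str] | None = None,
    se_bound: float = DEFAULT_SE_BOUND,
    separation_bound: float = DEFAULT_SEPARATION_BOUND,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FittedPolicy:
    """Maximum-likelihood logistic regression of a dichotomous outcome on cues.

    Parameters
    ----------
    cues
        Case-by-cue matrix (``pandas.DataFrame`` or array); an empty cue
        set fits the intercept-only model.
    outcome
        0/1 vector.
    se_bound, separation_bound
        Guards on standardized-cue coefficients and their standard errors;
        exceeding either flags the fit as separated and non-converged.

    Raises
    ------
    DegenerateDataError
        If the outcome is constant.
    ConfigurationError
        If any cue column is constant.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ConfigurationError("outcome must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("outcome is constant; logistic model is degenerate")

    if cues is None or (hasattr(cues, "shape") and np.size(cues) == 0) or (
        isinstance(cues, pd.DataFrame) and cues.shape[1] == 0
    ):
        x_raw = np.empty((len(y), 0))
        names: tuple[str, ...] = ()
    else:
        x_raw, names = _as_matrix(cues, cue_names)
    if x_raw.shape[0] != len(y):
        raise ConfigurationError("cues and outcome have different lengths")

    sds = x_raw.std(axis=0, ddof=1) if x_raw.shape[1] else np.array([])
    for name, sd in zip(names, sds):
        if sd == 0:
            raise ConfigurationError(f"cue {name!r} is constant")

    design = np.hstack([np.ones((len(y), 1)), x_raw])
    beta, se, ll, n_iter, converged = _irls(design, y, tol=tol, max_iter=max_iter)

    p_hat = expit(design @ beta)
    std_coefs = beta[1:] * sds
    std_ses = se[1:] * sds
    separation = bool(
        np.any(np.abs(std_coefs) > separation_bound) or np.any(std_ses > se_bound)
    )
    return FittedPolicy(
        candidate_cues=names,
        included_cues=names,
        coefficients=dict(zip(names, beta[1:])),
        intercept=float(beta[0]),
        standard_errors={"intercept": float(se[0]), **dict(zip(names, se[1:]))},
        fitted_probs=p_hat,
        residuals=y - p_hat,
        converged=converged and not separation,
        separation=separation,
        log_likelihood=ll,
        n_iter=n_iter,
        cue_sds=dict(zip(names, sds)),
    )


def fit_stepwise(
    cues,
    outcome,
    cue_names: Sequence[str] | None = None,
    entry_thresholds: Sequence[float] = DEFAULT_ENTRY_THRESHOLDS,
    se_bound: float = DEFAULT_SE_BOUND,
    separation_bound: float = DEFAULT_SEPARATION_BOUND,
) -> FittedPolicy:
    """Forward-stepwise logistic regression with a standard-error guard.

    Cues enter one at a time by likelihood-ratio test at the current entry
    threshold; a candidate model is admissible only if it converged without
    a separation flag and every standardized-cue coefficient SE is at most
    ``se_bound``.  If no cue can enter at a threshold, the next (more
    lenient) threshold in the ladder is tried; the guaranteed terminal
    fallback is the intercept-only model.  Candidate cues are examined in
    their declared column order and ties on the LR p-value are broken by
    that order, so the procedure is deterministic.

    Excluded cues carry exactly zero weight downstream.
    """
    x_all, names = _as_matrix(cues, cue_names)
    y = np.asarray(outcome, dtype=float)

    def subset_fit(included: tuple[str, ...]) -> FittedPolicy:
        cols = [names.index(c) for c in included]
        fit = fit_logistic(
            x_all[:, cols] if cols else None,
            y,
            cue_names=included,
            se_bound=se_bound,
            separation_bound=separation_bound,
        )
        # Re-attach the full candidate set so excluded cues are visible.
        return FittedPolicy(
            candidate_cues=names,
            included_cues=included,
            coefficients=fit.coefficients,
            intercept=fit.intercept,
            standard_errors=fit.standard_errors,
            fitted_probs=fit.fitted_probs,
            residuals=fit.residuals,
            converged=fit.converged,
            separation=fit.separation,
            log_likelihood=fit.log_likelihood,
            n_iter=fit.n_iter,
            cue_sds=dict(zip(names, x_all.std(axis=0, ddof=1))),
        )

    def admissible(fit: FittedPolicy) -> bool:
        if not fit.converged or fit.separation:
            return False
        sds = fit.cue_sds or {}
        return all(
            fit.standard_errors[c] * sds[c] <= se_bound for c in fit.included_cues
        )

    base = subset_fit(())
    for threshold in entry_thresholds:
        current = base
        while True:
            best: FittedPolicy | None = None
            best_p = np.inf
            for cand in names:
                if cand in current.included_cues:
                    continue
                trial = subset_fit(current.included_cues + (cand,))
                if not admissible(trial):
                    continue
                lr = 2.0 * (trial.log_likelihood - current.log_likelihood)
                p_val = float(chi2.sf(max(lr, 0.0), df=1))
                if p_val < threshold and p_val < best_p:  # ties -> declared order
                    best, best_p = trial, p_val
            if best is None:
                break
            current = best
        if current.included_cues:
            return FittedPolicy(**{**current.__dict__, "entry_threshold_used": threshold})
    return FittedPolicy(**{**base.__dict__, "entry_threshold_used": entry_thresholds[-1]})


def cue_diagnostics(cues, cue_names: Sequence[str] | None = None) -> CueDiagnostics:
    """Pearson intercorrelations and the tolerance statistic per cue.

    Tolerance is 1 - R2 from an ordinary least-squares regression of the
    cue on all remaining cues; values near zero flag a cue that is almost
    a linear combination of the others.
    """
    x, names = _as_matrix(cues, cue_names)
    if x.shape[0] < 3:
        raise DegenerateDataError("need at least 3 cases for cue diagnostics")
    sds = x.std(axis=0, ddof=1)
    for name, sd in zip(names, sds):
        if sd == 0:
            raise ConfigurationError(f"cue {name!r} is constant")
    corr = np.corrcoef(x, rowvar=False)
    if corr.ndim == 0:  # single cue
        corr = np.array([[1.0]])

    tol: dict[str, float] = {}
    n = x.shape[0]
    for i, name in enumerate(names):
        others = np.delete(x, i, axis=1)
        if others.shape[1] == 0:
            tol[name] = 1.0
            continue
        design = np.hstack([np.ones((n, 1)), others])
        coef, *_ = np.linalg.lstsq(design, x[:, i], rcond=None)
        resid = x[:, i] - design @ coef
        ss_res = float(resid @ resid)
        centered = x[:, i] - x[:, i].mean()
        ss_tot = float(centered @ centered)
        tol[name] = float(np.clip(ss_res / ss_tot, 0.0, 1.0))
    return CueDiagnostics(cue_names=names, intercorrelation=corr, tolerance=tol)
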