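"""Repeat-judgement consistency: phi coefficient and parametric bootstrap.

A scenario set re-presents a handful of its cases; whether a participant
gives the same judgement on both presentations of a case measures the
consistency of their judgement policy, independently of its accuracy.
Pairs (first occurrence, repeat) are cross-tabulated into a 2x2 table —
pooled over participants by default, since five pairs per participant
rarely support a defined per-participant coefficient — and summarized by
the phi coefficient, the Pearson correlation of the two 0/1 vectors.

Conditions are compared by a parametric bootstrap of the phi difference:
each condition's table is resampled from a multinomial at its observed
total and cell proportions, and the SD of the resampled differences is
the bootstrap standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, DegenerateDataError, UndefinedPhiError
from .synthetic import JudgementSet, ScenarioSet


@dataclass(frozen=True)
class RepeatTable:
    """2x2 cross-tabulation of first-occurrence vs repeat judgements.

    Rows index the first-occurrence judgement (no / yes), columns the
    repeat judgement: ``a`` = no/no, ``b`` = no/yes, ``c`` = yes/no,
    ``d`` = yes/yes.
    """

    a: int
    b: int
    c: int
    d: int
    scope: str = "pooled"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigurationError("table counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise DegenerateDataError("empty repeat table")
        return np.array([self.a, self.b, self.c, self.d]) / self.total

    @classmethod
    def from_pairs(cls, first, repeat, scope: str = "pooled") -> "RepeatTable":
        """Build a table from aligned 0/1 vectors of paired judgements."""
        f = np.asarray(first, dtype=int)
        r = np.asarray(repeat, dtype=int)
        if f.shape != r.shape:
            raise ConfigurationError("paired vectors have different lengths")
        return cls(
            a=int(np.sum((f == 0) & (r == 0))),
            b=int(np.sum((f == 0) & (r == 1))),
            c=int(np.sum((f == 1) & (r == 0))),
            d=int(np.sum((f == 1) & (r == 1))),
            scope=scope,
        )


@dataclass(frozen=True)
class ConsistencyComparison:
    """Bootstrap comparison of phi between two conditions."""

    phi_a: float
    phi_b: float
    difference: float
    bootstrap_se: float
    z: float
    p_value: float
    n_replications: int
    n_redrawn: int
    seed: int


def phi_coefficient(table: RepeatTable) -> float:
    """Phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).

    Identical to the Pearson correlation of the two 0/1-coded vectors.
    Raises :class:`UndefinedPhiError` if any marginal is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if table.total == 0 or any(m == 0 for m in margins):
        raise UndefinedPhiError(
            f"phi undefined for table (a={a}, b={b}, c={c}, d={d}): zero marginal"
        )
    return float((a * d - b * c) / np.sqrt(np.prod([float(m) for m in margins])))


def consistency_phi(
    judgement_sets: Sequence[JudgementSet],
    scenario_set: ScenarioSet,
    scope: str = "pooled",
) -> tuple[float, RepeatTable] | dict[int, tuple[float | None, RepeatTable]]:
    """Phi over the repeated cases of a scenario set.

    For each participant, the judgement on each repeat presentation is
    paired with the judgement on its first occurrence.  With
    ``scope='pooled'`` (default) all pairs enter a single table and one
    phi is returned; with ``scope='per-participant'`` a mapping
    participant_id -> (phi or None when undefined, table) is returned.
    """
    pairs = scenario_set.repeat_pairs()
    if not pairs:
        raise DegenerateDataError("scenario set has no repeated presentations")

    def participant_pairs(js: JudgementSet) -> tuple[np.ndarray, np.ndarray]:
        y = js.as_array()
        first = np.array([y[i] for i, _ in pairs])
        rep = np.array([y[j] for _, j in pairs])
        return first, rep

    if scope == "pooled":
        firsts = np.concatenate([participant_pairs(js)[0] for js in judgement_sets])
        reps = np.concatenate([participant_pairs(js)[1] for js in judgement_sets])
        table = RepeatTable.from_pairs(firsts, reps, scope="pooled")
        return phi_coefficient(table), table
    if scope == "per-participant":
        out: dict[int, tuple[float | None, RepeatTable]] = {}
        for js in judgement_sets:
            f, r = participant_pairs(js)
            table = RepeatTable.from_pairs(f, r, scope="per-participant")
            try:
                out[js.participant_id] = (phi_coefficient(table), table)
            except UndefinedPhiError:
                out[js.participant_id] = (None, table)
        return out
    raise ConfigurationError(f"unknown scope {scope!r}")


def bootstrap_phi_difference(
    table_a: RepeatTable,
    table_b: RepeatTable,
    B: int = 50,
    seed: int = 0,
) -> ConsistencyComparison:
    """Parametric bootstrap of the phi difference between two conditions.

    Each replicate resamples both tables from multinomials at the observed
    totals and cell proportions and recomputes the phi difference; the SE
    is the n-1 SD over replicates and the z statistic is the observed
    difference over that SE, with a two-sided normal p-value.  Replicates
    on which either phi is undefined are redrawn so exactly ``B``
    replicates contribute; the redraw count is reported.  Deterministic
    given ``seed``.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    phi_a = phi_coefficient(table_a)  # raises if degenerate at observed counts
    phi_b = phi_coefficient(table_b)
    rng = np.random.default_rng(seed)
    diffs = np.empty(B)
    n_redrawn = 0
    for i in range(B):
        for _attempt in range(10_000):
            counts_a = rng.multinomial(table_a.total, table_a.proportions())
            counts_b = rng.multinomial(table_b.total, table_b.proportions())
            try:
                pa = phi_coefficient(RepeatTable(*counts_a.tolist()))
                pb = phi_coefficient(RepeatTable(*counts_b.tolist()))
            except UndefinedPhiError:
                n_redrawn += 1
                continue
            diffs[i] = pa - pb
            break
        else:  # pragma: no cover - requires pathological tables
            raise DegenerateDataError("bootstrap could not draw a defined replicate")
    observed = phi_a - phi_b
    se = float(np.std(diffs, ddof=1)) if B > 1 else float("nan")
    z = observed / se if se > 0 else float("inf") * np.sign(observed) if observed else 0.0
    p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return ConsistencyComparison(
        phi_a=phi_a,
        phi_b=phi_b,
        difference=observed,
        bootstrap_se=se,
        z=float(z),
        p_value=p,
        n_replications=B,
        n_redrawn=n_redrawn,
        seed=seed,
    )
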