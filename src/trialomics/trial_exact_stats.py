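"""Exact binomial machinery for single-arm phase-2 trials.

Implements the single-stage exact design of A'Hern (find the smallest
sample size ``n`` admitting a response threshold ``r`` that controls the
one-sided type-I error under the unacceptable rate ``p0`` while keeping
power under the target rate ``p1``), Clopper-Pearson exact confidence
intervals, confirmed objective-response-rate estimation on RECIST-style
response records, and evaluation of a pre-specified two-stage
futility/promising rule.

All tail probabilities come from the exact binomial distribution; no
normal approximations are used anywhere in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "DesignSpec",
    "DesignResult",
    "TwoStageRule",
    "ResponseRecord",
    "BinomialCI",
    "binom_tail_ge",
    "ahern_design",
    "clopper_pearson",
    "confirmed_orr",
    "evaluate_two_stage",
    "read_response_records",
    "format_percent",
]

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
#: RECIST categories that can constitute a confirmed objective response.
OBJECTIVE_RESPONSES = ("CR", "PR")


class DomainError(ValueError):
    """Raised when an argument lies outside the operation's domain."""


class DesignSearchError(RuntimeError):
    """Raised when no exact design exists below the search ceiling."""


@dataclass(frozen=True)
class DesignSpec:
    """Hypotheses for a single-arm exact binomial design.

    Parameters
    ----------
    p0 : float
        Unacceptable (null) response probability.
    p1 : float
        Target (alternative) response probability; must exceed ``p0``.
    alpha : float
        One-sided type-I error bound.
    power : float
        Required power at ``p1``.
    """

    p0: float
    p1: float
    alpha: float
    power: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 < self.p1 <= 1.0):
            raise DomainError(f"need 0 <= p0 < p1 <= 1, got p0={self.p0}, p1={self.p1}")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError(f"alpha must lie in (0,1), got {self.alpha}")
        if not (0.0 < self.power < 1.0):
            raise DomainError(f"power must lie in (0,1), got {self.power}")


@dataclass(frozen=True)
class DesignResult:
    """A single-stage exact design: treat ``n`` patients, declare the
    regimen promising when at least ``r`` respond."""

    n: int
    r: int
    #: Attained one-sided type-I error P(X >= r | n, p0).
    alpha_attained: float = 0.0
    #: Attained power P(X >= r | n, p1).
    power_attained: float = 0.0


@dataclass(frozen=True)
class TwoStageRule:
    """A pre-specified two-stage stopping rule.

    Stage 1 enrols ``n1`` patients; fewer than ``s1_min`` stage-1
    successes stops for futility.  Otherwise the trial continues to
    ``n_total`` patients and is promising when the final success count
    reaches ``r_final``.
    """

    n1: int
    s1_min: int
    n_total: int
    r_final: int

    def __post_init__(self) -> None:
        if not self.n1 < self.n_total:
            raise DomainError("n1 must be smaller than n_total")
        if not (0 <= self.s1_min <= self.n1):
            raise DomainError("s1_min must lie in [0, n1]")
        if self.r_final > self.n_total:
            raise DomainError("r_final cannot exceed n_total")


@dataclass(frozen=True)
class ResponseRecord:
    """One patient's best RECIST response within a cohort."""

    patient_id: str
    cohort: int
    best_response: str
    confirmed: bool
    best_change_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.best_response not in RESPONSE_CATEGORIES:
            raise DomainError(f"unknown best_response {self.best_response!r}")
        if self.confirmed and self.best_response not in OBJECTIVE_RESPONSES:
            raise DomainError("confirmed responses must be CR or PR")


@dataclass(frozen=True)
class BinomialCI:
    """An exact two-sided binomial confidence interval for k/n."""

    k: int
    n: int
    level: float
    lo: float
    hi: float


def binom_tail_ge(k: int, n: int, p: float) -> float:
    """Upper binomial tail P(X >= k) for X ~ Binomial(n, p).

    ``k`` may be 0 (tail is 1) or ``n + 1`` (tail is 0), which the
    design search uses as boundary cases.
    """
    if k < 0 or n < 0 or not (0.0 <= p <= 1.0):
        raise DomainError(f"invalid domain: k={k}, n={n}, p={p}")
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    # survival function at k-1 gives P(X >= k); scipy sums the exact pmf.
    return float(stats.binom.sf(k - 1, n, p))


def ahern_design(spec: DesignSpec, n_max: int = 1000) -> DesignResult:
    """Exact single-stage design search.

    Iterates ``n`` upward from 1 and returns the smallest ``n`` for
    which some threshold ``r`` satisfies both

    * P(X >= r | n, p0) <= alpha  (type-I error control), and
    * P(X >= r | n, p1) >= power  (power requirement),

    with ``r`` the smallest such threshold at that ``n``.
    """
    for n in range(1, n_max + 1):
        # The type-I condition holds for all r above some cutoff and the
        # power condition for all r below another; scan r upward and
        # return the first r satisfying both.
        for r in range(1, n + 1):
            a = binom_tail_ge(r, n, spec.p0)
            if a > spec.alpha:
                continue
            pw = binom_tail_ge(r, n, spec.p1)
            if pw >= spec.power:
                return DesignResult(n=n, r=r, alpha_attained=a, power_attained=pw)
            break  # power only decreases as r grows
    raise DesignSearchError(f"no design with n <= {n_max} for {spec}")


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact (Clopper-Pearson) two-sided confidence interval for a
    binomial proportion, in its beta-quantile form.

    The lower bound is the ``(1-level)/2`` beta quantile with shape
    ``(k, n-k+1)`` and the upper the ``(1+level)/2`` quantile with shape
    ``(k+1, n-k)``; ``k = 0`` forces ``lo = 0`` and ``k = n`` forces
    ``hi = 1``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if not (0 <= k <= n):
        raise DomainError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < level < 1.0):
        raise DomainError("level must lie in (0,1)")
    lo = 0.0 if k == 0 else float(stats.beta.ppf((1.0 - level) / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf((1.0 + level) / 2.0, k + 1, n - k))
    return BinomialCI(k=k, n=n, level=level, lo=lo, hi=hi)


def confirmed_orr(
    records: Iterable[ResponseRecord],
    cohort: int,
    level: float = 0.95,
) -> tuple[float, BinomialCI]:
    """Confirmed objective response rate of one cohort with its exact CI.

    A responder is a record with ``confirmed`` set (hence CR or PR).
    Non-evaluable (NE) patients stay in the denominator, matching
    full-analysis-set logic.
    """
    in_cohort = [r for r in records if r.cohort == cohort]
    if not in_cohort:
        raise DomainError(f"no records in cohort {cohort!r}")
    k = sum(1 for r in in_cohort if r.confirmed)
    n = len(in_cohort)
    return k / n, clopper_pearson(k, n, level)


def evaluate_two_stage(
    rule: TwoStageRule,
    stage1_successes: int,
    final_successes: Optional[int] = None,
    require_final: bool = False,
) -> str:
    """Evaluate a two-stage rule against observed success counts.

    Returns one of ``stop_futility``, ``continue``, ``promising`` or
    ``not_promising``.  When stage 1 passes and no final count is given,
    the trial is still accruing: the decision is ``continue`` unless
    ``require_final`` is set, in which case a missing final count is an
    error.
    """
    if not (0 <= stage1_successes <= rule.n1):
        raise DomainError("stage1_successes must lie in [0, n1]")
    if stage1_successes < rule.s1_min:
        return "stop_futility"
    if final_successes is None:
        if require_final:
            raise DomainError("stage 1 passed but final success count is absent")
        return "continue"
    # Stage 1 may count a different (short-term) endpoint than the final
    # analysis, so final_successes is not constrained by stage1_successes.
    if not (0 <= final_successes <= rule.n_total):
        raise DomainError("final_successes must lie in [0, n_total]")
    return "promising" if final_successes >= rule.r_final else "not_promising"


def read_response_records(path) -> list[ResponseRecord]:
    """Read response records from CSV with columns
    patient_id,cohort,best_response,confirmed,best_change_pct."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        change = getattr(row, "best_change_pct", None)
        if change is not None and isinstance(change, float) and math.isnan(change):
            change = None
        confirmed = row.confirmed
        if isinstance(confirmed, str):
            confirmed = confirmed.strip().lower() in ("true", "1", "yes")
        records.append(
            ResponseRecord(
                patient_id=str(row.patient_id),
                cohort=int(row.cohort),
                best_response=str(row.best_response),
                confirmed=bool(confirmed),
                best_change_pct=change,
            )
        )
    return records


def format_percent(x: float) -> str:
    """Format a proportion as a percent, one decimal, rounding half away
    from zero, dropping a trailing '.0' (0.706 -> '70.6', 0.81 -> '81')."""
    pct = x * 100.0
    scaled = math.floor(abs(pct) * 10.0 + 0.5) / 10.0
    scaled = math.copysign(scaled, pct)
    if scaled == int(scaled):
        return str(int(scaled))
    return f"{scaled:.1f}"
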