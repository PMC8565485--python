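"""Feasibility rates, difficulty-trajectory summaries and paired statistics.

Feasibility protocol
--------------------
Six pre-defined rates, each compared to a pre-registered threshold:

==============  ==========================================  =========
rate            definition                                  threshold
==============  ==========================================  =========
inclusion       100 * included / screened                   >= 50
adherence       100 * attended sessions / offered sessions  >= 80
compliance      100 * attended minutes / offered minutes    >= 80
attrition       100 * dropouts / included                   <= 15
motivation      10 * mean VAS rating (0-10 scale)           >= 60
satisfaction    10 * mean VAS rating (0-10 scale)           >= 60
==============  ==========================================  =========

Percentages are rounded half-up to integers before the threshold
comparison, matching how such protocol tables are reported.

Paired pre/post analysis
------------------------
Small feasibility cohorts are analysed nonparametrically: descriptives
as median and interquartile range, within-subject change by the
Wilcoxon signed-rank test (T = the smaller of the two signed rank sums,
mid-ranks for tied absolute differences, zero differences dropped,
tie-corrected normal approximation without continuity correction, or an
exact sign-flip permutation distribution for small n), and the effect
size r = |z|/sqrt(n) classified as small (r < 0.30), medium
(0.30 <= r < 0.50) or large (r >= 0.50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .progression import DEFAULT_ZONES, ZoneConfig
from .simulate import SessionRecord

__all__ = [
    "FeasibilityCounts",
    "FeasibilityThresholds",
    "RateResult",
    "FeasibilityReport",
    "PairedSample",
    "WilcoxonResult",
    "PairedDescriptives",
    "DegenerateSampleError",
    "UndefinedRateError",
    "feasibility_report",
    "counts_from_records",
    "wilcoxon_signed_rank",
    "effect_size_class",
    "paired_descriptives",
    "difficulty_trajectory",
]


class UndefinedRateError(ZeroDivisionError):
    """A feasibility rate has a zero denominator."""


class DegenerateSampleError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class FeasibilityCounts:
    """Raw trial bookkeeping counts feeding the six rates."""

    screened: int
    included: int
    dropouts: int
    offered_sessions: int
    attended_sessions: int
    offered_minutes: float
    attended_minutes: float
    mean_motivation: float
    mean_satisfaction: float

    def __post_init__(self) -> None:
        for name in (
            "screened",
            "included",
            "dropouts",
            "offered_sessions",
            "attended_sessions",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.included > self.screened:
            raise ValueError("included cannot exceed screened")
        if self.dropouts > self.included:
            raise ValueError("dropouts cannot exceed included")
        if self.attended_sessions > self.offered_sessions:
            raise ValueError("attended_sessions cannot exceed offered_sessions")
        if self.offered_minutes < 0 or self.attended_minutes < 0:
            raise ValueError("minutes must be >= 0")
        if self.attended_minutes > self.offered_minutes:
            raise ValueError("attended_minutes cannot exceed offered_minutes")
        for name in ("mean_motivation", "mean_satisfaction"):
            if not (0.0 <= getattr(self, name) <= 10.0):
                raise ValueError(f"{name} must lie in [0, 10]")


@dataclass(frozen=True)
class FeasibilityThresholds:
    """Acceptance thresholds in percent; attrition is an upper bound."""

    inclusion_min: float = 50.0
    adherence_min: float = 80.0
    compliance_min: float = 80.0
    attrition_max: float = 15.0
    motivation_min: float = 60.0
    satisfaction_min: float = 60.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100]")


@dataclass(frozen=True)
class RateResult:
    """One feasibility rate with its threshold verdict."""

    name: str
    data: str
    raw_pct: float
    pct: int
    threshold: float
    direction: str  # "ge" or "le"
    met: bool


@dataclass(frozen=True)
class FeasibilityReport:
    rates: tuple[RateResult, ...]

    @property
    def all_met(self) -> bool:
        return all(r.met for r in self.rates)

    def __getitem__(self, name: str) -> RateResult:
        for r in self.rates:
            if r.name == name:
                return r
        raise KeyError(name)

    def as_dict(self) -> dict:
        return {
            "rates": {
                r.name: {
                    "data": r.data,
                    "raw_pct": r.raw_pct,
                    "pct": r.pct,
                    "threshold": r.threshold,
                    "direction": r.direction,
                    "met": r.met,
                }
                for r in self.rates
            },
            "all_met": self.all_met,
        }

    def to_text(self) -> str:
        """Human-readable table: criterion, threshold, data, outcome, met."""
        header = f"{'criterion':<14}{'threshold':<12}{'data':<28}{'outcome':>8}  met"
        lines = [header, "-" * len(header)]
        for r in self.rates:
            sign = ">=" if r.direction == "ge" else "<="
            lines.append(
                f"{r.name:<14}{sign} {r.threshold:<9.0f}{r.data:<28}"
                f"{r.pct:>7}%  {'yes' if r.met else 'NO'}"
            )
        return "\n".join(lines)


def _rate(numer: float, denom: float, name: str) -> float:
    if denom == 0:
        raise UndefinedRateError(f"{name} rate undefined: zero denominator")
    return 100.0 * numer / denom


def feasibility_report(
    counts: FeasibilityCounts,
    thresholds: FeasibilityThresholds | None = None,
) -> FeasibilityReport:
    """Compute the six protocol rates and their threshold verdicts.

    Verdicts compare the half-up-rounded integer percent to the
    threshold: attrition must stay at or below its bound, every other
    rate at or above.
    """
    t = thresholds or FeasibilityThresholds()
    c = counts
    specs = [
        ("inclusion", _rate(c.included, c.screened, "inclusion"),
         f"{c.included}/{c.screened} participants", t.inclusion_min, "ge"),
        ("adherence", _rate(c.attended_sessions, c.offered_sessions, "adherence"),
         f"{c.attended_sessions}/{c.offered_sessions} sessions", t.adherence_min, "ge"),
        ("compliance", _rate(c.attended_minutes, c.offered_minutes, "compliance"),
         f"{c.attended_minutes:g}/{c.offered_minutes:g} min", t.compliance_min, "ge"),
        ("attrition", _rate(c.dropouts, c.included, "attrition"),
         f"{c.dropouts}/{c.included} participants", t.attrition_max, "le"),
        ("motivation", 10.0 * c.mean_motivation,
         f"mean VAS {c.mean_motivation:g}/10", t.motivation_min, "ge"),
        ("satisfaction", 10.0 * c.mean_satisfaction,
         f"mean VAS {c.mean_satisfaction:g}/10", t.satisfaction_min, "ge"),
    ]
    rates = []
    for name, raw, data, threshold, direction in specs:
        pct = _round_half_up(raw)
        met = pct >= threshold if direction == "ge" else pct <= threshold
        rates.append(RateResult(name, data, raw, pct, threshold, direction, met))
    return FeasibilityReport(tuple(rates))


def counts_from_records(
    records: Sequence[SessionRecord], screened: int | None = None
) -> FeasibilityCounts:
    """Aggregate a session log into feasibility bookkeeping counts.

    Dropped sessions count as offered but not attended; motivation and
    satisfaction are averaged over attended sessions only.  ``screened``
    defaults to the number of included participants (inclusion 100%).
    """
    if not records:
        raise ValueError("records must be non-empty")
    ids = {r.participant_id for r in records}
    included = len(ids)
    dropouts = len({r.participant_id for r in records if r.dropped})
    attended = [r for r in records if not r.dropped]
    motiv = [r.motivation for r in attended if not math.isnan(r.motivation)]
    satis = [r.satisfaction for r in attended if not math.isnan(r.satisfaction)]
    return FeasibilityCounts(
        screened=screened if screened is not None else included,
        included=included,
        dropouts=dropouts,
        offered_sessions=len(records),
        attended_sessions=len(attended),
        offered_minutes=float(sum(r.planned_min for r in records)),
        attended_minutes=float(sum(r.attended_min for r in records)),
        mean_motivation=float(np.mean(motiv)) if motiv else 0.0,
        mean_satisfaction=float(np.mean(satis)) if satis else 0.0,
    )


@dataclass(frozen=True)
class PairedSample:
    """Pre/post outcome vectors paired by index.

    Pairs with a missing (non-finite) value on either side are removed
    on construction and counted in ``n_missing``.
    """

    pre: tuple[float, ...]
    post: tuple[float, ...]
    n_missing: int = 0

    def __post_init__(self) -> None:
        if len(self.pre) != len(self.post):
            raise ValueError("pre and post must have equal length")
        if len(self.pre) < 1:
            raise ValueError("sample must contain at least one complete pair")

    @classmethod
    def from_arrays(cls, pre: Iterable[float], post: Iterable[float]) -> "PairedSample":
        pre = np.asarray(list(pre), dtype=float)
        post = np.asarray(list(post), dtype=float)
        if pre.shape != post.shape:
            raise ValueError("pre and post must have equal length")
        keep = np.isfinite(pre) & np.isfinite(post)
        return cls(
            pre=tuple(pre[keep]),
            post=tuple(post[keep]),
            n_missing=int((~keep).sum()),
        )

    @property
    def n(self) -> int:
        return len(self.pre)

    @property
    def differences(self) -> np.ndarray:
        """Per-pair change, post - pre."""
        return np.asarray(self.post) - np.asarray(self.pre)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # T, the smaller signed rank sum
    n_eff: int  # pairs remaining after zero differences are dropped
    z: float
    p_value: float
    r: float
    method: str


def _signflip_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each achievable positive-rank sum over all sign flips.

    ``ranks2`` holds the mid-ranks doubled so they are integers; the
    returned array c satisfies c[s] = #{sign patterns with 2*W+ = s}.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r2 in ranks2:
        r2 = int(r2)
        counts[r2:] = counts[r2:] + counts[:-r2]
    return counts


def wilcoxon_signed_rank(
    sample: PairedSample, method: str = "asymptotic"
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences (post - pre).

    Zero differences are dropped; tied absolute differences get
    mid-ranks.  ``T`` is the smaller of the positive and negative rank
    sums.  The asymptotic p uses the tie-corrected normal approximation
    without continuity correction; the exact p enumerates the sign-flip
    distribution (n_eff <= 20) and reports the probability that the
    smaller rank sum is at most the observed ``T``.  The effect size is
    r = |z|/sqrt(n_eff) in both methods.
    """
    d = sample.differences
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    if method not in ("asymptotic", "exact"):
        raise ValueError(f"unknown method {method!r}")
    if method == "asymptotic" and n < 5:
        raise ValueError("asymptotic method requires at least 5 non-zero pairs")
    if method == "exact" and n > 20:
        raise ValueError("exact enumeration is limited to 20 non-zero pairs")

    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    T = min(w_pos, w_neg)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        raise DegenerateSampleError("zero variance: all |differences| identical ties")
    z = (T - mu) / math.sqrt(sigma2)
    r = abs(z) / math.sqrt(n)

    if method == "asymptotic":
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signflip_distribution(ranks2)
        total2 = int(ranks2.sum())
        t2 = int(round(2 * T))
        sums = np.arange(total2 + 1)
        keep = np.minimum(sums, total2 - sums) <= t2
        p = float(counts[keep].sum() / 2.0**n)
    return WilcoxonResult(
        statistic=T, n_eff=n, z=float(z), p_value=float(min(p, 1.0)), r=float(r),
        method=method,
    )


def effect_size_class(r: float) -> str:
    """Classify an effect size r: small (< 0.30), medium (< 0.50), large."""
    if r < 0:
        raise ValueError("effect size r must be >= 0 (use |r|)")
    if r < 0.30:
        return "small"
    if r < 0.50:
        return "medium"
    return "large"


@dataclass(frozen=True)
class PairedDescriptives:
    """Median/IQR descriptives of a paired sample and its differences."""

    n: int
    median_pre: float
    iqr_pre: tuple[float, float]
    median_post: float
    iqr_post: tuple[float, float]
    median_diff: float
    iqr_diff: tuple[float, float]


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    q25, q50, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return float(q50), (float(q25), float(q75))


def paired_descriptives(sample: PairedSample) -> PairedDescriptives:
    pre = np.asarray(sample.pre)
    post = np.asarray(sample.post)
    m_pre, iqr_pre = _median_iqr(pre)
    m_post, iqr_post = _median_iqr(post)
    m_diff, iqr_diff = _median_iqr(sample.differences)
    return PairedDescriptives(
        n=sample.n,
        median_pre=m_pre,
        iqr_pre=iqr_pre,
        median_post=m_post,
        iqr_post=iqr_post,
        median_diff=m_diff,
        iqr_diff=iqr_diff,
    )


def difficulty_trajectory(
    records: Sequence[SessionRecord], zones: ZoneConfig = DEFAULT_ZONES
) -> pd.DataFrame:
    """Per-session-index mean difficulty ratings and in-target fractions.

    Dropped sessions are excluded.  Returns one row per session index
    holding n, mean motor and cognitive VAS, and the fraction of raw
    ratings inside the target zone on each axis.
    """
    rows = []
    attended = [r for r in records if not r.dropped]
    by_index: dict[int, list[SessionRecord]] = {}
    for r in attended:
        by_index.setdefault(r.session_index, []).append(r)
    for s in sorted(by_index):
        recs = by_index[s]
        motor = np.array([r.motor_vas for r in recs])
        cog = np.array([r.cognitive_vas for r in recs])
        rows.append(
            {
                "session_index": s,
                "n": len(recs),
                "mean_motor_vas": float(motor.mean()),
                "mean_cognitive_vas": float(cog.mean()),
                "frac_target_motor": float(
                    np.mean([(zones.in_target(v)) for v in motor])
                ),
                "frac_target_cognitive": float(
                    np.mean([(zones.in_target(v)) for v in cog])
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "session_index",
            "n",
            "mean_motor_vas",
            "mean_cognitive_vas",
            "frac_target_motor",
            "frac_target_cognitive",
        ],
    )
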