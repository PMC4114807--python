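"""Recompute p values from printed statistics and judge reporting consistency.

A reported result like ``t(20) = 1.50, p = .04`` is checked by recomputing
the p value from the printed statistic and degrees of freedom and asking
whether the printed p could have arisen from *any* statistic that rounds to
the printed one.  Both sides are therefore treated as rounding intervals:

* the printed statistic ``x`` with ``k`` decimals stands for the half-open
  interval ``[x - u/2, x + u/2)`` with ``u = 10**-k``; pushing that interval
  through the (monotone) statistic-to-p map gives the interval of p values
  consistent with the printed statistic;
* the printed p stands for its own rounding interval (``=``), or for
  ``(0, bound)`` / ``(bound, 1]`` for ``<`` / ``>`` comparators.

The result is *consistent* when the two intervals overlap.  Inconsistent
results are reporting errors; an error is *large* when reported and
recomputed p differ by more than .01, and *gross* when a result reported as
significant (p < .05) recomputes to a non-significant p (>= .05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .extraction import PComparator, ReportedResult, TailNote, TestFamily

__all__ = [
    "PInterval",
    "ConsistencyVerdict",
    "recompute_p",
    "rounding_interval",
    "reported_p_interval",
    "statistic_p_interval",
    "check_consistency",
    "classify_error",
]


@dataclass(frozen=True)
class PInterval:
    """An interval of p values with explicit endpoint closure."""

    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.hi <= 1.0):
            raise ValueError(f"invalid p interval [{self.lo}, {self.hi}]")

    def overlaps(self, other: "PInterval") -> bool:
        if self.hi < other.lo or other.hi < self.lo:
            return False
        if self.hi == other.lo:
            return self.hi_closed and other.lo_closed
        if other.hi == self.lo:
            return other.hi_closed and self.lo_closed
        return True

    def entirely_below(self, bound: float) -> bool:
        return self.hi < bound or (self.hi == bound and not self.hi_closed)

    def contains(self, x: float) -> bool:
        if x < self.lo or x > self.hi:
            return False
        if x == self.lo and not self.lo_closed:
            return False
        if x == self.hi and not self.hi_closed:
            return False
        return True

    def halved(self) -> "PInterval":
        return PInterval(self.lo / 2.0, self.hi / 2.0, self.lo_closed, self.hi_closed)


@dataclass(frozen=True)
class ConsistencyVerdict:
    p_recomputed: float
    p_interval: PInterval
    reported_interval: PInterval
    consistent: bool
    one_tailed_salvage: bool
    error: bool
    is_large: bool
    is_gross: bool

    @property
    def error_class(self) -> str:
        return "error" if self.error else "none"


def recompute_p(family: TestFamily, df1: float | None, df2: float, statistic: float) -> float:
    """Two-tailed p for a t statistic; upper-tail p for an F statistic."""
    if not math.isfinite(statistic) or not math.isfinite(df2) or df2 <= 0:
        raise ValueError("statistic and dfs must be finite, df2 > 0")
    if family is TestFamily.t:
        return float(2.0 * stats.t.sf(abs(statistic), df2))
    if df1 is None or not math.isfinite(df1) or df1 < 1:
        raise ValueError("F tests need finite df1 >= 1")
    if statistic < 0:
        raise ValueError("F statistic must be non-negative")
    return float(stats.f.sf(statistic, df1, df2))


def _decimals(printed: str) -> int:
    s = printed.strip()
    return len(s.split(".", 1)[1]) if "." in s else 0


def rounding_interval(printed: str) -> tuple[float, float]:
    """Half-open interval ``[v - u/2, v + u/2)`` of numbers that round to
    the printed decimal string (``u = 10**-k`` for ``k`` printed decimals;
    trailing zeros count)."""
    v = float(printed)  # raises on non-numeric
    if not math.isfinite(v):
        raise ValueError(f"non-finite printed value {printed!r}")
    u = 10.0 ** (-_decimals(printed))
    return (v - u / 2.0, v + u / 2.0)


def reported_p_interval(comparator: PComparator, p_text: str) -> PInterval:
    """Interval of p values compatible with the printed p claim."""
    v = float(p_text)
    if not 0.0 < v < 1.0:
        raise ValueError(f"p value {p_text!r} outside (0, 1)")
    if comparator is PComparator.eq:
        lo, hi = rounding_interval(p_text)
        return PInterval(max(lo, 0.0), min(hi, 1.0), lo_closed=True, hi_closed=False)
    if comparator is PComparator.lt:
        return PInterval(0.0, v, lo_closed=False, hi_closed=False)
    return PInterval(v, 1.0, lo_closed=False, hi_closed=True)


def statistic_p_interval(
    family: TestFamily, df1: float | None, df2: float, statistic_text: str
) -> PInterval:
    """Image of the statistic's rounding interval under the p mapping.

    The p map is strictly decreasing in |statistic|, so the interval of
    achievable p values comes from the extreme |statistic| values.  A
    statistic interval straddling zero (e.g. printed "0.0") attains
    |statistic| = 0 and hence p = 1.
    """
    s_lo, s_hi = rounding_interval(statistic_text)
    if family is TestFamily.F:
        s_lo = max(s_lo, 0.0)
    # Image of [s_lo, s_hi) under abs(): track which endpoints are attained.
    if s_lo >= 0.0:
        a_lo, a_hi = s_lo, s_hi
        a_lo_closed, a_hi_closed = True, False
    elif s_hi <= 0.0:
        a_lo, a_hi = abs(s_hi), abs(s_lo)
        a_lo_closed, a_hi_closed = False, True
    else:  # straddles zero: |x| ranges over [0, max(|s_lo|, s_hi))... or ]
        a_lo, a_lo_closed = 0.0, True
        if abs(s_lo) > s_hi:
            a_hi, a_hi_closed = abs(s_lo), True
        else:
            a_hi, a_hi_closed = s_hi, False
    p_at_hi = recompute_p(family, df1, df2, a_hi)
    p_at_lo = recompute_p(family, df1, df2, a_lo)
    # p decreasing in |statistic|: endpoint closures swap.
    return PInterval(p_at_hi, p_at_lo, lo_closed=a_hi_closed, hi_closed=a_lo_closed)


def classify_error(
    p_recomputed: float,
    reported_interval: PInterval,
    consistent: bool,
    reported_point: float,
) -> tuple[bool, bool, bool]:
    """(error, is_large, is_gross) for a checked result.

    ``reported_point`` is the printed p value for ``=`` reports and the
    printed bound for ``<``/``>`` reports; magnitude judgments use point
    values, not interval endpoints.
    """
    if consistent:
        return (False, False, False)
    is_large = abs(reported_point - p_recomputed) > 0.01
    is_gross = reported_interval.entirely_below(0.05) and p_recomputed >= 0.05
    return (True, is_large, is_gross)


def check_consistency(r: ReportedResult, *, strict: bool = False) -> ConsistencyVerdict:
    """Full rounding-aware consistency check for one reported result.

    When ``strict`` is False (default), an inconsistent result whose
    halved p interval overlaps the reported interval *and* whose context
    mentioned a one-tailed test is salvaged: counted consistent but flagged
    ``one_tailed_salvage`` so it can be tallied separately.
    """
    p_rec = recompute_p(r.test_family, r.df1, r.df2, abs(r.statistic))
    p_int = statistic_p_interval(r.test_family, r.df1, r.df2, r.statistic_text)
    rep_int = reported_p_interval(r.p_comparator, r.p_text)
    consistent = p_int.overlaps(rep_int)
    salvage = False
    if (
        not consistent
        and not strict
        and r.tail_note is TailNote.one_tailed_context
        and p_int.halved().overlaps(rep_int)
    ):
        consistent = True
        salvage = True
    error, is_large, is_gross = classify_error(p_rec, rep_int, consistent, r.p_value)
    return ConsistencyVerdict(
        p_recomputed=p_rec,
        p_interval=p_int,
        reported_interval=rep_int,
        consistent=consistent,
        one_tailed_salvage=salvage,
        error=error,
        is_large=is_large,
        is_gross=is_gross,
    )
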