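"""Screen t-test degrees of freedom against the described sample size.

Undisclosed removal of cases (outliers, dropouts) leaves a trace: the df of
a t test computed after exclusions is smaller than the df implied by the
sample size the article describes.  For an independent two-sample t test the
expected df is N - 2; for a paired or one-sample test it is n - 1, after
subtracting any *disclosed* exclusions and missingness.  Any exact-integer
mismatch is flagged as a discrepancy; Welch-style fractional dfs and unknown
designs are conservatively indeterminate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .extraction import ReportedResult, TestFamily

__all__ = [
    "Design",
    "DesignSpec",
    "DfVerdict",
    "expected_df",
    "check_t_df",
    "article_discrepancy",
    "screen_t_results",
]


class Design(str, Enum):
    independent_two_sample = "independent_two_sample"
    paired_or_one_sample = "paired_or_one_sample"
    unknown = "unknown"


class DfVerdict(str, Enum):
    match = "match"
    discrepancy = "discrepancy"
    indeterminate = "indeterminate"


@dataclass(frozen=True)
class DesignSpec:
    """Study design metadata, supplied alongside the article (not text-mined)."""

    design: Design
    n_total: int
    n_groups: tuple[int, int] | None = None
    reported_exclusions: int = 0
    reported_missing: int = 0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.reported_exclusions < 0 or self.reported_missing < 0:
            raise ValueError("exclusion/missing counts must be non-negative")
        if self.n_groups is not None and sum(self.n_groups) != self.n_total:
            raise ValueError("group sizes must sum to n_total")


def expected_df(spec: DesignSpec) -> int:
    """Expected t-test df from design and disclosed exclusions/missingness."""
    if spec.design is Design.unknown:
        raise ValueError("expected df is indeterminate for unknown designs")
    n_eff = spec.n_total - spec.reported_exclusions - spec.reported_missing
    return n_eff - 2 if spec.design is Design.independent_two_sample else n_eff - 1


def check_t_df(result: ReportedResult, spec: DesignSpec) -> DfVerdict:
    """Compare a t test's reported df with the design-implied df.

    Fractional (Welch) dfs and unknown designs yield ``indeterminate``,
    never ``discrepancy`` — mirroring a hand-check that only calls an
    inconsistency after ruling out dropout and missingness.
    """
    if result.test_family is not TestFamily.t:
        raise ValueError("df screening applies to t tests only")
    if spec.design is Design.unknown:
        return DfVerdict.indeterminate
    if not float(result.df2).is_integer():
        return DfVerdict.indeterminate
    return DfVerdict.match if int(result.df2) == expected_df(spec) else DfVerdict.discrepancy


def article_discrepancy(
    verdicts: Iterable[DfVerdict],
) -> tuple[bool | None, Counter]:
    """Article-level flag: any t test with a df discrepancy.

    Returns ``(flag, counts)`` where counts tallies match/discrepancy/
    indeterminate verdicts.  With no determinate verdict at all the flag is
    ``None`` (the article cannot be screened).
    """
    counts: Counter = Counter({v: 0 for v in DfVerdict})
    for v in verdicts:
        counts[v] += 1
    if counts[DfVerdict.match] == 0 and counts[DfVerdict.discrepancy] == 0:
        return (None, counts)
    return (counts[DfVerdict.discrepancy] > 0, counts)


def screen_t_results(
    results: Iterable[ReportedResult], specs: Sequence[DesignSpec]
) -> list[DfVerdict]:
    """Screen every t test in an article against its described studies.

    Articles typically describe several studies and the mapping from test
    to study is not recorded in the text, so a t test counts as a match
    when *any* described study's expected df equals the reported df;
    otherwise it is a discrepancy (or indeterminate for Welch dfs or when
    no study has a known design).  Non-t results are skipped.
    """
    verdicts: list[DfVerdict] = []
    known = [s for s in specs if s.design is not Design.unknown]
    for r in results:
        if r.test_family is not TestFamily.t:
            continue
        if not known:
            verdicts.append(DfVerdict.indeterminate)
            continue
        if not float(r.df2).is_integer():
            verdicts.append(DfVerdict.indeterminate)
            continue
        per_study = [check_t_df(r, s) for s in known]
        if DfVerdict.match in per_study:
            verdicts.append(DfVerdict.match)
        else:
            verdicts.append(DfVerdict.discrepancy)
    return verdicts
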