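"""Find and parse APA-style t and F test reports in plain article text.

An APA-formatted result reads like ``F(1, 23) = 4.45, p = .046`` or
``t(40) = -2.50, p < .05``.  Only *completely* reported results (test
statistic, degrees of freedom, and p value all present) are returned;
fragments missing any element are skipped.  Printed precision is preserved:
the statistic and p value are kept as the exact decimal strings found in the
text, because trailing zeros determine the rounding interval used later by
the consistency checker.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Group",
    "TestFamily",
    "PComparator",
    "TailNote",
    "RawDocument",
    "ReportedResult",
    "scan_text",
    "render_result",
    "read_manual_results",
    "results_to_frame",
]


class Group(str, Enum):
    """Article group label: did the article report removing outliers?"""

    outliers_removed = "outliers_removed"
    no_removal = "no_removal"


class TestFamily(str, Enum):
    t = "t"
    F = "F"


class PComparator(str, Enum):
    eq = "eq"
    lt = "lt"
    gt = "gt"


class TailNote(str, Enum):
    none = "none"
    one_tailed_context = "one_tailed_context"


@dataclass(frozen=True)
class RawDocument:
    """One article body plus the metadata the pipeline needs."""

    article_id: str
    text: str
    group: Group
    journal: str = ""
    study_sample_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.study_sample_sizes):
            raise ValueError("study sample sizes must be positive")


@dataclass(frozen=True)
class ReportedResult:
    """One statistical result exactly as printed.

    ``statistic_text`` and ``p_text`` keep the printed decimal strings so
    that the number of decimal places (including trailing zeros) remains
    recoverable.
    """

    test_family: TestFamily
    df1: float | None  # numerator df; None for t tests
    df2: float
    statistic_text: str
    p_comparator: PComparator
    p_text: str
    span: tuple[int, int] = (0, 0)
    source: str = "auto"  # "auto" | "manual"
    tail_note: TailNote = TailNote.none

    def __post_init__(self) -> None:
        stat = float(self.statistic_text)
        if not (stat == stat and abs(stat) != float("inf")):
            raise ValueError(f"non-finite statistic {self.statistic_text!r}")
        p = float(self.p_text)
        if not 0.0 < p < 1.0:
            raise ValueError(f"p value {self.p_text!r} outside (0, 1)")
        if self.df2 <= 0:
            raise ValueError("df2 must be positive")
        if self.test_family is TestFamily.F:
            if self.df1 is None or self.df1 < 1:
                raise ValueError("F tests need df1 >= 1")
            if stat < 0:
                raise ValueError("F statistics are non-negative")

    @property
    def statistic(self) -> float:
        return float(self.statistic_text)

    @property
    def p_value(self) -> float:
        return float(self.p_text)


# Unicode minus / en-dash are common in copy-pasted article text.
_DASHES = str.maketrans({"−": "-", "–": "-"})

_NUM = r"\d+(?:\.\d+)?"
_RESULT_RE = re.compile(
    rf"""
    \*{{0,2}}(?P<fam>[tF])\*{{0,2}}          # t or F, optional italics stars
    \s*\(\s*
    (?P<d1>{_NUM})                           # first (or only) df
    (?:\s*,\s*(?P<d2>{_NUM}))?               # second df (F only)
    \s*\)\s*
    =\s*
    (?P<stat>[-−–]?\s?(?:\d+\.\d+|\.\d+|\d+))   # printed statistic
    \s*,\s*
    (?:
        \*{{0,2}}p\*{{0,2}}\s*(?P<cmp>[=<>])\s*(?P<p>0?\.\d+)
      | (?P<ns>ns)
    )
    """,
    re.VERBOSE,
)

_CMP_MAP = {"=": PComparator.eq, "<": PComparator.lt, ">": PComparator.gt}

_ONE_TAILED_RE = re.compile(r"one[- ](?:tailed|sided)", re.IGNORECASE)


def _tail_note(text: str, span: tuple[int, int], window: int) -> TailNote:
    lo = max(0, span[0] - window)
    hi = min(len(text), span[1] + window)
    if _ONE_TAILED_RE.search(text[lo:hi]):
        return TailNote.one_tailed_context
    return TailNote.none


def scan_text(doc: RawDocument, *, one_tailed_window: int = 100) -> list[ReportedResult]:
    """Extract every completely reported t/F result from ``doc.text``.

    Unparseable or incomplete fragments are skipped (and logged); the
    returned spans are non-overlapping and ordered.  A keyword window of
    ``one_tailed_window`` characters around each match is searched for
    "one-tailed"/"one-sided" to set ``tail_note``.
    """
    if not doc.text:
        raise ValueError("document text is empty")
    out: list[ReportedResult] = []
    for m in _RESULT_RE.finditer(doc.text):
        family = TestFamily(m.group("fam"))
        d1, d2 = m.group("d1"), m.group("d2")
        if family is TestFamily.F and d2 is None:
            logger.info("skipping F result without two dfs at %s", m.span())
            continue
        if family is TestFamily.t and d2 is not None:
            logger.info("skipping t result with two dfs at %s", m.span())
            continue
        stat_text = m.group("stat").translate(_DASHES).replace(" ", "")
        if m.group("ns") is not None:
            cmp_, p_text = PComparator.gt, ".05"
        else:
            cmp_, p_text = _CMP_MAP[m.group("cmp")], m.group("p")
        try:
            r = ReportedResult(
                test_family=family,
                df1=float(d1) if family is TestFamily.F else None,
                df2=float(d2 if family is TestFamily.F else d1),
                statistic_text=stat_text,
                p_comparator=cmp_,
                p_text=p_text,
                span=m.span(),
                source="auto",
                tail_note=_tail_note(doc.text, m.span(), one_tailed_window),
            )
        except ValueError as exc:
            logger.info("skipping fragment at %s: %s", m.span(), exc)
            continue
        out.append(r)
    return out


def _fmt_df(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


_CMP_SYM = {PComparator.eq: "=", PComparator.lt: "<", PComparator.gt: ">"}


def render_result(r: ReportedResult) -> str:
    """Render a result in canonical APA layout, preserving printed precision.

    ``scan_text`` on the rendered string recovers every field of ``r``
    (modulo span), which the synthetic-corpus generator relies on.
    """
    if r.test_family is TestFamily.F:
        head = f"F({_fmt_df(r.df1)}, {_fmt_df(r.df2)})"
    else:
        head = f"t({_fmt_df(r.df2)})"
    return f"{head} = {r.statistic_text}, p {_CMP_SYM[r.p_comparator]} {r.p_text}"


_MANUAL_COLUMNS = [
    "article_id",
    "test_family",
    "df1",
    "df2",
    "statistic_text",
    "p_comparator",
    "p_text",
]


def read_manual_results(path) -> list[tuple[str, ReportedResult]]:
    """Read a manually entered results table (CSV).

    Manual entry is the route for results not laid out in plain APA style
    (e.g. an effect size printed between the statistic and the p value).
    Returns ``(article_id, result)`` pairs with ``source == "manual"``.
    A malformed row rejects the whole file with its row number and reason.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANUAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manual results file missing columns: {missing}")
    out: list[tuple[str, ReportedResult]] = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, after the header line
        try:
            family = TestFamily(row["test_family"])
            df1 = float(row["df1"]) if row["df1"] not in ("", "NA") else None
            p = float(row["p_text"])
            if not 0.0 < p < 1.0:
                raise ValueError("p out of range")
            r = ReportedResult(
                test_family=family,
                df1=df1 if family is TestFamily.F else None,
                df2=float(row["df2"]),
                statistic_text=row["statistic_text"].translate(_DASHES),
                p_comparator=PComparator(row["p_comparator"]),
                p_text=row["p_text"],
                source="manual",
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"manual results row {rownum}: {exc}") from exc
        out.append((row["article_id"], r))
    return out


def results_to_frame(pairs: Iterable[tuple[str, ReportedResult]]) -> pd.DataFrame:
    """Tidy results table, one row per reported result."""
    rows = []
    for article_id, r in pairs:
        rows.append(
            {
                "article_id": article_id,
                "test_family": r.test_family.value,
                "df1": r.df1,
                "df2": r.df2,
                "statistic_text": r.statistic_text,
                "p_comparator": r.p_comparator.value,
                "p_text": r.p_text,
                "span_start": r.span[0],
                "span_end": r.span[1],
                "source": r.source,
                "tail_note": r.tail_note.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "article_id",
            "test_family",
            "df1",
            "df2",
            "statistic_text",
            "p_comparator",
            "p_text",
            "span_start",
            "span_end",
            "source",
            "tail_note",
        ],
    )
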