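"""Article-level reduction: inclusion rule, per-article medians, group tallies.

Analysis happens at the level of articles because results within an article
are dependent in intractable ways.  Only results *reported as significant*
(the printed p claim lies strictly below .05) enter the article-level
measures; each article contributes its median recomputed p value, its error
counts, and the median of its per-study sample sizes.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .df_check import DfVerdict
from .extraction import RawDocument, ReportedResult
from .recompute import ConsistencyVerdict, reported_p_interval

logger = logging.getLogger(__name__)

__all__ = ["ArticleRecord", "include_result", "summarize_article", "tally_groups", "articles_to_frame"]


@dataclass(frozen=True)
class ArticleRecord:
    article_id: str
    group: str
    journal: str
    n_significant: int
    median_recomputed_p: float
    n_error: int
    n_large: int
    n_gross: int
    n_salvaged: int
    median_sample_size: float | None
    df_flag: bool | None = None  # any t-test df discrepancy; None if unscreenable

    def __post_init__(self) -> None:
        if self.n_error < self.n_large or self.n_error < self.n_gross:
            raise ValueError("large/gross error counts cannot exceed total errors")


def include_result(r: ReportedResult) -> bool:
    """True when the printed p claim lies strictly below .05.

    ``p = .046`` is included (its rounding interval tops out at .0465);
    ``p = .05`` is not (the interval straddles .05); ``p < .05`` is
    included; any ``>`` report is not.
    """
    return reported_p_interval(r.p_comparator, r.p_text).entirely_below(0.05)


def summarize_article(
    doc: RawDocument,
    results: Sequence[tuple[ReportedResult, ConsistencyVerdict]],
    df_flag: bool | None = None,
) -> ArticleRecord | None:
    """Reduce one article's checked results to an :class:`ArticleRecord`.

    Articles with no included (significant) result are dropped, with the
    reason logged, mirroring the corpus inclusion rule.
    """
    included = [(r, v) for r, v in results if include_result(r)]
    if not included:
        logger.info("article %s excluded: no result reported significant", doc.article_id)
        return None
    return ArticleRecord(
        article_id=doc.article_id,
        group=doc.group.value,
        journal=doc.journal,
        n_significant=len(included),
        median_recomputed_p=statistics.median(v.p_recomputed for _, v in included),
        n_error=sum(v.error for _, v in included),
        n_large=sum(v.is_large for _, v in included),
        n_gross=sum(v.is_gross for _, v in included),
        n_salvaged=sum(v.one_tailed_salvage for _, v in included),
        median_sample_size=(
            statistics.median(doc.study_sample_sizes) if doc.study_sample_sizes else None
        ),
        df_flag=df_flag,
    )


def articles_to_frame(articles: Iterable[ArticleRecord]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in articles])


def tally_groups(articles: Sequence[ArticleRecord]) -> pd.DataFrame:
    """Per-group, per-journal tallies of statistics and errors.

    One row per (group, journal) plus a "Total" row per group.  Columns
    cover both the statistic-level counts (number of included results,
    errors, large errors, gross errors) and the article-level counts
    (articles, articles with at least one error / large / gross error),
    with percentage columns alongside.  Totals are checked to equal the
    column sums of the journal rows.
    """
    if not articles:
        raise ValueError("no articles to tally")
    df = articles_to_frame(articles)
    df["has_error"] = df["n_error"] > 0
    df["has_large"] = df["n_large"] > 0
    df["has_gross"] = df["n_gross"] > 0

    def _block(sub: pd.DataFrame) -> dict:
        return {
            "n_articles": len(sub),
            "n_statistics": int(sub["n_significant"].sum()),
            "n_error": int(sub["n_error"].sum()),
            "n_large": int(sub["n_large"].sum()),
            "n_gross": int(sub["n_gross"].sum()),
            "n_articles_error": int(sub["has_error"].sum()),
            "n_articles_large": int(sub["has_large"].sum()),
            "n_articles_gross": int(sub["has_gross"].sum()),
        }

    rows = []
    for group, gsub in df.groupby("group", sort=True):
        for journal, jsub in gsub.groupby("journal", sort=True):
            rows.append({"group": group, "journal": journal, **_block(jsub)})
        rows.append({"group": group, "journal": "Total", **_block(gsub)})
    out = pd.DataFrame(rows)

    count_cols = [c for c in out.columns if c.startswith("n_")]
    for group, gsub in out.groupby("group"):
        journals = gsub[gsub["journal"] != "Total"]
        total = gsub[gsub["journal"] == "Total"]
        if not (journals[count_cols].sum() == total[count_cols].iloc[0]).all():
            raise AssertionError(f"tally totals do not match journal sums for {group}")

    # percentage conventions: one decimal at statistic level, whole at article level
    for c in ("n_error", "n_large", "n_gross"):
        out[f"pct_{c[2:]}"] = (100 * out[c] / out["n_statistics"]).round(1)
    for c in ("n_articles_error", "n_articles_large", "n_articles_gross"):
        out[f"pct_{c[2:]}"] = (100 * out[c] / out["n_articles"]).round(0).astype(int)
    return out
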