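"""End-to-end corpus analysis: scan -> check -> df screen -> article table.

Glue layer over the stage modules.  Takes raw documents plus the metadata
table (study sample sizes and designs), and produces the tidy per-result
table with consistency verdicts and the article-level table that feeds the
group-comparison suite.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .articles import ArticleRecord, articles_to_frame, summarize_article
from .df_check import Design, DesignSpec, DfVerdict, article_discrepancy, screen_t_results
from .extraction import RawDocument, ReportedResult, results_to_frame, scan_text
from .recompute import check_consistency

logger = logging.getLogger(__name__)

__all__ = ["design_specs_for", "analyze_corpus"]


def design_specs_for(doc: RawDocument, designs: Sequence[str] | None = None) -> list[DesignSpec]:
    """Build per-study design specs from a document's metadata.

    ``designs`` parallels ``doc.study_sample_sizes``; missing entries
    default to ``independent_two_sample``.
    """
    specs = []
    for i, n in enumerate(doc.study_sample_sizes):
        design = Design(designs[i]) if designs and i < len(designs) else Design.independent_two_sample
        specs.append(DesignSpec(design=design, n_total=n))
    return specs


def analyze_corpus(
    docs: Sequence[RawDocument],
    designs: Mapping[str, Sequence[str]] | None = None,
    manual_results: Sequence[tuple[str, ReportedResult]] | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full per-article pipeline over a corpus.

    Returns ``(results_df, articles_df)``: one row per reported result with
    its consistency verdict appended, and one row per retained article.
    Articles with no result reported significant are dropped (logged).
    """
    manual_by_id: dict[str, list[ReportedResult]] = {}
    for article_id, r in manual_results or []:
        manual_by_id.setdefault(article_id, []).append(r)

    result_rows: list[tuple[str, ReportedResult]] = []
    verdict_rows: list[dict] = []
    records: list[ArticleRecord] = []
    for doc in docs:
        found = scan_text(doc) + manual_by_id.get(doc.article_id, [])
        checked = [(r, check_consistency(r, strict=strict)) for r in found]
        df_flag = None
        if doc.study_sample_sizes:
            specs = design_specs_for(doc, designs.get(doc.article_id) if designs else None)
            t_verdicts = screen_t_results((r for r, _ in checked), specs)
            df_flag, _ = article_discrepancy(t_verdicts)
        for r, v in checked:
            result_rows.append((doc.article_id, r))
            verdict_rows.append(
                {
                    "p_recomputed": round(v.p_recomputed, 6),
                    "consistent": v.consistent,
                    "one_tailed_salvage": v.one_tailed_salvage,
                    "error_class": v.error_class,
                    "is_large": v.is_large,
                    "is_gross": v.is_gross,
                }
            )
        record = summarize_article(doc, checked, df_flag=df_flag)
        if record is not None:
            records.append(record)

    results_df = pd.concat(
        [results_to_frame(result_rows), pd.DataFrame(verdict_rows)], axis=1
    )
    articles_df = articles_to_frame(records) if records else pd.DataFrame()
    return results_df, articles_df
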