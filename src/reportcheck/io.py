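"""Reading and writing the pipeline's plain-text interchange formats.

* article bodies: one ``<article_id>.txt`` per article;
* metadata CSV: article_id, group, journal, sample_sizes (semicolon-joined
  integers), optional designs (semicolon-joined design names);
* tidy results CSV / article-level CSV: written straight from the pipeline
  DataFrames.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .extraction import Group, RawDocument

__all__ = ["read_metadata", "load_corpus", "write_corpus", "designs_from_metadata"]


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"article_id", "group", "journal", "sample_sizes"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def _parse_sizes(field: str) -> tuple[int, ...]:
    return tuple(int(x) for x in field.split(";")) if field else ()


def designs_from_metadata(meta: pd.DataFrame) -> dict[str, list[str]]:
    if "designs" not in meta.columns:
        return {}
    return {
        row["article_id"]: row["designs"].split(";")
        for _, row in meta.iterrows()
        if row["designs"]
    }


def load_corpus(text_dir, metadata_path) -> tuple[list[RawDocument], pd.DataFrame]:
    """Load article text files named ``<article_id>.txt`` plus metadata."""
    meta = read_metadata(metadata_path)
    text_dir = Path(text_dir)
    docs = []
    for _, row in meta.iterrows():
        path = text_dir / f"{row['article_id']}.txt"
        docs.append(
            RawDocument(
                article_id=row["article_id"],
                text=path.read_text(encoding="utf-8"),
                group=Group(row["group"]),
                journal=row["journal"],
                study_sample_sizes=_parse_sizes(row["sample_sizes"]),
            )
        )
    return docs, meta


def write_corpus(out_dir, docs, metadata: pd.DataFrame, truth=None) -> None:
    """Write article texts, metadata CSV, and (optionally) ground truth."""
    out = Path(out_dir)
    texts = out / "articles"
    texts.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (texts / f"{doc.article_id}.txt").write_text(doc.text, encoding="utf-8")
    metadata.to_csv(out / "metadata.csv", index=False)
    if truth is not None:
        truth.results.to_csv(out / "truth_results.csv", index=False)
        truth.articles.to_csv(out / "truth_articles.csv", index=False)
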