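import numpy as np
import pytest

from reportcheck.extraction import (
    Group,
    PComparator,
    RawDocument,
    ReportedResult,
    TestFamily,
)


@pytest.fixture
def doc_factory():
    def make(text, article_id="a1", group=Group.no_removal, journal="JESP", sizes=()):
        return RawDocument(
            article_id=article_id,
            text=text,
            group=group,
            journal=journal,
            study_sample_sizes=tuple(sizes),
        )

    return make


@pytest.fixture
def worked_example():
    """The canonical APA-style report F(1,23) = 4.45, p = .046."""
    return ReportedResult(
        test_family=TestFamily.F,
        df1=1.0,
        df2=23.0,
        statistic_text="4.45",
        p_comparator=PComparator.eq,
        p_text=".046",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
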