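"""Ground-truth synthetic article corpora.

Generates plain-text articles whose statistical structure matches the kind
of corpus the pipeline analyzes: two article groups, per-article counts of
significant results following a right-skewed count law, mechanistically
generated t/F statistics (effect size and sample size are drawn, the
statistic is drawn from the corresponding noncentral distribution, and the
true p follows) so that statistic, dfs, and p cohere, plus configurable
injection of reporting errors and undisclosed case exclusions.

Because true p values arise from the statistic rather than being sampled
directly, the significant p values come out right-skewed, as in real
corpora.  Every injected perturbation is verified through the consistency
checker before it is written, so the recorded ground-truth class always
matches what the pipeline can recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import recompute
from .df_check import Design, DesignSpec
from .extraction import (
    Group,
    PComparator,
    RawDocument,
    ReportedResult,
    TailNote,
    TestFamily,
    render_result,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate_corpus", "inject_error", "render_article_text"]

# journal tags with per-group article weights (six psychology journals)
_JOURNALS = ("JESP", "CD", "CP", "JADP", "JECP", "JPSP")
_JOURNAL_WEIGHTS = {
    Group.outliers_removed: (21, 6, 15, 12, 18, 20),
    Group.no_removal: (13, 6, 10, 10, 11, 11),
}

_TEMPLATES = (
    "A significant effect of condition emerged, {apa}.",
    "The difference between groups was reliable, {apa}.",
    "Analysis confirmed the predicted effect, {apa}.",
    "The interaction reached significance, {apa}.",
    "Participants in the treatment group scored higher, {apa}.",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """All generator knobs.

    Defaults emulate the corpus conditions the pipeline targets: 92 vs 61
    articles, per-article significant-result counts with medians near 14
    and 12 (zero-truncated negative binomial, means 19.4 / 14.5), per-study
    sample sizes with median near 80, per-result error-injection rates
    around 4% / 1% / 1.1% (small / large / gross), and undisclosed-exclusion
    injection in 41% of articles.
    """

    n_articles: tuple[int, int] = (92, 61)  # (outliers_removed, no_removal)
    results_mean: tuple[float, float] = (19.4, 14.5)
    results_shape: tuple[float, float] = (1.0, 1.8)  # per-group NB dispersion
    effect_d_mean: float = 0.5
    effect_d_sd: float = 0.2
    group_effect: float = 0.0  # added to effect_d_mean for the no_removal group
    sample_size_log_mean: float = math.log(80.0)
    sample_size_log_sd: float = 0.5
    frac_f_tests: float = 0.5
    rate_small: float = 0.040
    rate_large: float = 0.010
    rate_gross: float = 0.011
    # article-level error propensity: gamma multiplier with mean 1 and this
    # variance, shared by all results in an article; keeps the marginal
    # injection rates while making per-article error counts overdispersed
    # (so the downstream negative binomial regression has real work to do)
    error_dispersion: float = 0.8
    exclusion_rate: float = 0.41
    exclusion_deficit_max: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        rates = (self.rate_small, self.rate_large, self.rate_gross, self.exclusion_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("injection rates must lie in [0, 1]")
        if self.rate_small + self.rate_large + self.rate_gross > 1.0:
            raise ValueError("per-result error rates sum above 1")
        if self.error_dispersion < 0:
            raise ValueError("error_dispersion must be non-negative")
        if any(m <= 0 for m in self.results_mean) or any(s <= 0 for s in self.results_shape):
            raise ValueError("results-per-article law must yield positive counts")


@dataclass
class GroundTruth:
    """Per-result and per-article truth for recovery tests."""

    results: pd.DataFrame  # article_id, family, dfs, true stat/p, error_class, printed fields
    articles: pd.DataFrame  # article_id, group, journal, df_deficit, n_results


def _fmt_p(p: float) -> tuple[PComparator, str]:
    if p < 0.0005:
        return PComparator.lt, ".001"
    return PComparator.eq, f"{p:.3f}".lstrip("0")


def _fmt_stat(x: float) -> str:
    return f"{x:.2f}"


def _draw_true_result(
    rng: np.random.Generator, spec: SyntheticSpec, d_mean: float, n: int, significant: bool
) -> tuple[TestFamily, float | None, float, float, float]:
    """Draw (family, df1, df2, statistic, true_p); resamples until the true
    p is on the requested side of .05 (printed at 3 decimals)."""
    for _ in range(1000):
        if significant:
            d = max(0.05, rng.normal(d_mean, spec.effect_d_sd))
        else:
            d = abs(rng.normal(0.0, 0.08))
        if rng.random() < spec.frac_f_tests:
            family = TestFamily.F
            df1 = float(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
            df2 = float(n - df1 - 1)
            nc = n * d * d / 4.0
            stat = float(stats.ncf.rvs(df1, df2, nc, random_state=rng))
            p = float(stats.f.sf(stat, df1, df2))
        else:
            family = TestFamily.t
            df1 = None
            df2 = float(n - 2)
            nc = d * math.sqrt(n) / 2.0
            stat = float(stats.nct.rvs(df2, nc, random_state=rng))
            p = float(2.0 * stats.t.sf(abs(stat), df2))
        if significant and p < 0.0495:
            return family, df1, df2, stat, p
        if not significant and p >= 0.055:
            return family, df1, df2, stat, p
    raise RuntimeError("could not draw a result on the requested side of .05")


def _verify(r: ReportedResult, want: str) -> bool:
    v = recompute.check_consistency(r)
    got = (
        "none"
        if not v.error
        else "gross" if v.is_gross else "large" if v.is_large else "small"
    )
    included = r.p_comparator is not PComparator.gt and v.reported_interval.entirely_below(0.05)
    return got == want and included


def inject_error(
    rng: np.random.Generator,
    family: TestFamily,
    df1: float | None,
    df2: float,
    stat: float,
    true_p: float,
    error_class: str,
) -> ReportedResult:
    """Build a printed result realizing the requested error class.

    ``small``: the reported p is shifted beyond rounding tolerance but by at
    most .01; ``large``: by more than .01 (still reported and recomputed
    significant); ``gross``: the truth is non-significant but the reported p
    is below .05.  The perturbed result is validated through the consistency
    checker; candidate perturbations are resampled until the realized class
    matches.
    """
    stat_text = _fmt_stat(stat)
    if error_class == "none":
        cmp_, p_text = _fmt_p(true_p)
        return ReportedResult(family, df1, df2, stat_text, cmp_, p_text)
    for _ in range(200):
        if error_class == "gross":
            reported = round(float(rng.uniform(0.005, 0.045)), 3)
        elif error_class == "small":
            delta = float(rng.uniform(0.002, 0.009)) * (1 if rng.random() < 0.5 else -1)
            reported = round(true_p + delta, 3)
        elif error_class == "large":
            delta = float(rng.uniform(0.012, 0.038))
            sign = 1 if true_p < 0.012 else (-1 if rng.random() < 0.5 else 1)
            reported = round(true_p + sign * delta, 3)
        else:
            raise ValueError(f"unknown error class {error_class!r}")
        if not 0.001 <= reported <= 0.049:
            continue
        r = ReportedResult(
            family, df1, df2, stat_text, PComparator.eq, f"{reported:.3f}".lstrip("0")
        )
        if _verify(r, error_class):
            return r
    raise RuntimeError(f"could not realize error class {error_class!r} for p={true_p}")


def render_article_text(
    rng: np.random.Generator, results: list[ReportedResult]
) -> tuple[str, list[str]]:
    """Render results into short prose, varying layout to exercise the
    scanner's dialects (canonical, italics markers, tight spacing)."""
    sentences = ["This article reports the results of the studies described below."]
    for r in results:
        apa = render_result(r)
        style = rng.integers(0, 3)
        if style == 1:  # italics markers
            apa = (
                apa.replace(f"{r.test_family.value}(", f"*{r.test_family.value}*(")
                .replace(", p ", ", *p* ")
            )
        elif style == 2:  # tight spacing
            apa = apa.replace(" = ", "=").replace(" < ", "<").replace("(1, ", "(1,")
        tmpl = _TEMPLATES[int(rng.integers(0, len(_TEMPLATES)))]
        sentences.append(tmpl.format(apa=apa))
    return " ".join(sentences), sentences


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[RawDocument], pd.DataFrame, GroundTruth]:
    """Generate a full corpus: documents, metadata table, and ground truth.

    Reproducible given ``spec.seed``.  The metadata table carries the
    study sample sizes and designs the df screen needs; injected exclusion
    deficits are, by construction, *not* disclosed there.
    """
    rng = np.random.default_rng(spec.seed)
    docs: list[RawDocument] = []
    meta_rows = []
    truth_rows = []
    article_rows = []
    aid = 0
    for gi, group in enumerate((Group.outliers_removed, Group.no_removal)):
        weights = np.asarray(_JOURNAL_WEIGHTS[group], dtype=float)
        weights /= weights.sum()
        d_mean = spec.effect_d_mean + (spec.group_effect if group is Group.no_removal else 0.0)
        mean = spec.results_mean[gi]
        r_shape = spec.results_shape[gi]
        nb_p = r_shape / (r_shape + mean)
        for _ in range(spec.n_articles[gi]):
            aid += 1
            article_id = f"a{aid:04d}"
            journal = str(rng.choice(_JOURNALS, p=weights))
            k = 0
            while k == 0:
                k = int(rng.negative_binomial(r_shape, nb_p))
            n_studies = 1 + int(rng.poisson(0.8))
            study_n = [
                int(np.clip(round(rng.lognormal(spec.sample_size_log_mean, spec.sample_size_log_sd)), 20, 500))
                for _ in range(n_studies)
            ]
            deficit = 0
            if rng.random() < spec.exclusion_rate:
                deficit = int(rng.integers(1, spec.exclusion_deficit_max + 1))
            if spec.error_dispersion > 0:
                eps = float(
                    rng.gamma(1.0 / spec.error_dispersion, spec.error_dispersion)
                )
            else:
                eps = 1.0
            base = spec.rate_gross + spec.rate_large + spec.rate_small
            eps = min(eps, 0.9 / base) if base > 0 else eps
            results: list[ReportedResult] = []
            for j in range(k):
                study = int(rng.integers(0, n_studies))
                n = study_n[study]
                u = rng.random()
                if u < eps * spec.rate_gross:
                    cls = "gross"
                elif u < eps * (spec.rate_gross + spec.rate_large):
                    cls = "large"
                elif u < eps * (spec.rate_gross + spec.rate_large + spec.rate_small):
                    cls = "small"
                else:
                    cls = "none"
                # An undisclosed exclusion means the analysis ran on n - deficit
                # cases: the statistic, df, and p all reflect the reduced n,
                # while the metadata still describes n.
                n_eff = max(n - deficit, 8)
                family, df1, df2, stat, true_p = _draw_true_result(
                    rng, spec, d_mean, n_eff, significant=(cls != "gross")
                )
                r = inject_error(rng, family, df1, df2, stat, true_p, cls)
                results.append(r)
                truth_rows.append(
                    {
                        "article_id": article_id,
                        "result_index": j,
                        "study": study,
                        "test_family": family.value,
                        "df1": df1,
                        "df2": df2,
                        "true_statistic": stat,
                        "true_p": true_p,
                        "error_class": cls,
                        "statistic_text": r.statistic_text,
                        "p_comparator": r.p_comparator.value,
                        "p_text": r.p_text,
                    }
                )
            text, _ = render_article_text(rng, results)
            docs.append(
                RawDocument(
                    article_id=article_id,
                    text=text,
                    group=group,
                    journal=journal,
                    study_sample_sizes=tuple(study_n),
                )
            )
            meta_rows.append(
                {
                    "article_id": article_id,
                    "group": group.value,
                    "journal": journal,
                    "sample_sizes": ";".join(str(n) for n in study_n),
                    "designs": ";".join([Design.independent_two_sample.value] * n_studies),
                }
            )
            article_rows.append(
                {
                    "article_id": article_id,
                    "group": group.value,
                    "journal": journal,
                    "df_deficit": deficit,
                    "n_results": k,
                }
            )
    metadata = pd.DataFrame(meta_rows)
    truth = GroundTruth(
        results=pd.DataFrame(truth_rows), articles=pd.DataFrame(article_rows)
    )
    return docs, metadata, truth
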