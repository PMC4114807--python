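"""Article-level group comparison suite.

Compares two groups of articles (outliers removed vs no reported removal)
on their per-article medians and error counts, using:

* the Wilcoxon rank-sum test (exact for small tie-free samples, normal
  approximation with tie correction otherwise);
* a reassignment (permutation) null for the rank-sum statistic W, built by
  randomly re-labelling articles while preserving group sizes;
* negative binomial regressions of per-article error counts on the group
  indicator, controlling for log(number of reported statistics);
* Fisher exact tests on article-level error flags (the registered fallback
  when error counts are too sparse for count regression);
* a Monte-Carlo power simulation for the rank-sum test under a standardized
  mean shift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "WilcoxonResult",
    "PermutationResult",
    "NBRegressionResult",
    "PowerSimSpec",
    "wilcoxon_rank_sum",
    "permutation_null_W",
    "nb_regression",
    "fisher_exact_2x2",
    "wilcoxon_power_sim",
    "compare_groups",
]


@dataclass(frozen=True)
class WilcoxonResult:
    """Rank-sum statistic for the first sample, W = U1 + n1(n1+1)/2."""

    W: float
    p_value: float
    alternative: str
    method: str

    @property
    def p_asymptotic(self) -> float:  # name kept for the asymptotic default
        return self.p_value


@dataclass(frozen=True)
class PermutationResult:
    observed_W: float
    reps: int
    p_empirical: float
    seed: int | None
    alternative: str


@dataclass(frozen=True)
class NBRegressionResult:
    """Coefficients for intercept, group indicator, log(#statistics)."""

    params: tuple[float, float, float]
    bse: tuple[float, float, float]
    p_values: tuple[float, float, float]
    dispersion: float  # NB2 alpha: Var = mu + alpha * mu^2; 0 under Poisson fallback
    converged: bool
    model: str  # "negative_binomial" or "poisson"

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "p": self.p_values,
            },
            index=["intercept", "group", "log_n_statistics"],
        )


@dataclass(frozen=True)
class PowerSimSpec:
    d: float = 0.5
    n_per_group: int = 90
    alpha: float = 0.05
    reps: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.reps < 1000:
            raise ValueError("use at least 1000 replicates")


def _rank_sum_W(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum())


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> WilcoxonResult:
    """Two-sample Wilcoxon rank-sum test with midranks for ties.

    Exact null enumeration when both samples are small and tie-free;
    otherwise the normal approximation with tie correction (and continuity
    correction).  Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples need at least one value")
    W = _rank_sum_W(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return WilcoxonResult(W=W, p_value=1.0, alternative=alternative, method="degenerate")
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return WilcoxonResult(W=W, p_value=float(res.pvalue), alternative=alternative, method=method)


def permutation_null_W(
    x,
    y,
    reps: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    exhaustive: bool = False,
) -> PermutationResult:
    """Empirical null for the rank-sum W by re-assigning articles to groups.

    Group sizes are preserved; each permutation re-labels which articles
    belong to group 1 and records the resulting W.  The empirical p uses the
    add-one convention ``(1 + #extreme) / (reps + 1)`` so it is never zero;
    with ``exhaustive=True`` all ``C(n, n1)`` assignments are enumerated and
    the exact permutation p (no correction) is returned.

    Two-sided extremeness is ``|W - E[W]| >= |W_obs - E[W]|`` with
    ``E[W] = n1 (n + 1) / 2``; one-sided uses the signed comparison.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = n1 + n2
    observed = float(ranks[:n1].sum())
    mean_W = n1 * (n + 1) / 2.0

    def _extreme(null_W: np.ndarray) -> np.ndarray:
        if alternative == "two-sided":
            return np.abs(null_W - mean_W) >= abs(observed - mean_W) - 1e-9
        if alternative == "greater":
            return null_W >= observed - 1e-9
        if alternative == "less":
            return null_W <= observed + 1e-9
        raise ValueError(f"unknown alternative {alternative!r}")

    if exhaustive:
        null_W = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(n), n1)], dtype=float
        )
        p = float(_extreme(null_W).mean())
        return PermutationResult(observed, len(null_W), p, seed, alternative)

    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    chunk = max(1, min(reps, int(2e7) // n))
    while done < reps:
        m = min(chunk, reps - done)
        # random subsets of size n1 via argpartition of uniform keys
        keys = rng.random((m, n))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        null_W = ranks[idx].sum(axis=1)
        count += int(_extreme(null_W).sum())
        done += m
    p = (1 + count) / (reps + 1)
    return PermutationResult(observed, reps, float(p), seed, alternative)


def nb_regression(counts, group, n_stats) -> NBRegressionResult:
    """Negative binomial regression of per-article error counts.

    ``mean = exp(b0 + b1*group + b2*log(n_stats))`` with the NB2 dispersion
    estimated by maximum likelihood.  Falls back to Poisson (dispersion 0)
    with a warning when the NB fit fails to converge or the dispersion
    estimate degenerates.  All-zero counts admit no count regression and
    raise; callers fall back to Fisher exact tests on article-level flags.
    """
    counts = np.asarray(counts, dtype=float)
    group = np.asarray(group, dtype=float)
    n_stats = np.asarray(n_stats, dtype=float)
    if counts.size < 10:
        raise ValueError("need at least 10 articles for count regression")
    if np.any(n_stats < 1):
        raise ValueError("each article needs at least one statistic")
    if counts.sum() == 0:
        raise ValueError("all counts are zero; use fisher_exact_2x2 on article flags")
    X = sm.add_constant(np.column_stack([group, np.log(n_stats)]), has_constant="add")

    def _pack(res, dispersion: float, model: str) -> NBRegressionResult:
        params = res.params[:3]
        return NBRegressionResult(
            params=tuple(float(v) for v in params),
            bse=tuple(float(v) for v in res.bse[:3]),
            p_values=tuple(float(v) for v in res.pvalues[:3]),
            dispersion=dispersion,
            converged=bool(res.mle_retvals.get("converged", True)),
            model=model,
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.NegativeBinomial(counts, X).fit(disp=0, maxiter=200)
        alpha = float(res.params[-1])
        if res.mle_retvals.get("converged", False) and np.isfinite(alpha) and alpha >= 0:
            return _pack(res, alpha, "negative_binomial")
    except Exception:  # noqa: BLE001 - any optimizer failure routes to Poisson
        pass
    warnings.warn("negative binomial fit did not converge; falling back to Poisson")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Poisson(counts, X).fit(disp=0, maxiter=200)
    return _pack(res, 0.0, "poisson")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric rule:
    sum of table probabilities no larger than the observed one).  A zero
    margin gives p = 1."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def wilcoxon_power_sim(spec: PowerSimSpec) -> float:
    """Monte-Carlo power of the two-sided rank-sum test.

    Draws ``n_per_group`` values from N(0, 1) and N(d, 1) per replicate and
    reports the fraction of replicates rejecting at ``alpha``.
    """
    rng = np.random.default_rng(spec.seed)
    rej = 0
    done = 0
    chunk = max(1, min(spec.reps, 20_000))
    while done < spec.reps:
        m = min(chunk, spec.reps - done)
        x = rng.normal(0.0, 1.0, (m, spec.n_per_group))
        y = rng.normal(spec.d, 1.0, (m, spec.n_per_group))
        p = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided").pvalue
        rej += int((p < spec.alpha).sum())
        done += m
    return rej / spec.reps


def compare_groups(
    article_df: pd.DataFrame,
    reps: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> dict:
    """Run the full comparison suite on an article-level table.

    Expects columns article_id, group, journal, n_significant,
    median_recomputed_p, n_error, n_large, n_gross, median_sample_size.
    Group 1 is ``outliers_removed``.  Returns a JSON-serializable report.
    """
    g1 = article_df[article_df["group"] == "outliers_removed"]
    g2 = article_df[article_df["group"] == "no_removal"]
    if g1.empty or g2.empty:
        raise ValueError("both article groups must be present")

    def _wilcoxon_block(col: str) -> dict:
        rows = {}
        for journal in sorted(article_df["journal"].unique()):
            a = g1.loc[g1["journal"] == journal, col].dropna()
            b = g2.loc[g2["journal"] == journal, col].dropna()
            if len(a) and len(b):
                w = wilcoxon_rank_sum(a, b, alternative)
                rows[journal] = {"W": w.W, "p": w.p_value, "n1": len(a), "n2": len(b)}
        a, b = g1[col].dropna(), g2[col].dropna()
        w = wilcoxon_rank_sum(a, b, alternative)
        rows["Total"] = {"W": w.W, "p": w.p_value, "n1": len(a), "n2": len(b)}
        return rows

    report: dict = {
        "seed": seed,
        "alternative": alternative,
        "n_articles": {"outliers_removed": len(g1), "no_removal": len(g2)},
        "wilcoxon_median_p": _wilcoxon_block("median_recomputed_p"),
        "wilcoxon_n_significant": _wilcoxon_block("n_significant"),
        "wilcoxon_median_sample_size": _wilcoxon_block("median_sample_size"),
    }

    perm = permutation_null_W(
        g1["median_recomputed_p"].to_numpy(),
        g2["median_recomputed_p"].to_numpy(),
        reps=reps,
        seed=seed,
        alternative=alternative,
    )
    report["permutation_median_p"] = {
        "observed_W": perm.observed_W,
        "reps": perm.reps,
        "p_empirical": perm.p_empirical,
    }

    group01 = (article_df["group"] == "outliers_removed").astype(int).to_numpy()
    n_stats = article_df["n_significant"].to_numpy()
    report["nb_regressions"] = {}
    report["fisher_exact"] = {}
    for label, col in [("all", "n_error"), ("large", "n_large"), ("gross", "n_gross")]:
        counts = article_df[col].to_numpy()
        try:
            fit = nb_regression(counts, group01, n_stats)
            report["nb_regressions"][label] = {
                "model": fit.model,
                "intercept": fit.params[0],
                "group": fit.params[1],
                "log_n_statistics": fit.params[2],
                "se": list(fit.bse),
                "p": list(fit.p_values),
                "dispersion": fit.dispersion,
            }
        except ValueError:
            report["nb_regressions"][label] = {"model": "none", "reason": "counts too sparse"}
        flags1 = int((g1[col] > 0).sum())
        flags2 = int((g2[col] > 0).sum())
        table = [[flags1, len(g1) - flags1], [flags2, len(g2) - flags2]]
        report["fisher_exact"][label] = {"table": table, "p": fisher_exact_2x2(table)}
    return report
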