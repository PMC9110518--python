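"""Nonparametric comparison of lesion metrics across clinical stages.

The omnibus test is Kruskal-Wallis with the usual tie correction; the
all-pairs post hoc is the Steel-Dwass(-Critchlow-Fligner) procedure: each
pair of groups is compared with a two-sample rank statistic computed on
that pair alone, standardised by its tie-corrected null mean and
variance, and sqrt(2)x the absolute standardised statistic is referred to
the studentized-range distribution with k groups and infinite degrees of
freedom.  A permutation variant of the post hoc is provided for small
samples.

Both tests are two-sided; the conventional significance level is 0.05.
No multiplicity adjustment is applied *across* metrics (each metric is
reported with its own omnibus and post hoc p-values).

Cohort tables are plain pandas DataFrames with at least ``lesion_id``,
``stage`` (in {1, 2, 3}) and the metric columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

VALID_STAGES = (1, 2, 3)
DEFAULT_METRICS = ("rsuv_max", "rsuv_mean", "mbv_cm3", "rtbu")


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis omnibus result.

    ``H`` is the uncorrected rank statistic; ``p`` is the chi-square
    upper-tail probability of the tie-corrected statistic ``H / tie_correction``
    on ``df = k - 1`` degrees of freedom.
    """

    H: float
    df: int
    p: float
    tie_correction: float

    @property
    def H_corrected(self) -> float:
        return self.H / self.tie_correction if self.tie_correction > 0 else 0.0


@dataclass(frozen=True)
class PairwiseResult:
    """One Steel-Dwass pairwise comparison."""

    pair: tuple[int, int]
    t_statistic: float
    p_adjusted: float
    unreliable: bool = False


@dataclass(frozen=True)
class StageSummary:
    """Per-stage n / median / IQR of one metric."""

    metric: str
    stage: int
    n: int
    median: float
    q1: float
    q3: float

    def format(self, fmt: str = "{:.2f}") -> str:
        """Render as ``median [q1-q3]``."""
        return (
            f"{fmt.format(self.median)} "
            f"[{fmt.format(self.q1)}–{fmt.format(self.q3)}]"
        )


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise InputError("need at least 2 groups")
    if any(g.size == 0 for g in out):
        raise InputError("every group must be non-empty")
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Kruskal-Wallis H test with tie correction.

    ``H = 12 / (N (N+1)) * sum n_i (Rbar_i - (N+1)/2)^2`` on midranks;
    the tie correction is ``C = 1 - sum(t^3 - t) / (N^3 - N)`` over tie
    groups, and the p-value is the chi-square upper tail of ``H / C`` with
    ``k - 1`` degrees of freedom.  All-identical data gives ``H = 0, p = 1``.
    """
    gs = _as_groups(groups)
    k = len(gs)
    pooled = np.concatenate(gs)
    n_total = pooled.size
    if n_total < 3:
        raise InputError("need a total of at least 3 observations")
    ranks = sps.rankdata(pooled)
    grand_mean = (n_total + 1) / 2.0
    h = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + g.size]
        start += g.size
        h += g.size * (r.mean() - grand_mean) ** 2
    h *= 12.0 / (n_total * (n_total + 1))

    _, tie_counts = np.unique(pooled, return_counts=True)
    c = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n_total**3 - n_total)
    if c <= 0:  # all values identical
        return KWResult(H=0.0, df=k - 1, p=1.0, tie_correction=0.0)
    p = float(sps.chi2.sf(h / c, k - 1))
    return KWResult(H=float(h), df=k - 1, p=p, tie_correction=c)


def _pair_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised tie-corrected two-sample rank statistic on one pair."""
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    ranks = sps.rankdata(np.concatenate([x, y]))
    r_sum = ranks[:n_x].sum()
    expect = n_x * (n + 1) / 2.0
    var = n_x * n_y / (n * (n - 1.0)) * np.sum((ranks - (n + 1) / 2.0) ** 2)
    if var <= 0:
        return 0.0
    return float((r_sum - expect) / np.sqrt(var))


def steel_dwass(
    groups: Sequence[Sequence[float]],
    method: str = "asymptotic",
    seed: int | None = None,
    n_permutations: int = 10_000,
) -> list[PairwiseResult]:
    """All-pairs Steel-Dwass comparisons.

    Parameters
    ----------
    method
        ``"asymptotic"`` refers sqrt(2)|t| to the studentized range with
        ``k`` groups and infinite df.  ``"permutation"`` estimates each
        adjusted p as the tail fraction of the max-over-pairs statistic
        across draws in which every pair's pooled sample is independently
        re-randomised between its two groups; requires ``seed``.
    """
    gs = _as_groups(groups)
    k = len(gs)
    small = any(g.size < 2 for g in gs)
    if small:
        warnings.warn(
            "Steel-Dwass with a group of size < 2: asymptotic p-values are unreliable",
            stacklevel=2,
        )
    pairs = list(combinations(range(k), 2))
    t_obs = {(i, j): _pair_statistic(gs[i], gs[j]) for i, j in pairs}

    if method == "asymptotic":
        return [
            PairwiseResult(
                pair=(i, j),
                t_statistic=t_obs[(i, j)],
                p_adjusted=float(
                    min(
                        1.0,
                        sps.studentized_range.sf(
                            np.sqrt(2.0) * abs(t_obs[(i, j)]), k, np.inf
                        ),
                    )
                ),
                unreliable=small,
            )
            for i, j in pairs
        ]
    if method != "permutation":
        raise InputError(f"unknown method {method!r}")
    if seed is None:
        raise InputError("the permutation method requires an explicit seed")
    if n_permutations < 10_000:
        raise InputError("use at least 10,000 permutation draws")

    rng = np.random.default_rng(seed)
    # Per pair: permuting values between the two groups is equivalent to
    # permuting the pooled midranks; the null variance is permutation
    # invariant, so each draw only needs a permuted rank sum.
    abs_t = np.empty((n_permutations, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        x, y = gs[i], gs[j]
        n_x = x.size
        n = n_x + y.size
        ranks = sps.rankdata(np.concatenate([x, y]))
        expect = n_x * (n + 1) / 2.0
        var = n_x * y.size / (n * (n - 1.0)) * np.sum((ranks - (n + 1) / 2.0) ** 2)
        if var <= 0:
            abs_t[:, col] = 0.0
            continue
        perms = rng.permuted(
            np.tile(ranks, (n_permutations, 1)), axis=1
        )[:, :n_x].sum(axis=1)
        abs_t[:, col] = np.abs(perms - expect) / np.sqrt(var)
    max_t = abs_t.max(axis=1)
    out = []
    for i, j in pairs:
        t = t_obs[(i, j)]
        p = (1.0 + np.sum(max_t >= abs(t) - 1e-12)) / (n_permutations + 1.0)
        out.append(
            PairwiseResult(
                pair=(i, j),
                t_statistic=t,
                p_adjusted=float(min(1.0, p)),
                unreliable=False,
            )
        )
    return out


def validate_cohort(cohort: pd.DataFrame, require_metrics: Sequence[str] = ()) -> None:
    """Check the minimal cohort-table contract (raises :class:`InputError`)."""
    for col in ("lesion_id", "stage"):
        if col not in cohort.columns:
            raise InputError(f"cohort table missing column {col!r}")
    if cohort["lesion_id"].duplicated().any():
        dup = cohort.loc[cohort["lesion_id"].duplicated(), "lesion_id"].iloc[0]
        raise InputError(f"duplicate lesion id {dup!r}")
    bad = set(cohort["stage"].unique()) - set(VALID_STAGES)
    if bad:
        raise InputError(f"invalid stage values {sorted(bad)}; expected {VALID_STAGES}")
    for m in require_metrics:
        if m not in cohort.columns:
            raise InputError(f"unknown metric {m!r}")


def summarize_by_stage(cohort: pd.DataFrame, metric: str) -> list[StageSummary]:
    """Per-stage n, median and IQR (linear-interpolation quantiles)."""
    validate_cohort(cohort, require_metrics=[metric])
    out = []
    for stage, sub in cohort.groupby("stage"):
        vals = sub[metric].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append(
            StageSummary(
                metric=metric,
                stage=int(stage),
                n=vals.size,
                median=float(med),
                q1=float(q1),
                q3=float(q3),
            )
        )
    return out


@dataclass
class MetricComparison:
    """Everything computed for one metric in the stage report."""

    metric: str
    summaries: list[StageSummary]
    kw: KWResult
    pairwise: list[PairwiseResult]
    significant: bool


def stage_comparison_report(
    cohort: pd.DataFrame,
    metrics: Sequence[str] = DEFAULT_METRICS,
    alpha: float = 0.05,
    posthoc_method: str = "asymptotic",
    seed: int | None = None,
) -> list[MetricComparison]:
    """Omnibus + post hoc comparison of each metric across stages.

    The Steel-Dwass post hoc is always computed and reported as such,
    regardless of the omnibus outcome.
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    validate_cohort(cohort, require_metrics=metrics)
    stages = sorted(cohort["stage"].unique())
    if len(stages) < 2:
        raise InputError("need at least 2 stages present in the cohort")
    report = []
    for metric in metrics:
        groups = [
            cohort.loc[cohort["stage"] == s, metric].to_numpy(dtype=float)
            for s in stages
        ]
        kw = kruskal_wallis(groups)
        pw_idx = steel_dwass(groups, method=posthoc_method, seed=seed)
        pairwise = [
            PairwiseResult(
                pair=(stages[r.pair[0]], stages[r.pair[1]]),
                t_statistic=r.t_statistic,
                p_adjusted=r.p_adjusted,
                unreliable=r.unreliable,
            )
            for r in pw_idx
        ]
        report.append(
            MetricComparison(
                metric=metric,
                summaries=summarize_by_stage(cohort, metric),
                kw=kw,
                pairwise=pairwise,
                significant=kw.p < alpha,
            )
        )
    return report


def report_to_frame(report: list[MetricComparison]) -> pd.DataFrame:
    """Flatten a stage report into a long-format DataFrame."""
    rows = []
    for mc in report:
        for s in mc.summaries:
            rows.append(
                {
                    "metric": mc.metric,
                    "kind": "summary",
                    "stage": s.stage,
                    "pair": "",
                    "n": s.n,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "statistic": np.nan,
                    "p": np.nan,
                    "significant": "",
                }
            )
        rows.append(
            {
                "metric": mc.metric,
                "kind": "kruskal_wallis",
                "stage": np.nan,
                "pair": "",
                "n": sum(s.n for s in mc.summaries),
                "median": np.nan,
                "q1": np.nan,
                "q3": np.nan,
                "statistic": mc.kw.H_corrected,
                "p": mc.kw.p,
                "significant": bool(mc.significant),
            }
        )
        for pr in mc.pairwise:
            rows.append(
                {
                    "metric": mc.metric,
                    "kind": "steel_dwass",
                    "stage": np.nan,
                    "pair": f"{pr.pair[0]}-{pr.pair[1]}",
                    "n": np.nan,
                    "median": np.nan,
                    "q1": np.nan,
                    "q3": np.nan,
                    "statistic": pr.t_statistic,
                    "p": pr.p_adjusted,
                    "significant": "",
                }
            )
    return pd.DataFrame(rows)


def report_to_markdown(report: list[MetricComparison], alpha: float = 0.05) -> str:
    """Human-readable Markdown rendering of the stage report."""
    lines = []
    for mc in report:
        lines.append(f"## {mc.metric}")
        lines.append("")
        lines.append("| stage | n | median [IQR] |")
        lines.append("| --- | --- | --- |")
        for s in mc.summaries:
            lines.append(f"| {s.stage} | {s.n} | {s.format()} |")
        flag = "significant" if mc.significant else "not significant"
        lines.append("")
        lines.append(
            f"Kruskal-Wallis: H = {mc.kw.H_corrected:.3f}, "
            f"df = {mc.kw.df}, p = {mc.kw.p:.4f} ({flag} at alpha = {alpha})"
        )
        lines.append("")
        lines.append("| pair | t | adjusted p (post hoc) |")
        lines.append("| --- | --- | --- |")
        for pr in mc.pairwise:
            note = " (unreliable: small group)" if pr.unreliable else ""
            lines.append(
                f"| {pr.pair[0]} vs {pr.pair[1]} | {pr.t_statistic:.3f} | "
                f"{pr.p_adjusted:.4f}{note} |"
            )
        lines.append("")
    return "\n".join(lines)


def cohort_long_format(
    cohort: pd.DataFrame, metrics: Sequence[str] = DEFAULT_METRICS
) -> pd.DataFrame:
    """Boxplot-ready long table: one row per (lesion, metric)."""
    validate_cohort(cohort, require_metrics=metrics)
    return cohort.melt(
        id_vars=["stage"],
        value_vars=list(metrics),
        var_name="metric",
        value_name="value",
    )
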