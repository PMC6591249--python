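"""Effect-size estimation and the nonparametric testing battery.

The headline quantity is the percent increase of background-corrected mean
voxel intensity of an intron-bearing strain over its intronless control,
with a 95% percentile-bootstrap confidence interval.  Group comparisons use
the Mann-Whitney rank-sum test, Kruskal-Wallis followed by Dunn's
vs-control comparisons, and fixed-effects two-way ANOVA with Holm-Sidak
step-down adjustment — the battery appropriate for skewed, positive
expression data pooled across experiments.

Background correction is a two-step subtraction: the per-pixel dark-current
map removes camera signal, and the wild-type population mean removes tissue
autofluorescence, which is channel-dependent (markedly stronger under GFP
optics than mCherry optics).  Percent effects are only meaningful after
both; the estimator is scale-invariant but deliberately not
shift-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .quantify import CohortMeasurements

__all__ = [
    "EffectSizeResult",
    "TestResult",
    "autofluorescence_baseline",
    "background_correct",
    "effect_size",
    "mann_whitney_test",
    "kruskal_wallis_test",
    "dunn_vs_control",
    "two_way_anova",
    "holm_sidak_adjust",
]


@dataclass(frozen=True)
class EffectSizeResult:
    """Percent increase of the test group mean over the control mean."""

    percent_increase: float
    ci_low: float
    ci_high: float
    n_control: int
    n_test: int
    control_label: str = "control"
    test_label: str = "test"


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome (statistic, two-sided p, adjustment)."""

    statistic_name: str
    statistic_value: float
    p_value: float
    adjusted: bool = False
    method_label: str = ""


def autofluorescence_baseline(wildtype_cohort: CohortMeasurements) -> float:
    """Population-mean autofluorescence of a wild-type cohort, in ADU.

    The arithmetic mean of wild-type per-animal mean voxel intensities for
    one channel; subtracted from every transgenic cohort measured under the
    same optics.
    """
    if len(wildtype_cohort) == 0:
        raise ValueError("wild-type cohort is empty")
    channels = {a.channel for a in wildtype_cohort.animals}
    if len(channels) != 1:
        raise ValueError(f"wild-type cohort mixes channels: {sorted(channels)}")
    return float(wildtype_cohort.values.mean())


def background_correct(
    cohort: CohortMeasurements, baseline: float, baseline_channel: str | None = None
) -> np.ndarray:
    """Subtract the autofluorescence baseline from each animal's intensity.

    Negative corrected values are preserved; they signal animals below the
    wild-type mean, not errors.
    """
    if not np.isfinite(baseline):
        raise ValueError("baseline must be finite")
    if baseline_channel is not None and baseline_channel != cohort.channel:
        raise ValueError(
            f"baseline channel {baseline_channel!r} != cohort channel {cohort.channel!r}"
        )
    return cohort.values - baseline


def effect_size(
    control: Sequence[float],
    test: Sequence[float],
    n_boot: int = 5000,
    seed: int = 0,
    conf_level: float = 0.95,
    control_label: str = "control",
    test_label: str = "test",
) -> EffectSizeResult:
    """Percent increase of mean(test) over mean(control), with bootstrap CI.

    The point estimate is ``100 * (mean(test) - mean(control)) / mean(control)``;
    the CI is a nonparametric percentile bootstrap resampling animals within
    each group independently.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(test, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 animals")
    if a.mean() <= 0:
        raise ValueError(
            "control mean is non-positive; background correction failed or "
            "the cohort is degenerate"
        )
    point = 100.0 * (b.mean() - a.mean()) / a.mean()
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    mean_a = a[idx_a].mean(axis=1)
    mean_b = b[idx_b].mean(axis=1)
    ok = mean_a > 0
    boots = 100.0 * (mean_b[ok] - mean_a[ok]) / mean_a[ok]
    alpha = 1.0 - conf_level
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return EffectSizeResult(
        percent_increase=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_control=int(a.size),
        n_test=int(b.size),
        control_label=control_label,
        test_label=test_label,
    )


def mann_whitney_test(
    a: Sequence[float], b: Sequence[float], mode: str = "approx"
) -> TestResult:
    """Two-sided Mann-Whitney rank-sum test.

    ``exact`` enumerates the permutation distribution of U (no ties, small
    samples only); ``approx`` uses the normal approximation with tie
    correction and 0.5 continuity correction.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if mode == "exact":
        pooled = np.concatenate([x, y])
        if np.unique(pooled).size != pooled.size:
            raise ValueError("exact mode requires tie-free data")
        if pooled.size > 20:
            raise ValueError("exact mode is limited to n_a + n_b <= 20")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        label = "Mann-Whitney (exact)"
    elif mode == "approx":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        label = "Mann-Whitney (normal approximation, tie-corrected)"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(
        statistic_name="U",
        statistic_value=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        adjusted=False,
        method_label=label,
    )


def kruskal_wallis_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    An all-constant input (every pooled value identical) returns the
    limiting convention H = 0, p = 1 instead of the 0/0 tie correction.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return TestResult("H", 0.0, 1.0, False, "Kruskal-Wallis (degenerate: all tied)")
    h, p = sps.kruskal(*arrays)
    return TestResult("H", float(h), float(p), False, "Kruskal-Wallis")


def dunn_vs_control(
    groups: Sequence[Sequence[float]], control_index: int = 0, alpha: float = 0.05
) -> list[TestResult]:
    """Dunn's post hoc rank comparisons of each group against a control.

    All groups are ranked jointly (midranks); each non-control group i gets

        z_i = (meanrank_i - meanrank_control) /
              sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_control))

    with tie term ``T = sum(t^3 - t)`` over tie groups.  Two-sided p-values
    are Bonferroni-adjusted for the k-1 vs-control comparisons and capped at
    1.  Results are ordered as the non-control groups are.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    if not 0 <= control_index < len(groups):
        raise ValueError(f"control_index {control_index} out of range")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))

    mean_ranks = []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size

    variance_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_comparisons = len(groups) - 1
    results = []
    for i, g in enumerate(arrays):
        if i == control_index:
            continue
        se = np.sqrt(
            variance_core * (1.0 / g.size + 1.0 / arrays[control_index].size)
        )
        if se == 0:  # every pooled value tied
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[control_index]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        results.append(
            TestResult(
                statistic_name="z",
                statistic_value=float(z),
                p_value=float(min(1.0, p * n_comparisons)),
                adjusted=True,
                method_label=f"Dunn vs control (Bonferroni x{n_comparisons})",
            )
        )
    return results


def two_way_anova(
    values: Sequence[float], factor_a: Sequence[str], factor_b: Sequence[str]
) -> dict[str, TestResult]:
    """Fixed-effects two-way ANOVA with interaction.

    Sums of squares follow the hierarchical (Type II) convention, which
    reduces to the classical decomposition on balanced data.  Returns one
    :class:`TestResult` per term under keys ``"A"``, ``"B"`` and ``"A:B"``.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a, dtype=object)
    fb = np.asarray(factor_b, dtype=object)
    if not y.size == fa.size == fb.size:
        raise ValueError("values and factor labels must have equal length")
    if len(set(fa)) < 2 or len(set(fb)) < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = pd.crosstab(pd.Series(fa), pd.Series(fb))
    if (cells.values == 0).any():
        raise ValueError("every factor-level cell must be nonempty")
    if y.size <= cells.size:
        raise ValueError("no residual degrees of freedom (need replicates)")
    data = pd.DataFrame({"y": y, "a": fa.astype(str), "b": fb.astype(str)})
    model = smf.ols("y ~ C(a) * C(b)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    key_map = {"C(a)": "A", "C(b)": "B", "C(a):C(b)": "A:B"}
    out: dict[str, TestResult] = {}
    for row_name, term in key_map.items():
        row = table.loc[row_name]
        out[term] = TestResult(
            statistic_name="F",
            statistic_value=float(row["F"]),
            p_value=float(row["PR(>F)"]),
            adjusted=False,
            method_label=f"Two-way ANOVA (Type II), term {term}",
        )
    return out


def holm_sidak_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down multiple-comparison adjustment.

    Sorted ascending, step i (1-based, m tests) rejects while
    ``p_(i) <= 1 - (1 - alpha)^(1/(m - i + 1))``; the first failure stops
    the procedure.  Adjusted p-values are
    ``max_{j <= i} min(1, 1 - (1 - p_(j))^(m - j + 1))``, reported in the
    original order.  Returns ``(reject, p_adjusted)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    exponents = m - np.arange(m)  # m, m-1, ..., 1
    adj_sorted = np.minimum(1.0, 1.0 - (1.0 - p_sorted) ** exponents)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    thresholds = 1.0 - (1.0 - alpha) ** (1.0 / exponents)
    passed = p_sorted <= thresholds
    cutoff = int(np.argmin(passed)) if not passed.all() else m
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:cutoff] = True
    reject = np.empty(m, dtype=bool)
    p_adj = np.empty(m, dtype=float)
    reject[order] = reject_sorted
    p_adj[order] = adj_sorted
    return reject, p_adj


def effect_table(results: Sequence[EffectSizeResult]) -> pd.DataFrame:
    """Tabulate effect-size results (one row per control/test comparison)."""
    return pd.DataFrame(
        [
            {
                "control_label": r.control_label,
                "test_label": r.test_label,
                "percent_increase": r.percent_increase,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_control": r.n_control,
                "n_test": r.n_test,
            }
            for r in results
        ]
    )
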