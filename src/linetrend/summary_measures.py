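"""Summary-measure analysis (SMA) of linear-trend repeated measures.

Each subject's response vector is reduced to two scalars -- the ordinary
least-squares slope of response on time (rate of change) and the mean of
the responses over time (level) -- and standard univariate tests are then
applied to the summaries:

* **time effect**: one-sample t of the pooled slopes against zero (under no
  time effect the population mean slope is zero);
* **group x time interaction**: k-sample comparison of the slopes between
  groups (Student's t for k = 2, one-way ANOVA F for k > 2, or the
  rank/permutation variants);
* **group effect**: the same k-sample machinery applied to the subject means.

Slopes and means tolerate unbalanced data and subject-specific time grids,
which is what makes this approach applicable when the multivariate route
is infeasible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import RepeatedMeasuresDataset
from .exceptions import (
    ConfigurationError,
    DegenerateTestError,
    UndefinedSummaryError,
)

logger = logging.getLogger(__name__)

VARIANTS = ("t", "anova", "wilcoxon", "kruskal", "permutation")


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject summary measures.

    ``slope`` is NaN when the subject has fewer than two distinct time
    values (flagged, not dropped); ``mean`` is defined for any n_points >= 1.
    """

    subject_id: object
    group: object
    slope: float
    mean: float
    n_points: int

    @property
    def slope_defined(self) -> bool:
        return not np.isnan(self.slope)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``df_den`` is None for tests without a denominator df (rank tests).
    """

    effect: str  # time | group | interaction
    method: str
    statistic_name: str
    statistic: float
    df_num: float | None
    df_den: float | None
    p_value: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def reject(self) -> bool:
        return self.p_value <= self.alpha


def subject_slope(times, responses) -> float:
    """OLS slope sum((t-tbar)(y-ybar)) / sum((t-tbar)^2) for one subject."""
    t = np.asarray(times, float)
    y = np.asarray(responses, float)
    if t.shape != y.shape:
        raise ValueError("times and responses must have equal length")
    if np.unique(t).size < 2:
        raise UndefinedSummaryError(
            "slope requires at least 2 distinct time values"
        )
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def subject_mean(responses) -> float:
    """Arithmetic mean of a subject's responses."""
    y = np.asarray(responses, float)
    if y.size == 0:
        raise UndefinedSummaryError("mean requires at least one response")
    return float(y.mean())


def summarize(ds: RepeatedMeasuresDataset) -> list[SubjectSummary]:
    """One :class:`SubjectSummary` per subject, in order of appearance.

    Subjects with < 2 distinct times get ``slope = NaN`` and a warning;
    they are excluded later from slope-based tests but keep their mean.
    """
    out = []
    for subj, grp, t, y in ds.subject_records():
        if np.unique(t).size >= 2:
            slope = subject_slope(t, y)
        else:
            slope = float("nan")
            logger.warning(
                "subject %r has < 2 distinct times; slope undefined", subj
            )
        out.append(
            SubjectSummary(
                subject_id=subj,
                group=grp,
                slope=slope,
                mean=subject_mean(y),
                n_points=len(y),
            )
        )
    return out


def _grouped(values: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    return [values[labels == g] for g in np.unique(labels)]


def test_time(summaries, alpha: float = 0.05) -> TestResult:
    """One-sample t of the pooled per-subject slopes against zero."""
    slopes = np.array([s.slope for s in summaries if s.slope_defined])
    if slopes.size < 2:
        raise DegenerateTestError("time test needs >= 2 defined slopes")
    if np.ptp(slopes) == 0.0:
        raise DegenerateTestError("slopes have zero variance")
    stat, p = stats.ttest_1samp(slopes, 0.0)
    return TestResult(
        effect="time",
        method="sma",
        statistic_name="t",
        statistic=float(stat),
        df_num=1,
        df_den=float(slopes.size - 1),
        p_value=float(p),
        alpha=alpha,
    )


def _k_sample_test(
    values: np.ndarray,
    labels: np.ndarray,
    effect: str,
    variant: str,
    alpha: float,
    perm_reps: int,
    seed,
) -> TestResult:
    """Shared engine for the interaction (slopes) and group (means) tests."""
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}; use {VARIANTS}")
    groups = _grouped(values, labels)
    k = len(groups)
    if k < 2:
        raise ConfigurationError(f"{effect} test requires k >= 2 groups")
    n_tot = values.size

    if variant in ("t", "anova", "permutation"):
        within_ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
        if within_ss == 0.0 and np.ptp(values) == 0.0:
            raise DegenerateTestError("summaries have zero variance in all groups")

    if variant == "t":
        if k != 2:
            raise ConfigurationError("t variant requires exactly 2 groups")
        if min(len(g) for g in groups) < 2:
            raise DegenerateTestError("each group needs >= 2 summaries")
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
        return TestResult(effect, "sma", "t", float(stat), 1,
                          float(n_tot - 2), float(p), alpha)
    if variant == "anova":
        stat, p = stats.f_oneway(*groups)
        return TestResult(effect, "sma", "F", float(stat), float(k - 1),
                          float(n_tot - k), float(p), alpha)
    if variant == "wilcoxon":
        if k != 2:
            raise ConfigurationError("wilcoxon variant requires exactly 2 groups")
        # midranks + normal approximation, no continuity correction
        res = stats.mannwhitneyu(
            groups[0], groups[1], alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
        return TestResult(effect, "sma", "U", float(res.statistic), None, None,
                          float(res.pvalue), alpha)
    if variant == "kruskal":
        stat, p = stats.kruskal(*groups)
        return TestResult(effect, "sma", "H", float(stat), float(k - 1), None,
                          float(p), alpha)

    # permutation: permute group labels, statistic = parametric statistic
    obs = _parametric_stat(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(perm_reps):
        perm = rng.permutation(values)
        split = np.split(perm, np.cumsum([len(g) for g in groups])[:-1])
        if abs(_parametric_stat(split)) >= abs(obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + perm_reps)
    name = "t_perm" if k == 2 else "F_perm"
    return TestResult(effect, "sma", name, float(obs), None, None,
                      float(p), alpha)


def _parametric_stat(groups: list[np.ndarray]) -> float:
    """Pooled two-sample t (k=2) or one-way F (k>2) without p-value."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k == 2:
        n1, n2 = len(groups[0]), len(groups[1])
        sp2 = (
            ((groups[0] - groups[0].mean()) ** 2).sum()
            + ((groups[1] - groups[1].mean()) ** 2).sum()
        ) / (n - 2)
        if sp2 == 0.0:
            return 0.0
        return (groups[0].mean() - groups[1].mean()) / np.sqrt(
            sp2 * (1 / n1 + 1 / n2)
        )
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        return 0.0 if ssb == 0.0 else np.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def test_interaction(
    summaries,
    variant: str = "t",
    alpha: float = 0.05,
    perm_reps: int = 9999,
    seed=None,
) -> TestResult:
    """k-sample comparison of per-subject slopes between groups.

    Equality of the group slope distributions is the summary-measure
    translation of 'no group x time interaction'.
    """
    defined = [s for s in summaries if s.slope_defined]
    n_undef = len(summaries) - len(defined)
    if n_undef:
        logger.warning("%d subject(s) with undefined slope excluded", n_undef)
    values = np.array([s.slope for s in defined])
    labels = np.array([s.group for s in defined])
    return _k_sample_test(values, labels, "interaction", variant, alpha,
                          perm_reps, seed)


def test_group(
    summaries,
    variant: str = "t",
    alpha: float = 0.05,
    perm_reps: int = 9999,
    seed=None,
) -> TestResult:
    """k-sample comparison of per-subject means between groups."""
    values = np.array([s.mean for s in summaries])
    labels = np.array([s.group for s in summaries])
    return _k_sample_test(values, labels, "group", variant, alpha,
                          perm_reps, seed)
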