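"""Unstructured multivariate analysis (UMA) / profile analysis.

The m repeated measurements are treated as a multivariate response with an
arbitrary common covariance matrix.  Testing works on contrast-transformed
responses ``d_i = C y_i`` where C is any full-rank (m-1) x m matrix whose
rows sum to zero (the adjacent-difference matrix by default; the statistics
are invariant to the choice):

* **parallelism** (group x time interaction): one-way MANOVA on the m-1
  transformed variables, Wilks' lambda = det(E)/det(E+H) converted to an F
  via Rao's approximation (exact for k = 2, where it coincides with the
  two-sample Hotelling T^2);
* **time effect**: one-sample Hotelling T^2 testing that the mean of the
  adjacent differences, pooled over groups, is the zero vector;
* **group effect**: delegated to the summary-measure test on subject means,
  which is typically more efficient than the MANOVA contrast of levels.

Feasibility requires more subjects than transformed variables
(N - k > m - 1 for parallelism, N >= m for the time test); with many time
points and few subjects the approach simply cannot be run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import RepeatedMeasuresDataset, WideMatrix, to_wide
from .exceptions import ConfigurationError, FeasibilityError, NumericalError
from .summary_measures import TestResult, summarize, test_group


@dataclass(frozen=True)
class ContrastMatrix:
    """(m-1) x m transformation matrix with zero row sums and rank m-1."""

    m: int
    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, float)
        if rows.shape != (self.m - 1, self.m):
            raise ConfigurationError("contrast matrix must be (m-1) x m")
        if not np.allclose(rows.sum(axis=1), 0.0):
            raise ConfigurationError("contrast rows must sum to zero")
        if np.linalg.matrix_rank(rows) != self.m - 1:
            raise ConfigurationError("contrast matrix must have rank m-1")
        object.__setattr__(self, "rows", rows)


def adjacent_contrast(m: int) -> ContrastMatrix:
    """Differences between adjacent measurements: row j = e_{j+1} - e_j."""
    if m < 2:
        raise ConfigurationError("adjacent contrast requires m >= 2")
    rows = np.zeros((m - 1, m))
    idx = np.arange(m - 1)
    rows[idx, idx] = -1.0
    rows[idx, idx + 1] = 1.0
    return ContrastMatrix(m=m, rows=rows)


def _transform(wide: WideMatrix, contrast: ContrastMatrix | None) -> np.ndarray:
    m = wide.n_times
    if contrast is None:
        contrast = adjacent_contrast(m)
    elif contrast.m != m:
        raise ConfigurationError(
            f"contrast is for m={contrast.m}, data have m={m}"
        )
    return wide.values @ contrast.rows.T  # (N, m-1)


def wilks_lambda_f(lam: float, p: int, q: int, v_error: int):
    """Rao's F approximation for Wilks' lambda.

    Parameters: p variables, q hypothesis df, v_error error df.  Exact when
    min(p, q) <= 2.  Returns ``(F, df1, df2)``.
    """
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    else:
        t = 1.0
    w = v_error + q - (p + q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    return f, df1, df2


def test_parallelism(
    wide: WideMatrix,
    contrast: ContrastMatrix | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """Wilks' lambda test that the k group mean profiles are parallel."""
    d = _transform(wide, contrast)
    labels = wide.groups
    levels = np.unique(labels)
    k = levels.size
    if k < 2:
        raise ConfigurationError("parallelism test requires k >= 2 groups")
    n_subj, p = d.shape
    if n_subj - k <= p:
        raise FeasibilityError(
            f"N - k = {n_subj - k} must exceed m - 1 = {p} for the MANOVA "
            "test (pooled covariance of the transformed responses singular)"
        )
    grand = d.mean(axis=0)
    e = np.zeros((p, p))
    h = np.zeros((p, p))
    for g in levels:
        dg = d[labels == g]
        cg = dg - dg.mean(axis=0)
        e += cg.T @ cg
        diff = dg.mean(axis=0) - grand
        h += len(dg) * np.outer(diff, diff)
    sign_e, logdet_e = np.linalg.slogdet(e)
    sign_t, logdet_t = np.linalg.slogdet(e + h)
    if sign_e <= 0:
        raise NumericalError("singular within-group SSCP matrix E")
    lam = float(np.exp(logdet_e - logdet_t))
    f, df1, df2 = wilks_lambda_f(lam, p, k - 1, n_subj - k)
    pval = float(stats.f.sf(f, df1, df2))
    return TestResult(
        effect="interaction",
        method="uma",
        statistic_name="wilks_lambda_F",
        statistic=float(f),
        df_num=float(df1),
        df_den=float(df2),
        p_value=pval,
        alpha=alpha,
    )


def test_time_hotelling(
    wide: WideMatrix,
    contrast: ContrastMatrix | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """One-sample Hotelling T^2 that the pooled mean adjacent difference is 0.

    T^2 = N dbar' S^{-1} dbar with S the (N-1)-divisor sample covariance of
    the differences; F = (N - m + 1) / ((N - 1)(m - 1)) * T^2 on
    (m - 1, N - m + 1) df.
    """
    d = _transform(wide, contrast)
    n_subj, p = d.shape
    if n_subj < p + 1:
        raise FeasibilityError(
            f"one-sample Hotelling test needs N >= m (N={n_subj}, m={p + 1})"
        )
    dbar = d.mean(axis=0)
    s = np.cov(d, rowvar=False, ddof=1).reshape(p, p)
    try:
        sol = np.linalg.solve(s, dbar)
        t2 = float(n_subj * dbar @ sol)
    except np.linalg.LinAlgError as err:
        if np.allclose(dbar, 0.0):
            t2 = 0.0  # e.g. exactly constant profiles: d == 0 for everyone
        else:
            raise NumericalError(f"singular covariance of differences: {err}")
    df1, df2 = p, n_subj - p
    f = (df2 / (p * (n_subj - 1))) * t2
    pval = float(stats.f.sf(f, df1, df2))
    return TestResult(
        effect="time",
        method="uma",
        statistic_name="hotelling_T2_F",
        statistic=float(f),
        df_num=float(df1),
        df_den=float(df2),
        p_value=pval,
        alpha=alpha,
    )


def test_group_uma(ds: RepeatedMeasuresDataset, alpha: float = 0.05,
                   variant: str | None = None) -> TestResult:
    """Group test via subject means -- identical to the SMA group test."""
    if variant is None:
        variant = "t" if ds.n_groups == 2 else "anova"
    return test_group(summarize(ds), variant=variant, alpha=alpha)


def analyze_uma(ds: RepeatedMeasuresDataset, alpha: float = 0.05) -> dict:
    """All three UMA tests on one dataset; returns {effect: TestResult}."""
    wide = to_wide(ds)
    return {
        "time": test_time_hotelling(wide, alpha=alpha),
        "interaction": test_parallelism(wide, alpha=alpha),
        "group": test_group_uma(ds, alpha=alpha),
    }
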