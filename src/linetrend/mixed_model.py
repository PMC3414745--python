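"""REML linear mixed models with selectable within-subject error covariance.

The model for subject i with m_i measurements is

    y_i = X_i beta + Z_i b_i + e_i,      b_i ~ N(0, G),  e_i ~ N(0, R_i)

with fixed effects ``intercept + group + time + group:time`` (group as k-1
reference-coded indicators, time as the numeric time value), random effects
either the intercept alone or intercept + time slope (G unstructured), and
error covariance R_i one of

* ``ind``  -- sigma^2 I  (with a random intercept this implies a
  compound-symmetry marginal covariance);
* ``ar1``  -- sigma^2 H, h_jj' = rho^|j-j'| over measurement positions;
* ``uns``  -- a free m x m SPD matrix indexed by position on the shared
  time grid (balanced complete data required).

Estimation maximises the restricted likelihood over the variance parameters
with beta profiled out by GLS; the parameterisation is unconstrained
(log standard deviations, Fisher-z for rho, log-Cholesky factors for G and
the unstructured R), optimised by L-BFGS-B with numerical gradients.
Per-term hypothesis tests are Wald F statistics (sequential by default,
marginal/type-III on request) with inner-outer denominator degrees of
freedom: between-subject terms (intercept, group)
are tested against N - p_between, within-subject terms (time, group:time)
against N_obs - N - p_within, where p_between / p_within count the fixed
columns constant / varying within subject.  The same rule is used by the
classical multilevel software this module is designed to agree with, and
results depend on it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .data_model import RepeatedMeasuresDataset
from .exceptions import ConfigurationError, FeasibilityError, NumericalError
from .summary_measures import TestResult

logger = logging.getLogger(__name__)

RANDOM_STRUCTURES = ("intercept", "intercept-slope")
ERROR_STRUCTURES = ("ind", "ar1", "uns")

_LOG2PI = np.log(2.0 * np.pi)
_PARAM_BOUND = 12.0  # |unconstrained parameter| cap, guards overflow


@dataclass(frozen=True)
class LMMSpec:
    """Model specification: which random effects and which error structure."""

    random: str = "intercept"
    structure: str = "ind"

    def __post_init__(self) -> None:
        if self.random not in RANDOM_STRUCTURES:
            raise ConfigurationError(
                f"random must be one of {RANDOM_STRUCTURES}, got {self.random!r}"
            )
        if self.structure not in ERROR_STRUCTURES:
            raise ConfigurationError(
                f"structure must be one of {ERROR_STRUCTURES}, "
                f"got {self.structure!r}"
            )

    @property
    def q(self) -> int:
        return 1 if self.random == "intercept" else 2


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated covariance parameters on the natural scale."""

    g_matrix: np.ndarray  # q x q random-effects covariance
    structure: str
    sigma2: float | None = None  # ind / ar1 error variance
    rho: float | None = None  # ar1 autocorrelation
    r_matrix: np.ndarray | None = None  # uns error covariance (m x m)

    @property
    def n_free(self) -> int:
        q = self.g_matrix.shape[0]
        n_g = q * (q + 1) // 2
        if self.structure == "ind":
            return n_g + 1
        if self.structure == "ar1":
            return n_g + 2
        m = self.r_matrix.shape[0]
        return n_g + m * (m + 1) // 2


@dataclass
class _Pattern:
    """Subjects sharing one observation-time pattern (vectorised together)."""

    times: np.ndarray  # (m_p,)
    grid_idx: np.ndarray  # positions on the shared grid (uns indexing)
    y: np.ndarray  # (n_s, m_p)
    x: np.ndarray  # (n_s, m_p, p)
    subjects: list


@dataclass
class DesignData:
    """Per-subject design matrices grouped by time pattern."""

    patterns: list[_Pattern]
    fixed_names: list[str]
    term_columns: dict[str, list[int]]  # term -> column indices
    between_terms: tuple[str, ...]
    within_terms: tuple[str, ...]
    n_subjects: int
    n_obs: int
    time_grid: np.ndarray
    spec: LMMSpec

    @property
    def p(self) -> int:
        return len(self.fixed_names)

    def z_for(self, times: np.ndarray) -> np.ndarray:
        if self.spec.q == 1:
            return np.ones((times.size, 1))
        return np.column_stack([np.ones(times.size), times])


def build_design(ds: RepeatedMeasuresDataset, spec: LMMSpec) -> DesignData:
    """Assemble X_i / Z_i / y_i for every subject.

    Fixed-effect columns: intercept, k-1 group indicators (lexicographic
    reference coding), time, and the group-indicator x time interactions.
    """
    groups = ds.groups
    k = len(groups)
    nonref = groups[1:]
    fixed_names = (
        ["intercept"]
        + [f"group[{g}]" for g in nonref]
        + ["time"]
        + [f"group[{g}]:time" for g in nonref]
    )
    term_columns = {
        "intercept": [0],
        "group": list(range(1, k)),
        "time": [k],
        "group:time": list(range(k + 1, 2 * k)),
    }
    grid = ds.time_grid
    pos = {t: j for j, t in enumerate(grid)}
    buckets: dict[tuple, dict] = {}
    n_obs = 0
    for subj, grp, t, y in ds.subject_records():
        key = tuple(t)
        b = buckets.setdefault(key, {"y": [], "x": [], "subjects": []})
        ind = np.array([1.0 if grp == g else 0.0 for g in nonref])
        x = np.column_stack(
            [np.ones_like(t)]
            + [np.full_like(t, v) for v in ind]
            + [t]
            + [t * v for v in ind]
        )
        b["y"].append(y)
        b["x"].append(x)
        b["subjects"].append(subj)
        n_obs += t.size
    patterns = []
    for key, b in buckets.items():
        times = np.array(key)
        patterns.append(
            _Pattern(
                times=times,
                grid_idx=np.array([pos[t] for t in times]),
                y=np.array(b["y"]),
                x=np.array(b["x"]),
                subjects=b["subjects"],
            )
        )
    if spec.structure == "uns" and any(
        p.times.size != grid.size for p in patterns
    ):
        raise FeasibilityError(
            "uns error structure requires every subject on the shared time grid"
        )
    return DesignData(
        patterns=patterns,
        fixed_names=fixed_names,
        term_columns=term_columns,
        between_terms=("intercept", "group"),
        within_terms=("time", "group:time"),
        n_subjects=ds.n_subjects,
        n_obs=n_obs,
        time_grid=grid,
        spec=spec,
    )


# -- variance parameterisation ---------------------------------------------


def _chol_from_params(params: np.ndarray, dim: int) -> np.ndarray:
    """Lower-triangular factor with log-parameterised diagonal."""
    l = np.zeros((dim, dim))
    idx = 0
    for i in range(dim):
        for j in range(i + 1):
            if i == j:
                l[i, j] = np.exp(params[idx])
            else:
                l[i, j] = params[idx]
            idx += 1
    return l


def _n_theta(spec: LMMSpec, m_grid: int) -> int:
    n_g = spec.q * (spec.q + 1) // 2
    if spec.structure == "ind":
        return n_g + 1
    if spec.structure == "ar1":
        return n_g + 2
    return n_g + m_grid * (m_grid + 1) // 2


def _unpack(theta: np.ndarray, spec: LMMSpec, m_grid: int):
    """theta -> (G, error-structure params)."""
    q = spec.q
    n_g = q * (q + 1) // 2
    lg = _chol_from_params(theta[:n_g], q)
    g = lg @ lg.T
    rest = theta[n_g:]
    if spec.structure == "ind":
        return g, {"sigma2": float(np.exp(2.0 * rest[0]))}
    if spec.structure == "ar1":
        return g, {
            "sigma2": float(np.exp(2.0 * rest[0])),
            "rho": float(np.tanh(rest[1])),
        }
    lr = _chol_from_params(rest, m_grid)
    return g, {"r_matrix": lr @ lr.T}


def _r_for_pattern(pat: _Pattern, err: dict, structure: str) -> np.ndarray:
    m = pat.times.size
    if structure == "ind":
        return err["sigma2"] * np.eye(m)
    if structure == "ar1":
        lags = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        return err["sigma2"] * err["rho"] ** lags
    return err["r_matrix"][np.ix_(pat.grid_idx, pat.grid_idx)]


def _profiled_reml(theta: np.ndarray, design: DesignData):
    """Negative REML log-likelihood with beta profiled out by GLS.

    Returns ``(neg_loglik, beta, beta_cov)``; the latter two are reused at
    the optimum.
    """
    spec = design.spec
    g, err = _unpack(theta, spec, design.time_grid.size)
    p = design.p
    # finite, sloped penalty on failure: keeps the line search recoverable
    # (an inf would NaN the finite-difference gradient and stall L-BFGS-B)
    penalty = 1e10 * (1.0 + float(np.sum(np.square(theta))))
    a = np.zeros((p, p))
    u = np.zeros(p)
    yvy = 0.0
    sum_logdet = 0.0
    for pat in design.patterns:
        z = design.z_for(pat.times)
        v = z @ g @ z.T + _r_for_pattern(pat, err, spec.structure)
        try:
            c, low = cho_factor(v, lower=True)
        except np.linalg.LinAlgError:
            return penalty, None, None
        vinv = cho_solve((c, low), np.eye(v.shape[0]))
        sum_logdet += pat.y.shape[0] * 2.0 * np.sum(np.log(np.diag(c)))
        xtvi = np.einsum("smp,mn->snp", pat.x, vinv)
        a += np.einsum("snp,snq->pq", xtvi, pat.x)
        u += np.einsum("snp,sn->p", xtvi, pat.y)
        yvy += np.einsum("sm,mn,sn->", pat.y, vinv, pat.y)
    try:
        ca, lowa = cho_factor(a, lower=True)
    except np.linalg.LinAlgError:
        return penalty, None, None
    beta = cho_solve((ca, lowa), u)
    logdet_a = 2.0 * np.sum(np.log(np.diag(ca)))
    qform = yvy - u @ beta
    neg2ll = sum_logdet + logdet_a + qform + (design.n_obs - p) * _LOG2PI
    beta_cov = cho_solve((ca, lowa), np.eye(p))
    return 0.5 * neg2ll, beta, beta_cov


def _start_values(design: DesignData) -> np.ndarray:
    """Moment-based starting point: OLS fit, residual variance split evenly
    between the random intercept and the error."""
    xs = np.concatenate([p.x.reshape(-1, design.p) for p in design.patterns])
    ys = np.concatenate([p.y.reshape(-1) for p in design.patterns])
    beta, *_ = np.linalg.lstsq(xs, ys, rcond=None)
    resid = ys - xs @ beta
    s2 = max(float(resid @ resid) / max(len(ys) - design.p, 1), 1e-8)
    half_log_sd = 0.5 * np.log(s2 / 2.0)
    spec = design.spec
    n_g = spec.q * (spec.q + 1) // 2
    theta_g = np.zeros(n_g)
    theta_g[0] = half_log_sd
    if spec.q == 2:
        theta_g[2] = half_log_sd - np.log(
            max(design.time_grid.max() - design.time_grid.min(), 1.0)
        )
    if spec.structure == "ind":
        theta_e = np.array([half_log_sd])
    elif spec.structure == "ar1":
        theta_e = np.array([half_log_sd, 0.0])
    else:
        m = design.time_grid.size
        theta_e = np.zeros(m * (m + 1) // 2)
        idx = 0
        for i in range(m):
            for j in range(i + 1):
                if i == j:
                    theta_e[idx] = half_log_sd
                idx += 1
    return np.concatenate([theta_g, theta_e])


@dataclass
class LMMFit:
    """A fitted linear mixed model."""

    spec: LMMSpec
    design: DesignData = field(repr=False)
    beta: pd.Series
    beta_cov: np.ndarray = field(repr=False)
    vc: VarianceComponents
    reml_loglik: float
    n_params: int  # d = fixed effects + free variance parameters
    aic: float
    bic: float
    converged: bool
    n_iter: int

    def marginal_covariance(self, times: np.ndarray | None = None) -> np.ndarray:
        """Fitted V = Z G Z' + R for a subject observed at ``times``
        (defaults to the shared grid)."""
        if times is None:
            times = self.design.time_grid
        times = np.asarray(times, float)
        z = self.design.z_for(times)
        m = times.size
        if self.vc.structure == "ind":
            r = self.vc.sigma2 * np.eye(m)
        elif self.vc.structure == "ar1":
            lags = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
            r = self.vc.sigma2 * self.vc.rho ** lags
        else:
            pos = {t: j for j, t in enumerate(self.design.time_grid)}
            idx = np.array([pos[t] for t in times])
            r = self.vc.r_matrix[np.ix_(idx, idx)]
        return z @ self.vc.g_matrix @ z.T + r


def reml_fit(
    ds: RepeatedMeasuresDataset,
    spec: LMMSpec | None = None,
    maxiter: int = 500,
    gtol: float = 1e-8,
) -> LMMFit:
    """Fit the linear mixed model by restricted maximum likelihood."""
    spec = spec or LMMSpec()
    design = build_design(ds, spec)
    m_grid = design.time_grid.size
    n_theta = _n_theta(spec, m_grid)
    p = design.p
    if design.n_obs <= p:
        raise FeasibilityError(f"need more than p={p} observations")
    if spec.structure == "uns" and n_theta + p >= design.n_obs:
        raise FeasibilityError(
            f"uns structure has {n_theta} covariance parameters; "
            f"not estimable from {design.n_obs} observations"
        )
    theta0 = _start_values(design)

    def objective(theta):
        val, _, _ = _profiled_reml(theta, design)
        return val

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=[(-_PARAM_BOUND, _PARAM_BOUND)] * n_theta,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        # a failed line search near the optimum is usually recoverable by
        # restarting with a fresh Hessian approximation
        for _ in range(2):
            if res.success:
                break
            res2 = optimize.minimize(
                objective,
                res.x,
                method="L-BFGS-B",
                bounds=[(-_PARAM_BOUND, _PARAM_BOUND)] * n_theta,
                options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
            )
            if res2.fun <= res.fun:
                res = res2
    neg_ll, beta, beta_cov = _profiled_reml(res.x, design)
    if beta is None:
        raise NumericalError("REML objective not evaluable at the optimum")
    g, err = _unpack(res.x, spec, m_grid)
    if g[0, 0] < 1e-8:
        logger.warning("random-intercept variance estimated at the boundary (~0)")
    vc = VarianceComponents(
        g_matrix=g,
        structure=spec.structure,
        sigma2=err.get("sigma2"),
        rho=err.get("rho"),
        r_matrix=err.get("r_matrix"),
    )
    d = p + n_theta
    ll = -neg_ll
    fit = LMMFit(
        spec=spec,
        design=design,
        beta=pd.Series(beta, index=design.fixed_names),
        beta_cov=beta_cov,
        vc=vc,
        reml_loglik=float(ll),
        n_params=d,
        aic=float(-2.0 * ll + 2.0 * d),
        bic=float(-2.0 * ll + d * np.log(design.n_obs)),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )
    if not res.success:
        logger.warning("REML optimisation did not converge: %s", res.message)
    return fit


def wald_f_tests(
    fit: LMMFit, alpha: float = 0.05, test_type: str = "sequential"
) -> list[TestResult]:
    """Wald F test per fixed-effect term.

    ``test_type="sequential"`` (default) tests each term adjusted for the
    terms preceding it in the order intercept, group, time, group:time --
    the convention of the classical multilevel software this module
    reproduces; ``"marginal"`` gives type-III tests adjusted for all other
    terms.  The two coincide for the last term (the interaction).
    Denominator df follow the inner-outer rule (see module docstring).
    """
    if test_type not in ("sequential", "marginal"):
        raise ConfigurationError(
            f"test_type must be 'sequential' or 'marginal', got {test_type!r}"
        )
    design = fit.design
    n_subj, n_obs = design.n_subjects, design.n_obs
    p_between = len(design.term_columns["intercept"]) + len(
        design.term_columns["group"]
    )
    p_within = len(design.term_columns["time"]) + len(
        design.term_columns["group:time"]
    )
    beta = fit.beta.to_numpy()
    if test_type == "sequential":
        # upper Cholesky R of cov(beta)^-1 orthogonalises the terms in
        # model order; the sequential F for a term is the mean square of
        # the corresponding entries of R @ beta.
        try:
            vinv = np.linalg.inv(fit.beta_cov)
            r_upper = np.linalg.cholesky(vinv, upper=True)
        except np.linalg.LinAlgError as err:
            raise NumericalError(f"singular coefficient covariance: {err}")
        z = r_upper @ beta
    effect_of = {"group": "group", "time": "time", "group:time": "interaction"}
    out = []
    for term in ("group", "time", "group:time"):
        cols = design.term_columns[term]
        if not cols:  # single-group data: no group / interaction columns
            continue
        if test_type == "sequential":
            stat = float(np.sum(z[cols] ** 2)) / len(cols)
        else:
            bc = beta[cols]
            vcc = fit.beta_cov[np.ix_(cols, cols)]
            try:
                stat = float(bc @ np.linalg.solve(vcc, bc)) / len(cols)
            except np.linalg.LinAlgError as err:
                raise NumericalError(f"singular coefficient covariance: {err}")
        if term in design.between_terms:
            df_den = n_subj - p_between
        else:
            df_den = n_obs - n_subj - p_within
        pval = float(stats.f.sf(stat, len(cols), df_den))
        out.append(
            TestResult(
                effect=effect_of[term],
                method=f"lmm-{fit.spec.structure}",
                statistic_name="wald_F",
                statistic=stat,
                df_num=float(len(cols)),
                df_den=float(df_den),
                p_value=pval,
                alpha=alpha,
            )
        )
    return out


def information_criteria(fit: LMMFit) -> tuple[float, float]:
    """(AIC, BIC) of a fitted model; d counts fixed + variance parameters."""
    return fit.aic, fit.bic


def fit_model_menu(
    ds: RepeatedMeasuresDataset, alpha: float = 0.05
) -> pd.DataFrame:
    """Fit the 6-model menu (intercept / intercept+slope x ind / ar1 / uns).

    Infeasible or failing fits are recorded with a reason, never fatal.
    Returns a DataFrame sorted by AIC with per-effect p-values and both
    criteria; ``fit`` column holds the LMMFit (or None).
    """
    rows = []
    for random in RANDOM_STRUCTURES:
        for structure in ERROR_STRUCTURES:
            spec = LMMSpec(random=random, structure=structure)
            row = {"random": random, "structure": structure, "fit": None,
                   "reason": ""}
            try:
                fit = reml_fit(ds, spec)
                tests = {t.effect: t.p_value for t in wald_f_tests(fit, alpha)}
                row.update(
                    fit=fit,
                    aic=fit.aic,
                    bic=fit.bic,
                    loglik=fit.reml_loglik,
                    d=fit.n_params,
                    converged=fit.converged,
                    p_group=tests["group"],
                    p_time=tests["time"],
                    p_interaction=tests["interaction"],
                )
            except (FeasibilityError, NumericalError) as err:
                row["reason"] = f"{type(err).__name__}: {err}"
                logger.warning("menu fit %s/%s skipped: %s", random,
                               structure, err)
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("aic", na_position="last").reset_index(drop=True)
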