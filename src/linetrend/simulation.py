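"""Monte Carlo engine for the linear-trend mixed-model comparison study.

Datasets are generated from a random-intercept linear-trend model with a
binary grouping variable X in {0, 1}:

    Y_ij = b0 + b1 X_i + b2 t_j + b3 (t_j X_i) + u_i + e_ij,

with t_j = 2j (j = 1..m), u_i ~ N(0, b0_sd^2) and the error vector e_i
drawn jointly normal with covariance R given by one of three structures:

* ``ind`` -- sigma2 * I;
* ``ar1`` -- sigma2 * H with h_jj' = rho^|j-j'|;
* ``uns`` -- an arbitrary SPD matrix (a reproducible stand-in by default,
  see :func:`default_uns_matrix`).

Each replicate is analysed by the summary-measure tests, the profile
(multivariate) tests, and REML mixed models under a grid of working error
structures; empirical rejection rates at level alpha estimate type-I error
(null configurations) and power.  Replicates are seeded by a counter-based
derivation from ``(seed, config_id, rep_index)``, so any cell is
reproducible in isolation and the study parallelises trivially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import RepeatedMeasuresDataset, to_wide
from .exceptions import (
    ConfigurationError,
    DegenerateTestError,
    FeasibilityError,
    LinetrendError,
    NumericalError,
)
from . import summary_measures as sma
from . import profile_manova as uma
from .mixed_model import LMMSpec, reml_fit, wald_f_tests

logger = logging.getLogger(__name__)

METHODS = ("sma", "uma", "lmm-ind", "lmm-ar1", "lmm-uns")
EFFECTS = ("time", "group", "interaction")


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the study grid (a data-generating configuration)."""

    m: int = 5
    n_per_group: int = 50
    beta: tuple = (2.0, 0.0, 0.0, 0.0)  # (b0, b1, b2, b3)
    b0_sd: float = 0.25
    structure: str = "ind"  # true error structure
    sigma2: float = 0.5
    rho: float = 0.7
    uns_r: np.ndarray | None = field(default=None, repr=False)
    alpha: float = 0.05
    config_id: int = 0

    n_groups = 2  # model has a binary grouping variable

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ConfigurationError("m must be >= 2")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if len(self.beta) != 4:
            raise ConfigurationError("beta must be (b0, b1, b2, b3)")
        if self.structure not in ("ind", "ar1", "uns"):
            raise ConfigurationError(f"unknown structure {self.structure!r}")
        if self.structure == "ar1" and not -1.0 < self.rho < 1.0:
            raise ConfigurationError("ar1 requires |rho| < 1")

    @property
    def times(self) -> np.ndarray:
        """Shared measurement times t_j = 2j, j = 1..m."""
        return 2.0 * np.arange(1, self.m + 1)

    def error_covariance(self) -> np.ndarray:
        """The true R matrix of the configuration."""
        m = self.m
        if self.structure == "ind":
            return self.sigma2 * np.eye(m)
        if self.structure == "ar1":
            lags = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
            return self.sigma2 * self.rho ** lags
        if self.uns_r is None:
            raise ConfigurationError("uns structure requires uns_r")
        r = np.asarray(self.uns_r, float)
        if r.shape != (m, m) or not np.allclose(r, r.T):
            raise ConfigurationError("uns_r must be a symmetric m x m matrix")
        if np.any(np.linalg.eigvalsh(r) <= 0):
            raise ConfigurationError("uns_r must be positive definite")
        return r


def default_uns_matrix(m: int, seed: int = 0) -> np.ndarray:
    """Reproducible stand-in for an arbitrary error covariance.

    Heterogeneous variances drawn uniformly in [0.25, 1.0] and correlations
    decaying geometrically with time-point separation (base drawn in
    [0.3, 0.6]); symmetric positive definite by construction and fixed for
    a given ``(m, seed)``.
    """
    if m < 2:
        raise ConfigurationError("m must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([m, seed]))
    variances = rng.uniform(0.25, 1.0, m)
    base = rng.uniform(0.3, 0.6)
    lags = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    corr = base ** lags
    sd = np.sqrt(variances)
    return corr * np.outer(sd, sd)


def generate_dataset(
    config: SimulationConfig, rep_index: int, seed: int = 0
) -> RepeatedMeasuresDataset:
    """Draw one replicate dataset from the configuration.

    The random stream is derived from ``(seed, config_id, rep_index)``, so
    the same triple always yields the identical dataset.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), int(config.config_id),
                                int(rep_index)])
    )
    n = config.n_per_group
    m = config.m
    t = config.times
    b0, b1, b2, b3 = config.beta
    x = np.repeat([0.0, 1.0], n)  # group indicator per subject
    n_subj = 2 * n
    # fixed-effect surface: b0 + b1*x + (b2 + b3*x) * t
    mean = b0 + b1 * x[:, None] + b2 * t[None, :] + b3 * np.outer(x, t)
    u = rng.normal(0.0, config.b0_sd, n_subj)
    r = config.error_covariance()
    if np.trace(r) == 0.0:  # noise-free override (degenerate R)
        eps = np.zeros((n_subj, m))
    else:
        chol = np.linalg.cholesky(r)
        eps = rng.standard_normal((n_subj, m)) @ chol.T
    y = mean + u[:, None] + eps
    df = pd.DataFrame(
        {
            "subject": np.repeat([f"s{i:04d}" for i in range(n_subj)], m),
            "group": np.repeat(np.where(x == 0, "g0", "g1"), m),
            "time": np.tile(t, n_subj),
            "response": y.reshape(-1),
        }
    )
    return RepeatedMeasuresDataset(df)


def analyze_one(
    ds: RepeatedMeasuresDataset,
    methods=METHODS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the selected methods to one dataset.

    Returns a tidy frame ``(method, effect, p_value, status, reason)``;
    infeasible or failed entries carry a reason code and a NaN p-value,
    never a fabricated number.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
    rows = []

    def add(method, effect, p=np.nan, status="ok", reason=""):
        rows.append(
            {"method": method, "effect": effect, "p_value": p,
             "status": status, "reason": reason}
        )

    k = ds.n_groups
    variant = "t" if k == 2 else "anova"

    if "sma" in methods:
        summaries = sma.summarize(ds)
        for effect, fn in (
            ("time", lambda: sma.test_time(summaries, alpha)),
            ("interaction",
             lambda: sma.test_interaction(summaries, variant, alpha)),
            ("group", lambda: sma.test_group(summaries, variant, alpha)),
        ):
            try:
                add("sma", effect, fn().p_value)
            except (DegenerateTestError, ConfigurationError) as err:
                add("sma", effect, status="degenerate", reason=str(err))

    if "uma" in methods:
        try:
            wide = to_wide(ds)
            # the multivariate route is reported as a whole: when the MANOVA
            # condition N - k > m - 1 fails, its trend tests are all skipped
            if wide.n_subjects - k <= wide.n_times - 1:
                raise FeasibilityError(
                    f"N - k = {wide.n_subjects - k} <= m - 1 = "
                    f"{wide.n_times - 1}: multivariate tests infeasible"
                )
        except FeasibilityError as err:
            for effect in ("time", "interaction"):
                add("uma", effect, status="infeasible", reason=str(err))
            try:
                add("uma", "group",
                    uma.test_group_uma(ds, alpha=alpha).p_value)
            except LinetrendError as err2:
                add("uma", "group", status="infeasible", reason=str(err2))
            wide = None
        if wide is not None:
            for effect, fn in (
                ("time", lambda: uma.test_time_hotelling(wide, alpha=alpha)),
                ("interaction", lambda: uma.test_parallelism(wide, alpha=alpha)),
                ("group", lambda: uma.test_group_uma(ds, alpha=alpha)),
            ):
                try:
                    add("uma", effect, fn().p_value)
                except (FeasibilityError, NumericalError) as err:
                    add("uma", effect, status="infeasible", reason=str(err))

    for method in methods:
        if not method.startswith("lmm-"):
            continue
        structure = method.split("-", 1)[1]
        try:
            fit = reml_fit(ds, LMMSpec(random="intercept", structure=structure))
        except LinetrendError as err:
            for effect in EFFECTS:
                add(method, effect, status="infeasible", reason=str(err))
            continue
        if not fit.converged:
            for effect in EFFECTS:
                add(method, effect, status="nonconverged",
                    reason="REML did not converge")
            continue
        try:
            for tr in wald_f_tests(fit, alpha):
                add(method, tr.effect, tr.p_value)
        except NumericalError as err:
            for effect in EFFECTS:
                add(method, effect, status="failed", reason=str(err))
    return pd.DataFrame(rows)


def empirical_rate(pvals, alpha: float = 0.05) -> float:
    """Fraction of p-values at or below alpha."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise DegenerateTestError("cannot compute a rate from zero p-values")
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return float(np.mean(p <= alpha))


def run_study(
    grid,
    methods=METHODS,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full factorial study: grid x methods x effects.

    Returns one row per (configuration, method, effect) with the empirical
    rejection rate over valid replicates, the valid/failed counts and the
    set of reason codes seen.  Deterministic for fixed (grid, reps, seed).
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    out = []
    for cfg in grid:
        collected: dict[tuple, list] = {}
        reasons: dict[tuple, set] = {}
        for rep in range(reps):
            ds = generate_dataset(cfg, rep, seed=seed)
            table = analyze_one(ds, methods=methods, alpha=alpha)
            for _, row in table.iterrows():
                key = (row["method"], row["effect"])
                collected.setdefault(key, []).append(
                    row["p_value"] if row["status"] == "ok" else np.nan
                )
                if row["status"] != "ok":
                    reasons.setdefault(key, set()).add(row["status"])
        logger.info("config %s done (%d reps)", cfg.config_id, reps)
        for (method, effect), pvals in collected.items():
            arr = np.asarray(pvals, float)
            valid = arr[~np.isnan(arr)]
            rate = empirical_rate(valid, alpha) if valid.size else np.nan
            out.append(
                {
                    "config_id": cfg.config_id,
                    "true_structure": cfg.structure,
                    "m": cfg.m,
                    "n_per_group": cfg.n_per_group,
                    "beta1": cfg.beta[1],
                    "beta2": cfg.beta[2],
                    "beta3": cfg.beta[3],
                    "method": method,
                    "effect": effect,
                    "rejection_rate": rate,
                    "n_valid": int(valid.size),
                    "n_failed": int(arr.size - valid.size),
                    "reason_codes": ";".join(
                        sorted(reasons.get((method, effect), set()))
                    ),
                }
            )
    return pd.DataFrame(out)


# -- the published study grid ----------------------------------------------

#: (beta1, beta2) pairs for the time/group power rows, keyed by m; the
#: within-subject effect sizes shrink as the number of measurements grows.
POWER_BETAS_TIME = {
    5: [(0.25, 0.020), (0.35, 0.040)],
    10: [(0.25, 0.010), (0.35, 0.020)],
    20: [(0.25, 0.005), (0.35, 0.010)],
}
#: beta3 values for the interaction power rows, keyed by m.
POWER_BETAS_INTERACTION = {
    5: [0.040, 0.080],
    10: [0.020, 0.040],
    20: [0.010, 0.020],
}


def paper_grid(
    structures=("ind", "ar1", "uns"),
    m_values=(5, 10, 20),
    n_values=(5, 10, 30, 50),
    uns_seed: int = 0,
) -> list[SimulationConfig]:
    """The full study grid: null + power rows for every (structure, m, n)."""
    grid = []
    cid = 0
    for structure in structures:
        for m in m_values:
            uns_r = default_uns_matrix(m, uns_seed) if structure == "uns" else None
            betas = [(2.0, 0.0, 0.0, 0.0)]
            betas += [(2.0, b1, b2, 0.0) for b1, b2 in POWER_BETAS_TIME[m]]
            betas += [(2.0, 0.0, 0.0, b3) for b3 in POWER_BETAS_INTERACTION[m]]
            for n in n_values:
                for beta in betas:
                    grid.append(
                        SimulationConfig(
                            m=m, n_per_group=n, beta=beta,
                            structure=structure, uns_r=uns_r, config_id=cid,
                        )
                    )
                    cid += 1
    return grid
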