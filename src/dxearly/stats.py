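"""Design calculations and cluster-aware analysis of study tables.

Design side: the variance-inflation (design effect) ``DE = 1 + (n - 1) rho``
for clusters of size ``n`` with intraclass correlation ``rho``, and the
cluster-adjusted minimum sample size ``ceil(base_n * DE)``.

Analysis side: per-session accuracy summaries (exact counts, percent rounded
half-up to one decimal), population-averaged logistic regression via
generalized estimating equations (GEE) with an exchangeable working
correlation and robust (sandwich) standard errors — the standard analysis for
binary outcomes clustered within participants — plus linear models with
cluster-robust covariance for the continuous outcomes, an order-effect
(training-effect) check, an ANOVA moment estimator of the binary-outcome ICC,
a cluster bootstrap cross-check, and a simulation-based power routine.

The GEE and cluster-robust OLS machinery is statsmodels
(:class:`statsmodels.genmod.generalized_estimating_equations.GEE`); fits are
returned as light Results objects (:class:`GEEFit`, :class:`LinearFit`) with
``summary()`` tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as dc_replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .errors import DomainError, FitError, SchemaError

__all__ = [
    "design_effect",
    "adjust_sample_size",
    "accuracy_summary",
    "GEEFit",
    "LinearFit",
    "gee_logistic",
    "cluster_linear",
    "session_effect",
    "session_effect_linear",
    "order_effect_check",
    "estimate_icc_anova",
    "cluster_bootstrap_or",
    "power_by_simulation",
]

_Z95 = float(norm.ppf(0.975))


def design_effect(n: int, icc: float) -> float:
    """Variance inflation for clusters of size ``n`` with intraclass
    correlation ``icc``: ``1 + (n - 1) * icc``."""
    if n < 1:
        raise DomainError(f"cluster size must be >= 1, got {n}")
    if not 0.0 <= icc < 1.0:
        raise DomainError(f"icc must lie in [0, 1), got {icc}")
    return 1.0 + (n - 1) * icc


def adjust_sample_size(base_n: int, de: float) -> int:
    """Cluster-adjusted minimum sample size: ``ceil(base_n * de)``."""
    if base_n < 1:
        raise DomainError(f"base sample size must be >= 1, got {base_n}")
    if de < 1.0:
        raise DomainError(f"design effect must be >= 1, got {de}")
    # guard against binary float dust just below an integer product
    return int(math.ceil(round(base_n * de, 9)))


def _percent_half_up(k: int, n: int) -> float:
    pct = Decimal(100 * k) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def accuracy_summary(results: pd.DataFrame, outcome: str = "correct_working") -> pd.DataFrame:
    """Per-session counts and percentages for a binary outcome column.

    Returns a frame indexed by session with ``count_correct``,
    ``denominator`` and ``percent`` (100·k/n, rounded half-up to one
    decimal, matching how study tables are presented).
    """
    for col in ("session", outcome):
        if col not in results.columns:
            raise SchemaError(f"results table: missing column {col!r}")
    rows = {}
    for session, grp in results.groupby("session", sort=True):
        vals = grp[outcome]
        if not vals.isin((0, 1)).all():
            raise SchemaError(f"results table: column {outcome!r} must be binary 0/1")
        k, n = int(vals.sum()), int(len(vals))
        rows[session] = {
            "count_correct": k,
            "denominator": n,
            "percent": _percent_half_up(k, n),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# fits


@dataclass(frozen=True)
class GEEFit:
    """Population-averaged logistic fit on clustered binary data."""

    names: tuple[str, ...]
    params: np.ndarray  # log-odds scale
    se: np.ndarray  # robust (or bias-reduced) standard errors
    alpha: float  # estimated exchangeable working correlation
    n_clusters: int
    n_obs: int
    converged: bool
    cov_type: str

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self) -> np.ndarray:
        lo = self.params - _Z95 * self.se
        hi = self.params + _Z95 * self.se
        return np.column_stack([lo, hi])

    def or_conf_int(self) -> np.ndarray:
        return np.exp(self.conf_int())

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def summary(self) -> str:
        ci = self.conf_int()
        orci = self.or_conf_int()
        lines = [
            "GEE logistic (exchangeable working correlation, "
            f"{self.cov_type} SEs)",
            f"clusters: {self.n_clusters}   observations: {self.n_obs}   "
            f"alpha-hat: {self.alpha:.4f}   converged: {self.converged}",
            f"{'term':<16}{'coef':>9}{'se':>8}{'z':>7}{'p':>8}"
            f"{'OR':>8}{'[2.5%':>9}{'97.5%]':>9}",
        ]
        for i, name in enumerate(self.names):
            lines.append(
                f"{name:<16}{self.params[i]:>9.4f}{self.se[i]:>8.4f}"
                f"{self.zvalues[i]:>7.2f}{self.pvalues[i]:>8.4f}"
                f"{self.odds_ratios[i]:>8.3f}{orci[i, 0]:>9.3f}{orci[i, 1]:>9.3f}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class LinearFit:
    """Linear fit with cluster-robust (sandwich) standard errors."""

    names: tuple[str, ...]
    params: np.ndarray
    se: np.ndarray
    n_clusters: int
    n_obs: int

    def conf_int(self) -> np.ndarray:
        return np.column_stack(
            [self.params - _Z95 * self.se, self.params + _Z95 * self.se]
        )

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Linear model (cluster-robust SEs)",
            f"clusters: {self.n_clusters}   observations: {self.n_obs}",
            f"{'term':<16}{'coef':>10}{'se':>9}{'z':>7}{'p':>8}{'[2.5%':>10}{'97.5%]':>10}",
        ]
        for i, name in enumerate(self.names):
            lines.append(
                f"{name:<16}{self.params[i]:>10.4f}{self.se[i]:>9.4f}"
                f"{self.zvalues[i]:>7.2f}{self.pvalues[i]:>8.4f}"
                f"{ci[i, 0]:>10.3f}{ci[i, 1]:>10.3f}"
            )
        return "\n".join(lines)


def _as_design(
    X, names: Optional[Sequence[str]]
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(str(c) for c in X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    return X, tuple(names)


def _validate_clustered(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> int:
    if len(y) != len(X) or len(y) != len(groups):
        raise DomainError("y, X and cluster ids must have equal length")
    n_clusters = len(np.unique(groups))
    if n_clusters < 2:
        raise DomainError("at least 2 clusters are required")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is singular (collinear columns)")
    return n_clusters


def gee_logistic(
    y,
    X,
    groups,
    names: Optional[Sequence[str]] = None,
    corr: str = "exchangeable",
    cov_type: str = "robust",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> GEEFit:
    """Population-averaged logistic regression on clustered binary data.

    Estimating equations are solved iteratively with the chosen working
    correlation (``exchangeable`` with a moment estimator for the common
    intra-cluster correlation, or ``independence``); standard errors are the
    robust sandwich by default (``cov_type="bias_reduced"`` applies the
    Mancl–DeRouen small-sample correction).  With an independence working
    correlation the coefficients coincide with the ordinary pooled logistic
    MLE.  Non-convergence is flagged on the returned fit; apparent complete
    separation raises :class:`FitError`.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    X, names = _as_design(X, names)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DomainError("outcome must be binary 0/1")
    n_clusters = _validate_clustered(y, X, groups)
    if corr == "exchangeable":
        cov_struct = sm.cov_struct.Exchangeable()
    elif corr == "independence":
        cov_struct = sm.cov_struct.Independence()
    else:
        raise DomainError(f"unknown working correlation {corr!r}")

    model = sm.GEE(y, X, groups=groups, family=sm.families.Binomial(), cov_struct=cov_struct)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=maxiter, ctol=tol, cov_type=cov_type)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"GEE fit failed: {exc}") from exc
    for w in caught:
        if "did not converge" in str(w.message).lower() or isinstance(
            w.message, sm.tools.sm_exceptions.IterationLimitWarning
        ):
            converged = False
    params = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not np.isfinite(params).all() or np.abs(params).max() > 30:
        raise FitError(
            "GEE fit diverged — outcome may be perfectly separated by the design"
        )
    if not np.isfinite(se).all():
        raise FitError("GEE fit produced non-finite standard errors")
    alpha = float(np.atleast_1d(cov_struct.dep_params)[0]) if corr == "exchangeable" else 0.0
    return GEEFit(
        names=names,
        params=params,
        se=se,
        alpha=alpha,
        n_clusters=n_clusters,
        n_obs=len(y),
        converged=converged,
        cov_type=cov_type,
    )


def cluster_linear(y, X, groups, names: Optional[Sequence[str]] = None) -> LinearFit:
    """OLS with cluster-robust (sandwich) covariance."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    X, names = _as_design(X, names)
    n_clusters = _validate_clustered(y, X, groups)
    res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
    return LinearFit(
        names=names,
        params=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        n_clusters=n_clusters,
        n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# study-table conveniences


def _session_design(results: pd.DataFrame, adjust_order: bool) -> tuple[pd.DataFrame, np.ndarray]:
    for col in ("session", "gp_id"):
        if col not in results.columns:
            raise SchemaError(f"results table: missing column {col!r}")
    X = pd.DataFrame(
        {
            "const": 1.0,
            "dss": (results["session"] == "dss").astype(float),
        }
    )
    if adjust_order:
        X["scenario_order"] = results["scenario_order"].astype(float)
    return X, results["gp_id"].to_numpy()


def session_effect(
    results: pd.DataFrame,
    outcome: str = "correct_working",
    adjust_order: bool = False,
    cov_type: str = "robust",
) -> GEEFit:
    """DSS-versus-baseline effect on a binary outcome (GEE logistic, clustered by GP)."""
    if outcome not in results.columns:
        raise SchemaError(f"results table: missing column {outcome!r}")
    X, groups = _session_design(results, adjust_order)
    return gee_logistic(results[outcome].to_numpy(), X, groups, cov_type=cov_type)


def session_effect_linear(results: pd.DataFrame, outcome: str) -> LinearFit:
    """DSS-versus-baseline effect on a continuous outcome (cluster-robust OLS)."""
    if outcome not in results.columns:
        raise SchemaError(f"results table: missing column {outcome!r}")
    X, groups = _session_design(results, adjust_order=False)
    return cluster_linear(results[outcome].to_numpy(), X, groups)


def order_effect_check(
    results: pd.DataFrame, outcome: str = "correct_working"
) -> dict[str, GEEFit]:
    """Training-effect check: outcome regressed on within-session order (1-6),
    separately per session.  Returns ``{"baseline": fit, "dss": fit}``."""
    for col in ("session", "scenario_order", "gp_id", outcome):
        if col not in results.columns:
            raise SchemaError(f"results table: missing column {col!r}")
    fits: dict[str, GEEFit] = {}
    for session, grp in results.groupby("session", sort=True):
        order = grp["scenario_order"].astype(float)
        order = order - order.min() + 1.0  # within-session order 1..6
        X = pd.DataFrame({"const": 1.0, "order": order})
        fits[str(session)] = gee_logistic(
            grp[outcome].to_numpy(), X, grp["gp_id"].to_numpy()
        )
    return fits


def estimate_icc_anova(y, groups) -> float:
    """One-way ANOVA moment estimator of the intraclass correlation.

    Works on binary or continuous outcomes; handles unbalanced clusters via
    the usual average cluster size ``n0``.
    """
    df = pd.DataFrame({"y": np.asarray(y, dtype=float), "g": np.asarray(groups)})
    k = df["g"].nunique()
    if k < 2:
        raise DomainError("at least 2 clusters are required")
    N = len(df)
    grand = df["y"].mean()
    sizes = df.groupby("g")["y"].count()
    means = df.groupby("g")["y"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    denom = msb + (n0 - 1.0) * msw
    if denom <= 0:
        return 0.0
    return float((msb - msw) / denom)


def cluster_bootstrap_or(
    results: pd.DataFrame,
    outcome: str = "correct_working",
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Cluster-bootstrap cross-check of the session odds ratio.

    Resamples GPs with replacement, refits the GEE session effect each time,
    and returns the point OR from the full data with a percentile CI from the
    bootstrap distribution.
    """
    rng = np.random.default_rng(seed)
    point = float(session_effect(results, outcome).odds_ratios[1])
    gps = results["gp_id"].unique()
    draws = []
    for _ in range(n_boot):
        chosen = rng.choice(gps, size=len(gps), replace=True)
        parts = []
        for b, g in enumerate(chosen):
            part = results[results["gp_id"] == g].copy()
            part["gp_id"] = f"boot{b}"
            parts.append(part)
        boot = pd.concat(parts, ignore_index=True)
        try:
            draws.append(float(session_effect(boot, outcome).odds_ratios[1]))
        except FitError:
            continue
    lo, hi = np.quantile(draws, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return point, (float(lo), float(hi))


def power_by_simulation(
    design,
    n_sims: int = 200,
    alpha: float = 0.05,
    outcome: str = "correct_working",
    seed: int = 0,
    cov_type: str = "robust",
) -> float:
    """Monte-Carlo power (or, under a null design, type-I error) of the GEE
    session-effect test at level ``alpha`` for the given study design."""
    from .simulate import simulate_study  # deferred: avoid import cycle

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31, size=n_sims)
    rejections = 0
    fitted = 0
    for s in seeds:
        table = simulate_study(dc_replace(design, seed=int(s)))
        try:
            fit = session_effect(table, outcome, cov_type=cov_type)
        except FitError:
            continue
        fitted += 1
        if fit.pvalues[1] < alpha:
            rejections += 1
    if fitted == 0:
        raise FitError("no simulated study produced a valid fit")
    return rejections / fitted
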