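"""Mixed-effects models for the haptic-factor analysis.

Continuous metrics (duration, TPL, RCM, error rate) are modeled with a
random-intercept-per-participant linear mixed model fitted by REML; the binary
accuracy outcome (endpoint within 30 mm) with a random-intercept logistic
GLMM whose marginal likelihood is integrated by adaptive Gauss-Hermite
quadrature.  The three haptic factors enter as treatment-coded indicators with
referents pulse / strong / 4 mm, so a coefficient reads as the shift caused by
changing to thrill / weak / 6 mm.  95% intervals are Wald; a factor is flagged
significant when its interval excludes 0 (log-odds scale for the GLMM).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
from statsmodels.tools import numdiff

from .errors import (
    ConvergenceError,
    DegenerateFitError,
    DomainError,
    FitError,
    FormatError,
    SeparationError,
)

FACTORS = ("vibration_type", "vibration_intensity", "skin_thickness_mm")

#: treatment coding: indicator is 1 at the non-referent level
_FACTOR_LEVELS = {
    "vibration_type": ("pulse", "thrill"),
    "vibration_intensity": ("strong", "weak"),
    "skin_thickness_mm": (4, 6),
}

FACTOR_CHANGE_LABELS = {
    "vibration_type": "pulse→thrill",
    "vibration_intensity": "strong→weak",
    "skin_thickness_mm": "4mm→6mm",
}

CONTINUOUS_METRICS = ("duration_s", "tpl_mm", "rcm_pct", "error_rate")

_Z975 = norm.ppf(0.975)


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise DomainError("confidence interval must bracket the estimate")

    @property
    def significant(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass(frozen=True)
class LmmFit:
    """Fitted random-intercept linear mixed model for one metric."""

    metric_name: str
    intercept: EffectEstimate
    fixed_effects: Mapping[str, EffectEstimate]  # keyed by factor name
    participant_intercept_variance: float
    residual_variance: float
    n_obs: int
    n_participants: int
    converged: bool

    def __post_init__(self) -> None:
        if self.participant_intercept_variance < 0 or self.residual_variance < 0:
            raise DomainError("variance components must be non-negative")


@dataclass(frozen=True)
class GlmmFit:
    """Fitted random-intercept logistic model for the binary accuracy outcome."""

    intercept: EffectEstimate
    fixed_effects: Mapping[str, EffectEstimate]  # log-odds scale
    random_intercept_variance: float
    n_obs: int
    n_participants: int
    converged: bool
    n_quad: int
    loglik: float
    _design: np.ndarray = field(repr=False)
    _cluster_modes: Mapping[str, float] = field(repr=False)
    _group_of_row: tuple = field(repr=False)

    def odds_ratios(self) -> dict[str, tuple[float, float, float]]:
        return {f: odds_ratio(self, f) for f in self.fixed_effects}

    def linear_predictors(self) -> np.ndarray:
        """Per-observation eta (fixed part plus empirical-Bayes intercept)."""
        beta = np.array(
            [self.intercept.estimate]
            + [self.fixed_effects[f].estimate for f in FACTORS]
        )
        eta = self._design @ beta
        u = np.array([self._cluster_modes[g] for g in self._group_of_row])
        return eta + u

    def fitted_probabilities(self) -> np.ndarray:
        """Per-observation pi = expit(eta); strictly inside (0, 1)."""
        return expit(self.linear_predictors())


def _design_matrix(table: pd.DataFrame) -> np.ndarray:
    """Intercept + three treatment-coded factor indicators, validated levels."""
    cols = [np.ones(len(table))]
    for factor in FACTORS:
        if factor not in table.columns:
            raise FormatError(f"metric table missing column {factor!r}")
        ref, alt = _FACTOR_LEVELS[factor]
        values = table[factor]
        if factor == "skin_thickness_mm":
            values = values.astype(int)
        bad = ~values.isin([ref, alt])
        if bad.any():
            raise DomainError(
                f"column {factor!r} contains levels outside {{{ref!r}, {alt!r}}}"
            )
        cols.append((values == alt).to_numpy(float))
    return np.column_stack(cols)


def _check_table(table: pd.DataFrame) -> None:
    if "participant_id" not in table.columns:
        raise FormatError("metric table missing column 'participant_id'")
    if table["participant_id"].nunique() < 2:
        raise DegenerateFitError("at least 2 participants required")


def _wald(estimate: float, se: float) -> EffectEstimate:
    return EffectEstimate(
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - _Z975 * se),
        ci_high=float(estimate + _Z975 * se),
    )


def fit_metric_lmm(table: pd.DataFrame, metric_name: str) -> LmmFit:
    """REML fit of the random-intercept model for one continuous metric.

    ``table`` needs one row per trial with ``participant_id``, the three
    factor columns and the metric column.  Non-convergence raises; it is never
    silently replaced by a fallback estimate.
    """
    _check_table(table)
    if metric_name not in table.columns:
        raise FormatError(f"metric table missing column {metric_name!r}")
    sub = table.dropna(subset=[metric_name])
    y = sub[metric_name].to_numpy(float)
    if len(y) == 0:
        raise DegenerateFitError(f"{metric_name}: no non-missing observations")
    if np.ptp(y) == 0.0:
        raise DegenerateFitError(f"{metric_name}: response is constant")
    X = _design_matrix(sub)
    groups = sub["participant_id"].to_numpy()
    model = sm.MixedLM(y, X, groups=groups)
    import warnings

    # lbfgs occasionally stalls near the variance boundary; fall through a
    # short optimizer ladder before declaring failure
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "cg", "powell"):
            try:
                candidate = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if candidate.converged:
                result = candidate
                break
    if result is None:
        raise ConvergenceError(f"{metric_name}: REML did not converge")
    params = result.fe_params
    bse = result.bse_fe
    effects = {
        factor: _wald(params[i + 1], bse[i + 1]) for i, factor in enumerate(FACTORS)
    }
    return LmmFit(
        metric_name=metric_name,
        intercept=_wald(params[0], bse[0]),
        fixed_effects=effects,
        participant_intercept_variance=float(np.asarray(result.cov_re)[0, 0]),
        residual_variance=float(result.scale),
        n_obs=int(len(y)),
        n_participants=int(sub["participant_id"].nunique()),
        converged=True,
    )


# ---------------------------------------------------------------------------
# Logistic GLMM by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _cluster_mode(eta0: np.ndarray, y: np.ndarray, inv_var: float) -> tuple[float, float]:
    """Mode and second derivative of the per-cluster integrand's log."""
    u = 0.0
    for _ in range(100):
        p = expit(eta0 + u)
        grad = float(np.sum(y - p)) - u * inv_var
        hess = -float(np.sum(p * (1.0 - p))) - inv_var
        step = grad / hess
        u_new = u - step
        if abs(u_new - u) < 1e-12:
            u = u_new
            break
        u = u_new
    p = expit(eta0 + u)
    hess = -float(np.sum(p * (1.0 - p))) - inv_var
    return u, hess


def _glmm_nll(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    group_rows: list[np.ndarray],
    z: np.ndarray,
    logw: np.ndarray,
    return_modes: bool = False,
):
    beta, sigma = theta[:-1], max(float(theta[-1]), 1e-8)
    inv_var = 1.0 / (sigma * sigma)
    eta_all = X @ beta
    total = 0.0
    modes = []
    sqrt2 = math.sqrt(2.0)
    for rows in group_rows:
        eta0, yj = eta_all[rows], y[rows]
        u_hat, hess = _cluster_mode(eta0, yj, inv_var)
        modes.append(u_hat)
        tau = 1.0 / math.sqrt(-hess)
        uk = u_hat + sqrt2 * tau * z
        eta = eta0[:, None] + uk[None, :]
        # log p(y | u_k) - u_k^2 / (2 sigma^2), summed over the cluster's rows
        ll = (yj[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
        ll -= 0.5 * uk * uk * inv_var
        total += logsumexp(logw + z * z + ll)
        total += math.log(sqrt2 * tau) - 0.5 * math.log(2.0 * math.pi * sigma * sigma)
    if return_modes:
        return -total, modes
    return -total


def _check_separation(table: pd.DataFrame, y: np.ndarray) -> None:
    if np.ptp(y) == 0.0:
        raise DegenerateFitError("accurate_binary: outcome is constant")
    for factor in FACTORS:
        for level in _FACTOR_LEVELS[factor]:
            vals = table[factor]
            if factor == "skin_thickness_mm":
                vals = vals.astype(int)
            mask = (vals == level).to_numpy()
            if mask.any() and np.ptp(y[mask]) == 0.0:
                raise SeparationError(factor)


def fit_accuracy_glmm(
    table: pd.DataFrame, outcome: str = "accurate_binary", n_quad: int = 25
) -> GlmmFit:
    """Random-intercept logistic fit of the binary accuracy outcome.

    The marginal likelihood is integrated cluster-by-cluster with adaptive
    Gauss-Hermite quadrature (``n_quad`` nodes, centered and scaled at each
    cluster's posterior mode).  Wald intervals are formed on the log-odds
    scale; exponentiate via :func:`odds_ratio` for odds ratios.
    """
    if n_quad < 15:
        raise DomainError("n_quad must be >= 15")
    _check_table(table)
    if outcome not in table.columns:
        raise FormatError(f"metric table missing column {outcome!r}")
    sub = table.dropna(subset=[outcome])
    y = sub[outcome].astype(bool).to_numpy(float)
    _check_separation(sub, y)
    X = _design_matrix(sub)
    groups = sub["participant_id"].to_numpy()
    labels, group_idx = np.unique(groups, return_inverse=True)
    group_rows = [np.flatnonzero(group_idx == g) for g in range(len(labels))]

    z, w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w)
    args = (y, X, group_rows, z, logw)

    # pooled logistic start for beta; modest sigma start
    try:
        beta0 = sm.Logit(y, X).fit(disp=0).params
    except Exception:
        beta0 = np.zeros(X.shape[1])
    theta0 = np.append(beta0, 0.5)
    bounds = [(None, None)] * X.shape[1] + [(1e-8, 20.0)]
    res = minimize(
        _glmm_nll, theta0, args=args, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success or not np.all(np.isfinite(res.x)):
        raise ConvergenceError(f"GLMM optimization failed: {res.message}")
    theta_hat = res.x
    k = X.shape[1]

    hess = numdiff.approx_hess(theta_hat, _glmm_nll, args=args)
    cov = None
    try:
        full = np.linalg.inv(hess)
        if np.all(np.diag(full)[:k] > 0):
            cov = full
    except np.linalg.LinAlgError:
        pass
    if cov is None:
        # sigma at/near its boundary: profile it out of the Wald covariance
        cov_beta = np.linalg.inv(hess[:k, :k])
        cov = np.zeros((k + 1, k + 1))
        cov[:k, :k] = cov_beta
    se = np.sqrt(np.diag(cov)[:k])

    nll, modes = _glmm_nll(theta_hat, *args, return_modes=True)
    effects = {
        factor: _wald(theta_hat[i + 1], se[i + 1]) for i, factor in enumerate(FACTORS)
    }
    sigma_hat = max(float(theta_hat[-1]), 0.0)
    return GlmmFit(
        intercept=_wald(theta_hat[0], se[0]),
        fixed_effects=effects,
        random_intercept_variance=sigma_hat * sigma_hat,
        n_obs=int(len(y)),
        n_participants=int(len(labels)),
        converged=True,
        n_quad=n_quad,
        loglik=-float(nll),
        _design=X,
        _cluster_modes={str(lab): m for lab, m in zip(labels, modes)},
        _group_of_row=tuple(str(g) for g in groups),
    )


def odds_ratio(glmm_fit: GlmmFit, factor: str) -> tuple[float, float, float]:
    """(OR, ci_low, ci_high): the exponentiated log-odds coefficient and CI."""
    if factor not in glmm_fit.fixed_effects:
        raise DomainError(
            f"unknown factor {factor!r}; expected one of {sorted(glmm_fit.fixed_effects)}"
        )
    eff = glmm_fit.fixed_effects[factor]
    return (math.exp(eff.estimate), math.exp(eff.ci_low), math.exp(eff.ci_high))


# ---------------------------------------------------------------------------
# Whole-study report
# ---------------------------------------------------------------------------

def analyze_study(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = CONTINUOUS_METRICS,
    n_quad: int = 25,
) -> dict:
    """Fit the accuracy GLMM plus one LMM per continuous metric.

    Per-metric fit failures are recorded under ``failures`` and do not abort
    the remaining models.  The returned dict is JSON-serializable.
    """
    report: dict = {
        "metrics": {},
        "accuracy": None,
        "variances": {},
        "n": {
            "obs": int(len(table)),
            "participants": int(table["participant_id"].nunique()),
        },
        "failures": {},
    }
    try:
        glmm = fit_accuracy_glmm(table, n_quad=n_quad)
        report["accuracy"] = {
            factor: {
                "log_odds": eff.estimate,
                "se": eff.se,
                "or": math.exp(eff.estimate),
                "or_ci_low": math.exp(eff.ci_low),
                "or_ci_high": math.exp(eff.ci_high),
                "significant": eff.significant,
            }
            for factor, eff in glmm.fixed_effects.items()
        }
        report["variances"]["accuracy_random_intercept"] = glmm.random_intercept_variance
    except FitError as exc:
        report["failures"]["accuracy"] = str(exc)
    for metric in metrics:
        try:
            fit = fit_metric_lmm(table, metric)
            report["metrics"][metric] = {
                factor: {
                    "estimate": eff.estimate,
                    "se": eff.se,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "significant": eff.significant,
                }
                for factor, eff in fit.fixed_effects.items()
            }
            report["variances"][metric] = {
                "participant_intercept": fit.participant_intercept_variance,
                "residual": fit.residual_variance,
            }
        except FitError as exc:
            report["failures"][metric] = str(exc)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def format_report_table(report: dict) -> str:
    """Human-readable factor-by-metric table ('*' marks significance at 0.05)."""
    lines = []
    header = f"{'model':<12} {'factor':<14} {'estimate':>10} {'95% CI':>22}  sig"
    lines.append(header)
    lines.append("-" * len(header))
    if report.get("accuracy"):
        for factor in FACTORS:
            cell = report["accuracy"][factor]
            lines.append(
                f"{'accuracy OR':<12} {FACTOR_CHANGE_LABELS[factor]:<14} "
                f"{cell['or']:>10.3f} "
                f"[{cell['or_ci_low']:>8.3f}, {cell['or_ci_high']:>8.3f}]  "
                f"{'*' if cell['significant'] else ''}"
            )
    for metric, factors in report.get("metrics", {}).items():
        for factor in FACTORS:
            cell = factors[factor]
            lines.append(
                f"{metric:<12} {FACTOR_CHANGE_LABELS[factor]:<14} "
                f"{cell['estimate']:>10.3f} "
                f"[{cell['ci_low']:>8.3f}, {cell['ci_high']:>8.3f}]  "
                f"{'*' if cell['significant'] else ''}"
            )
    for name, msg in report.get("failures", {}).items():
        lines.append(f"{name:<12} FIT FAILED: {msg}")
    return "\n".join(lines)
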