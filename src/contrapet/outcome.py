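"""Clinical-outcome statistics: covariate-adjusted association and survival.

Links the contralateral TSPO-PET signal to outcome with the study's battery:
partial correlation (residual-on-residual Pearson), multiple linear
regression with standardized coefficients, Cox proportional-hazards models
(Efron tie handling, optional per-SD z-transform of covariates), log-rank
tests after a median split (ties at the median go to the low group, matching
the strict ">median" definition of the high group), and covariate-adjusted
group comparisons (ANCOVA, reducing to the pooled Student t when no
covariates are given). Subjects lost to follow-up are excluded from survival
fits, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "CoxResult",
    "partial_correlation",
    "ols_regression",
    "cox_fit",
    "logrank_median_split",
    "seizure_comparison",
]


@dataclass
class CoxResult:
    terms: list
    hazard_ratios: np.ndarray
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    n: int
    events: int
    model_type: str  # univariate / multivariate

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "HR": self.hazard_ratios,
                "coef": self.coefficients,
                "se": self.standard_errors,
                "p": self.p_values,
            }
        )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.size and np.linalg.matrix_rank(X) < X.shape[1]:
        # identify columns that do not increase rank
        bad = []
        rank = 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == rank:
                bad.append(names[j])
            rank = r
        raise ValueError(f"rank-deficient covariates: collinear columns {bad}")


def partial_correlation(x, y, covariate_matrix=None) -> dict:
    """Pearson correlation of the residuals of x and y after OLS on the
    covariates (with intercept); p from a t distribution with n-k-2 df.

    With no covariates this is exactly the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariate_matrix is None or (
        hasattr(covariate_matrix, "size") and np.asarray(covariate_matrix).size == 0
    ):
        Z = np.empty((n, 0))
    else:
        Z = np.atleast_2d(np.asarray(covariate_matrix, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    names = [f"cov{j}" for j in range(k)]
    _check_full_rank(Z, names)
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("zero residual variance")
    r = float((rx * ry).sum() / denom)
    df = n - k - 2
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return {"r": r, "p": p, "n": n, "df": df}


def ols_regression(y, predictor_matrix, names: list[str] | None = None) -> dict:
    """Multiple linear regression with intercept.

    Returns raw and standardized betas (the latter from a fit on z-scored
    variables), per-term p values, R^2, adjusted R^2 and the overall F.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(predictor_matrix, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    names = names or [f"x{j}" for j in range(p)]
    _check_full_rank(np.column_stack([np.ones(n), X]), ["intercept"] + names)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    # standardized betas: fit on z-scored y and X
    sy = y.std(ddof=1)
    zX = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    zy = (y - y.mean()) / sy if sy > 0 else y * 0.0
    zfit = sm.OLS(zy, sm.add_constant(zX)).fit()
    return {
        "terms": names,
        "beta_raw": fit.params[1:],
        "beta_std": zfit.params[1:],
        "p": fit.pvalues[1:],
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "adj_r_squared": float(fit.rsquared_adj),
        "F": float(fit.fvalue),
        "F_p": float(fit.f_pvalue),
        "df_model": int(fit.df_model),
        "df_resid": int(fit.df_resid),
    }


def cox_fit(
    time,
    event,
    covariate_matrix: pd.DataFrame,
    z_transform_flags: dict | None = None,
) -> CoxResult:
    """Proportional-hazards partial-likelihood fit with Efron tie handling.

    Covariates flagged in ``z_transform_flags`` are z-transformed before
    fitting, so their hazard ratios are per SD. Requires >= 5 events.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    cov = pd.DataFrame(covariate_matrix).copy()
    if not np.all(np.isfinite(cov.to_numpy(dtype=float))):
        raise ValueError("covariates must be finite")
    n_events = int(event.sum())
    if n_events < 5:
        raise ValueError(f"need >= 5 events, got {n_events}")
    flags = z_transform_flags or {}
    for c, flag in flags.items():
        if flag:
            sd = cov[c].std(ddof=1)
            if sd == 0:
                raise ValueError(f"cannot z-transform constant covariate {c!r}")
            cov[c] = (cov[c] - cov[c].mean()) / sd
    df = cov.copy()
    df["_time"] = time
    df["_event"] = event.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"Cox fit failed (possible separation/non-convergence): {exc}"
        ) from exc
    terms = list(cph.params_.index)
    return CoxResult(
        terms=terms,
        hazard_ratios=np.exp(cph.params_.to_numpy()),
        coefficients=cph.params_.to_numpy(),
        standard_errors=cph.standard_errors_.to_numpy(),
        p_values=cph.summary["p"].to_numpy(),
        n=len(df),
        events=n_events,
        model_type="univariate" if cov.shape[1] == 1 else "multivariate",
    )


def logrank_median_split(values, time, event) -> dict:
    """Log-rank test after a median split of a continuous marker.

    High group: value strictly greater than the sample median; ties at the
    median join the low group. Kaplan-Meier median survival is reported per
    group (None when not reached).
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    med = float(np.median(values))
    high = values > med
    if high.all() or (~high).all():
        raise ValueError("median split produced an empty group")
    res = logrank_test(time[high], time[~high], event[high], event[~high])

    def km_median(t, e):
        if e.sum() == 0:
            return None
        km = KaplanMeierFitter().fit(t, e)
        m = km.median_survival_time_
        return None if np.isinf(m) else float(m)

    return {
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
        "median_split_value": med,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "median_OS_high": km_median(time[high], event[high]),
        "median_OS_low": km_median(time[~high], event[~high]),
    }


def seizure_comparison(
    signal, group_flags, covariates: pd.DataFrame | None = None
) -> dict:
    """Covariate-adjusted two-group comparison of a continuous signal
    (ANCOVA: OLS of signal on the group indicator plus covariates).

    With no covariates this reduces exactly to the two-sided pooled
    Student t test. Covariates collinear with the group indicator are
    dropped with a notice.
    """
    y = np.asarray(signal, dtype=float)
    g = np.asarray(group_flags, dtype=float)
    if len(np.unique(g)) != 2:
        raise ValueError("group flags must define exactly two groups")
    g = (g == g.max()).astype(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("both groups need >= 2 subjects")
    dropped = []
    cols: list[np.ndarray] = []
    names: list[str] = []
    if covariates is not None and len(pd.DataFrame(covariates).columns):
        cov = pd.DataFrame(covariates)
        base = np.column_stack([np.ones_like(g), g])
        for c in cov.columns:
            cand = np.column_stack(cols + [base, cov[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                dropped.append(str(c))
            else:
                cols.append(cov[c].to_numpy(dtype=float).reshape(-1, 1))
                names.append(str(c))
    X = np.column_stack([g.reshape(-1, 1)] + cols)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return {
        "estimate": float(fit.params[1]),
        "p": float(fit.pvalues[1]),
        "se": float(fit.bse[1]),
        "covariates_used": names,
        "covariates_dropped": dropped,
        "n": len(y),
    }
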