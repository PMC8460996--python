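"""Mortality models by sibling-group label category (SLC).

Three views of under-5 mortality differences between the AA, Trait and SCD
sibling-group label categories:

* weighted Kaplan-Meier curves (descriptive),
* a linear probability model of death before 60 months with survey weights,
  adjustment for geopolitical zone and urban/rural residence, and a random
  intercept per survey cluster (the inferential model whose SLC coefficients,
  scaled to deaths per 1000 livebirths, are the beta fed to the genotype
  decomposition),
* a stratified Cox proportional-hazards fit (descriptive hazard ratios).

The linear probability model is preferred over logistic regression here: the
target quantity is an absolute risk difference per 1000 livebirths, which the
linear model estimates directly and (in simulation) without bias, whereas a
logistic fit must be post-transformed at chosen covariate values.

The weighted random-intercept model is fitted by profiled REML with a
Woodbury-identity inversion of the cluster-block covariance, so the fit costs
O(clusters x p^2) per objective evaluation.  On a singular or failed fit the
estimation ladder falls back to weighted least squares with cluster-robust
standard errors; the fallback is recorded on the result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "SurvivalCurve",
    "ExcessEstimates",
    "weighted_km",
    "fit_excess_mortality",
    "fit_hazard_ratio",
    "crude_rates",
    "build_lpm_design",
]

logger = logging.getLogger(__name__)

SLC_LEVELS = ("AA", "Trait", "SCD")


@dataclass(frozen=True)
class SurvivalCurve:
    """Weighted product-limit survival curve for one SLC on [0, 60] months."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if len(s) and (np.diff(s) > 1e-12).any():
            raise ValueError("survival curve must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.label,
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
            }
        )


@dataclass(frozen=True)
class ExcessEstimates:
    """Excess under-5 deaths per 1000 livebirths by SLC, relative to AA.

    ``beta`` holds the Trait and SCD coefficients per 1000; ``cov`` their
    covariance on the same scale.  ``method`` records which rung of the
    estimation ladder produced the fit.
    """

    beta: pd.Series
    cov: pd.DataFrame
    intercept: float
    n: int
    method: str
    rho: float | None = None
    coefficients: pd.Series = field(default=None, repr=False)

    def __post_init__(self) -> None:
        c = self.cov.to_numpy()
        if not np.allclose(c, c.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh((c + c.T) / 2).min() < -1e-6:
            raise ValueError("covariance must be positive semidefinite")

    def conf_int(self, z: float = 1.96) -> pd.DataFrame:
        se = pd.Series(np.sqrt(np.diag(self.cov)), index=self.beta.index)
        return pd.DataFrame(
            {"lower": self.beta - z * se, "upper": self.beta + z * se}
        )


def _km_inputs(children: pd.DataFrame, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Duration/event arrays for under-5 survival, censoring at the horizon."""
    alive = children["alive"].astype(bool).to_numpy()
    death_age = children["age_at_death_months"].to_numpy(dtype=float)
    offset = children["birth_offset_months"].to_numpy(dtype=float)
    event = (~alive) & (death_age < horizon)
    duration = np.where(event, death_age, np.where(alive, np.minimum(offset, horizon), horizon))
    return duration, event.astype(int)


def weighted_km(
    children: pd.DataFrame,
    horizon: float = 60.0,
    label_col: str = "slc_label",
) -> dict[str, SurvivalCurve]:
    """Weighted Kaplan-Meier curve per SLC over [0, horizon] months.

    Living children are right-censored at min(attained age, horizon); deaths
    at or beyond the horizon are censored at the horizon.  Sample weights
    enter both the event and at-risk sums.  Empty groups yield an empty curve
    with a warning.
    """
    from lifelines import KaplanMeierFitter

    out: dict[str, SurvivalCurve] = {}
    for label in SLC_LEVELS:
        grp = children.loc[children[label_col] == label]
        if len(grp) == 0:
            logger.warning("no children in SLC %s; empty curve", label)
            out[label] = SurvivalCurve(label, np.array([]), np.array([]), np.array([]))
            continue
        duration, event = _km_inputs(grp, horizon)
        w = grp["weight"].to_numpy(dtype=float)
        kmf = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # curve is descriptive; no variance use
            kmf.fit(duration, event, weights=w, label=label)
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_[label].to_numpy(dtype=float)
        at_risk = (
            kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
        )
        out[label] = SurvivalCurve(label, times, surv, at_risk)
    return out


def build_lpm_design(
    children: pd.DataFrame, label_col: str = "slc_label"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Design matrix for the linear probability model.

    Columns: intercept, SLC dummies (Trait, SCD), zone dummies (first level is
    the reference), urban indicator.  Rows with missing label, weight or
    outcome are dropped.  Returns (y, X, w, cluster_codes, column names).
    """
    needed = children.dropna(
        subset=[label_col, "weight", "died_u5", "zone", "urban", "cluster_id"]
    )
    needed = needed.loc[needed[label_col].isin(SLC_LEVELS)]
    y = needed["died_u5"].to_numpy(dtype=float)
    w = needed["weight"].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(needed))]
    names = ["intercept"]
    for lev in ("Trait", "SCD"):
        dummy = (needed[label_col] == lev).to_numpy(dtype=float)
        if dummy.any():
            cols.append(dummy)
            names.append(f"slc_{lev}")
        else:
            logger.warning("SLC level %s has no observations; dropped", lev)
    zones = sorted(needed["zone"].unique())
    for z in zones[1:]:
        cols.append((needed["zone"] == z).to_numpy(dtype=float))
        names.append(f"zone_{z}")
    urban = needed["urban"].to_numpy(dtype=float)
    if len(np.unique(urban)) > 1:  # constant urbanicity is no covariate
        cols.append(urban)
        names.append("urban")
    X = np.column_stack(cols)
    cluster = pd.factorize(needed["cluster_id"])[0]
    return y, X, w, cluster, names


def _reml_random_intercept(
    y: np.ndarray, X: np.ndarray, w: np.ndarray, cluster: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted linear model with a cluster random intercept, profiled REML.

    The marginal covariance is sigma^2 (diag(1/w) + rho * J) blockwise per
    cluster; its inverse follows from the Woodbury identity, so each REML
    objective evaluation needs only per-cluster weighted sums.  Returns
    (coefficients, covariance of coefficients, rho_hat).
    """
    n, p = X.shape
    ncl = cluster.max() + 1
    XtWX = (X * w[:, None]).T @ X
    XtWy = X.T @ (w * y)
    ytWy = float(w @ (y * y))
    # per-cluster aggregates
    a = np.zeros((ncl, p))
    np.add.at(a, cluster, X * w[:, None])
    d = np.bincount(cluster, weights=w * y, minlength=ncl)
    s = np.bincount(cluster, weights=w, minlength=ncl)

    def profile(rho: float) -> tuple[float, np.ndarray, np.ndarray, float]:
        # covariates constant within clusters make A singular as rho -> inf;
        # such evaluations get an infinite criterion and are stepped over
        g = rho / (1.0 + rho * s)
        A = XtWX - (a * g[:, None]).T @ a
        b = XtWy - a.T @ (g * d)
        q = ytWy - float(g @ (d * d))
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf, A, np.full(p, np.nan), np.nan
        rss = q - float(beta @ b)
        if not np.isfinite(rss) or rss <= 0:
            return np.inf, A, beta, rss
        crit = (
            (n - p) * np.log(rss)
            + float(np.log1p(rho * s).sum())
            + float(np.linalg.slogdet(A)[1])
        )
        return crit, A, beta, rss

    res = minimize_scalar(
        lambda t: profile(np.exp(t))[0],
        bounds=(np.log(1e-8), np.log(1e3)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    # compare against the rho -> 0 boundary (no cluster variance)
    rho_hat = float(np.exp(res.x))
    if profile(1e-12)[0] <= res.fun:
        rho_hat = 0.0
    crit, A, beta, rss = profile(rho_hat)
    if not np.isfinite(crit):
        raise np.linalg.LinAlgError("REML profile is singular at the optimum")
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(A)
    return beta, cov, rho_hat


def _wls_cluster_robust(
    y: np.ndarray, X: np.ndarray, w: np.ndarray, cluster: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.WLS(y, X, weights=w).fit(
            cov_type="cluster", cov_kwds={"groups": cluster}
        )
    return fit.params, fit.cov_params()


def fit_excess_mortality(
    children: pd.DataFrame,
    label_col: str = "slc_label",
    method: str = "auto",
) -> ExcessEstimates:
    """Linear probability model of under-5 death on SLC, per 1000 livebirths.

    Expects the older cohort (birth offsets >= 60 months) with ``died_u5``
    present — apply :func:`sibling_linkage.cohort_filter` and
    :func:`sibling_linkage.add_under5_death` first.  Adjusts for zone and
    urbanicity; weights enter as regression weights.  ``method`` is ``"auto"``
    (random intercept with WLS fallback), ``"reml"`` or ``"wls"``.
    """
    y, X, w, cluster, names = build_lpm_design(children, label_col)
    if len(y) == 0:
        raise ValueError("no usable children for the excess-mortality model")
    rho = None
    if method in ("auto", "reml"):
        try:
            beta, cov, rho = _reml_random_intercept(y, X, w, cluster)
            used = "reml_random_intercept"
        except np.linalg.LinAlgError:
            if method == "reml":
                raise
            logger.warning("random-intercept fit singular; falling back to WLS")
            beta, cov = _wls_cluster_robust(y, X, w, cluster)
            used = "wls_cluster_robust"
    elif method == "wls":
        beta, cov = _wls_cluster_robust(y, X, w, cluster)
        used = "wls_cluster_robust"
    else:
        raise ValueError(f"unknown method {method!r}")

    beta_slc = pd.Series(np.nan, index=["Trait", "SCD"])
    cov_slc = pd.DataFrame(0.0, index=["Trait", "SCD"], columns=["Trait", "SCD"])
    present = [lev for lev in ("Trait", "SCD") if f"slc_{lev}" in names]
    idx = [names.index(f"slc_{lev}") for lev in present]
    beta_slc[present] = np.asarray(beta)[idx] * 1000.0
    cov_slc.loc[present, present] = np.asarray(cov)[np.ix_(idx, idx)] * 1e6
    return ExcessEstimates(
        beta=beta_slc,
        cov=cov_slc,
        intercept=float(beta[names.index("intercept")] * 1000.0),
        n=len(y),
        method=used,
        rho=rho,
        coefficients=pd.Series(beta, index=names),
    )


def fit_hazard_ratio(
    children: pd.DataFrame,
    label_col: str = "slc_label",
    horizon: float = 60.0,
) -> pd.DataFrame:
    """Stratified Cox PH fit: hazard ratios of Trait and SCD SLCs vs AA.

    Strata are zone x urbanicity; sample weights enter with robust variance.
    Descriptive companion to the linear model; non-convergence is reported,
    not fatal.
    """
    from lifelines import CoxPHFitter

    data = children.dropna(subset=[label_col, "weight", "zone", "urban"]).copy()
    data = data.loc[data[label_col].isin(SLC_LEVELS)]
    duration, event = _km_inputs(data, horizon)
    present = [
        lev for lev in ("Trait", "SCD") if (data[label_col] == lev).any()
    ]
    df = pd.DataFrame(
        {
            "duration": np.maximum(duration, 1e-6),
            "event": event,
            "strata": data["zone"].astype(str).to_numpy()
            + "|"
            + data["urban"].astype(int).astype(str).to_numpy(),
            "w": data["weight"].to_numpy(dtype=float),
        }
    )
    for lev in present:
        df[f"slc_{lev}"] = (data[label_col] == lev).astype(float).to_numpy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="duration",
                event_col="event",
                weights_col="w",
                strata=["strata"],
                robust=True,
            )
    except Exception as exc:  # pragma: no cover - rare numerical failure
        logger.warning("Cox fit failed (%s); hazard ratios unavailable", exc)
        return pd.DataFrame(
            {"hr": np.nan, "lower": np.nan, "upper": np.nan},
            index=["Trait", "SCD"],
        )
    summ = cph.summary
    out = pd.DataFrame(
        np.nan, index=["Trait", "SCD"], columns=["hr", "lower", "upper"]
    )
    for lev in present:
        row = summ.loc[f"slc_{lev}"]
        out.loc[lev] = [
            np.exp(row["coef"]),
            np.exp(row["coef lower 95%"]),
            np.exp(row["coef upper 95%"]),
        ]
    return out


def crude_rates(
    children: pd.DataFrame, label_col: str = "slc_label"
) -> pd.DataFrame:
    """Weighted livebirths, under-5 deaths and percent died per SLC."""
    data = children.dropna(subset=[label_col, "weight"])
    rows = []
    for label in SLC_LEVELS:
        grp = data.loc[data[label_col] == label]
        w = grp["weight"].to_numpy(dtype=float)
        births = float(w.sum())
        deaths = float((w * grp["died_u5"].to_numpy(dtype=float)).sum())
        rows.append(
            {
                "slc": label,
                "births_weighted": births,
                "deaths_weighted": deaths,
                "pct_died": 100.0 * deaths / births if births > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("slc")
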