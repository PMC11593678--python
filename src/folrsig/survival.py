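"""Survival analysis: Kaplan-Meier, log-rank, Cox PH (Efron ties).

Wraps lifelines behind a small result surface: product-limit estimates
with Greenwood confidence intervals for rates at fixed horizons (e.g. the
five-year rate at 60 months), log-rank comparison of class curves, Cox
regression with Wald tests (univariate, multivariate, interaction terms),
episode-split time-stratified hazard ratios over (0,6], (6,12], (12,inf)
months, and the univariate-screen -> multivariate workflow in which only
covariates with univariate Wald p < 0.05 enter the joint model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class KMEstimate:
    """Product-limit estimate with Greenwood variance."""

    survival: pd.DataFrame  # index: time, column "S"
    median: float  # NaN when S never reaches 0.5
    n: int
    n_events: int
    rates: dict = field(default_factory=dict)  # t -> (S, ci_low, ci_high)
    _kmf: KaplanMeierFitter | None = None


@dataclass
class CoxFit:
    """Per-covariate HR/CI/Wald-p plus global fit info."""

    summary: pd.DataFrame  # index: covariate; coef, hr, ci_low, ci_high, p
    n: int
    n_events: int
    log_likelihood: float

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _check_times(time: np.ndarray) -> None:
    if (np.asarray(time, dtype=float) <= 0).any():
        raise ValueError("survival times must be positive")


def km_estimate(
    time: np.ndarray | pd.Series,
    event: np.ndarray | pd.Series,
    rate_times: tuple[float, ...] = (60.0,),
) -> KMEstimate:
    """Kaplan-Meier curve, median survival, and rates at fixed horizons.

    Rate CIs use the plain Greenwood variance on the survival scale,
    S +/- 1.96 * S * sqrt(sum d_i / (n_i (n_i - d_i))), clipped to [0, 1].
    The median is the earliest time with S(t) <= 0.5 (NaN if never
    reached).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_times(time)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_.rename(columns={kmf._label: "S"})
    median = float(kmf.median_survival_time_)
    if median == np.inf:
        median = float("nan")
    # Greenwood cumulative variance term at each event time
    table = kmf.event_table
    at_risk = table["at_risk"].to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = np.where(
            (d > 0) & (at_risk > d), d / (at_risk * (at_risk - d)), 0.0
        )
    greenwood = pd.Series(np.cumsum(increments), index=table.index)
    rates = {}
    for t in rate_times:
        mask = surv.index <= t
        if not mask.any():
            rates[t] = (1.0, 1.0, 1.0)
            continue
        s_t = float(surv.loc[mask, "S"].iloc[-1])
        g_t = float(greenwood[greenwood.index <= t].iloc[-1])
        half = 1.96 * s_t * np.sqrt(g_t)
        rates[t] = (s_t, max(s_t - half, 0.0), min(s_t + half, 1.0))
    return KMEstimate(
        survival=surv,
        median=median,
        n=len(time),
        n_events=int(event.sum()),
        rates=rates,
        _kmf=kmf,
    )


def logrank_test(
    time: np.ndarray | pd.Series,
    event: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """k-group log-rank test -> (chi-square, p); 1 df for two groups."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    _check_times(time)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if event.sum() < 1:
        raise ValueError("log-rank needs at least one event")
    for g in uniq:
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} has no at-risk subjects")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


def _design_matrix(
    df: pd.DataFrame,
    covariates: list[str],
    interactions: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Dummy-code categoricals (drop first level) and build product terms."""
    pieces = []
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(col.astype(float).to_frame(cov))
    design = pd.concat(pieces, axis=1)
    for a, b in interactions or []:
        cols_a = [c for c in design.columns if c == a or c.startswith(f"{a}_")]
        cols_b = [c for c in design.columns if c == b or c.startswith(f"{b}_")]
        for ca in cols_a:
            for cb in cols_b:
                design[f"{ca}:{cb}"] = design[ca] * design[cb]
    return design


def _check_collinear(design: pd.DataFrame) -> None:
    mat = design.to_numpy(dtype=float)
    if mat.shape[1] == 0:
        raise ValueError("empty design matrix")
    centered = mat - mat.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < mat.shape[1]:
        raise ValueError(
            "collinear design matrix: duplicated or linearly dependent covariates"
        )


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    interactions: list[tuple[str, str]] | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron tie handling, Wald p-values).

    Categorical covariates are dummy-coded against their first level;
    ``interactions`` are pairs of covariate names expanded into product
    terms.  Collinear designs and non-convergence raise, as does an events
    count of zero.  A warning is issued when events < 5 x coefficients.
    """
    _check_times(df[duration_col].to_numpy())
    design = _design_matrix(df, covariates, interactions)
    _check_collinear(design)
    data = design.copy()
    data[duration_col] = df[duration_col].to_numpy(dtype=float)
    data[event_col] = df[event_col].to_numpy(dtype=int)
    n_events = int(data[event_col].sum())
    if n_events == 0:
        raise ValueError("no events: Cox model is not identifiable")
    if n_events < 5 * design.shape[1]:
        warnings.warn(
            f"only {n_events} events for {design.shape[1]} coefficients",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        n=len(data),
        n_events=n_events,
        log_likelihood=float(cph.log_likelihood_),
    )


def episode_split(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    cutpoints: tuple[float, ...] = (6.0, 12.0),
) -> pd.DataFrame:
    """Split each subject's follow-up into (start, stop] episodes at cutpoints.

    Output long format: id, start, stop, event (1 only in the terminal
    episode when the subject's event occurred) plus all other columns
    copied through.
    """
    cuts = tuple(float(c) for c in cutpoints)
    if any(b <= a for a, b in zip(cuts, cuts[1:])) or any(c <= 0 for c in cuts):
        raise ValueError("cutpoints must be positive and strictly increasing")
    rows = []
    for idx, row in df.iterrows():
        t, ev = float(row[duration_col]), int(row[event_col])
        start = 0.0
        for c in cuts + (np.inf,):
            stop = min(t, c)
            if stop <= start:
                break
            rows.append(
                {
                    "subject_id": idx,
                    "start": start,
                    "stop": stop,
                    "event": int(ev and stop == t),
                    **{
                        k: row[k]
                        for k in df.columns
                        if k not in (duration_col, event_col)
                    },
                }
            )
            start = stop
            if stop == t:
                break
    return pd.DataFrame(rows)


def cox_time_stratified(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariate: str,
    cutpoints: tuple[float, ...] = (6.0, 12.0),
) -> pd.DataFrame:
    """Interval-specific hazard ratios for one covariate.

    Follow-up is episode-split at the cutpoints and a time-varying Cox
    model is fit with one covariate x interval indicator per interval, so
    each interval gets its own HR.  Intervals with no events yield NaN
    estimates (reported, not raised).  Returns a DataFrame indexed by
    interval with hr, ci_low, ci_high, p, n_events.
    """
    long = episode_split(df, duration_col, event_col, cutpoints)
    cuts = tuple(float(c) for c in cutpoints)
    edges = (0.0,) + cuts + (np.inf,)
    intervals = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    names = [
        f"({lo:g},{hi:g}]" if np.isfinite(hi) else f"({lo:g},inf)"
        for lo, hi in intervals
    ]
    cov = long[covariate].astype(float)
    cols = []
    for (lo, hi), name in zip(intervals, names):
        in_interval = (long["start"] >= lo) & (long["start"] < hi)
        long[f"x_{name}"] = cov * in_interval.astype(float)
        cols.append(f"x_{name}")
    events_per = {
        name: int(long.loc[(long["start"] >= lo) & (long["start"] < hi), "event"].sum())
        for (lo, hi), name in zip(intervals, names)
    }
    fit_cols = [c for c, name in zip(cols, names) if events_per[name] > 0]
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(
            long[["subject_id", "start", "stop", "event"] + fit_cols],
            id_col="subject_id",
            start_col="start",
            stop_col="stop",
            event_col="event",
        )
    s = ctv.summary
    rows = []
    for c, name in zip(cols, names):
        if c in s.index:
            rows.append(
                {
                    "interval": name,
                    "hr": float(s.loc[c, "exp(coef)"]),
                    "ci_low": float(s.loc[c, "exp(coef) lower 95%"]),
                    "ci_high": float(s.loc[c, "exp(coef) upper 95%"]),
                    "p": float(s.loc[c, "p"]),
                    "n_events": events_per[name],
                }
            )
        else:
            rows.append(
                {
                    "interval": name,
                    "hr": float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                    "p": float("nan"),
                    "n_events": events_per[name],
                }
            )
    return pd.DataFrame(rows).set_index("interval")


@dataclass
class ScreenResult:
    univariate: dict  # covariate -> CoxFit
    multivariate: CoxFit | None
    entered: list[str]


def multivariate_screen(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    candidates: list[str],
    alpha: float = 0.05,
) -> ScreenResult:
    """Univariate Cox per candidate; joint model on those with p < alpha.

    For multi-level candidates the smallest per-term Wald p decides entry.
    When no candidate passes, the multivariate fit is skipped and reported
    as None.
    """
    univariate: dict = {}
    entered: list[str] = []
    for cov in candidates:
        fit = cox_fit(df, duration_col, event_col, [cov])
        univariate[cov] = fit
        if float(fit.summary["p"].min()) < alpha:
            entered.append(cov)
    multivariate = (
        cox_fit(df, duration_col, event_col, entered) if entered else None
    )
    return ScreenResult(univariate=univariate, multivariate=multivariate,
                        entered=entered)
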