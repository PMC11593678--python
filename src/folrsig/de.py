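"""Empirical-Bayes moderated-t differential expression.

Two-class supervised comparison (target-gene high vs low) in which each
gene's residual variance s_g^2 is shrunk toward a prior estimated from the
whole variance distribution.  Modelling s_g^2 | sigma_g^2 ~
sigma_g^2 chi^2_d / d and sigma_g^2 ~ scaled-inv-chi^2(d0, s0^2), the
posterior variance is

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and the moderated t

    t_g = (mean_high - mean_low) / (s~_g * sqrt(1/n1 + 1/n2))

follows a t distribution on d0 + d degrees of freedom under the null,
gaining power at small sample sizes.  The prior (d0, s0^2) is estimated by
method of moments on z_g = log(s_g^2), whose mean and variance under the
scaled-F sampling model are expressible through digamma/trigamma functions.

Gene selection applies three gates: p below ``p_max``, BH q below
``q_max``, and |log2 fold change| above log2(``fc_min``).  Fold change is
the difference of class means on the standardized log2 scale — the only
scale available after pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .harmonize import PooledCohort

_DF_CAP = 1e6  # stand-in for infinite df in t-distribution calls


@dataclass
class ModeratedTPrior:
    """Variance prior: d0 prior degrees of freedom (np.inf allowed), s0^2 scale."""

    d0: float
    s0_sq: float


@dataclass
class DEConfig:
    """Significance gates: p < p_max, q < q_max, linear FC > fc_min."""

    p_max: float = 0.05
    q_max: float = 0.01
    fc_min: float = 1.25

    def __post_init__(self) -> None:
        if not (0 < self.p_max < 1 and 0 < self.q_max < 1):
            raise ValueError("p_max and q_max must be in (0, 1)")
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1 (linear scale)")

    @property
    def log2fc_min(self) -> float:
        return float(np.log2(self.fc_min))


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the asymptotic starting value 0.5 + 1/x and the monotone Newton
    update on 1/y; converges quadratically for all positive x.
    """
    if x <= 0:
        raise ValueError("trigamma_inverse needs x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_eb_prior(s_sq: np.ndarray, residual_df: float) -> ModeratedTPrior:
    """Method-of-moments fit of (d0, s0^2) from observed gene variances.

    With z_g = log(s_g^2) and e_g = z_g - digamma(d/2) + log(d/2):
    E[e_g] = log(s0^2) - digamma(d0/2) + log(d0/2) and
    Var[e_g] = trigamma(d/2) + trigamma(d0/2).  Matching the sample mean
    and variance of e yields d0 via the inverse trigamma and then s0^2.
    If the excess variance is non-positive the variances are consistent
    with a single common value: d0 = +inf and s0^2 = exp(mean(e)).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq) & (s_sq > 0)]
    if len(s_sq) == 0:
        raise ValueError("no positive finite variances to fit")
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    if np.ptp(s_sq) == 0:
        # all variances identical: no dispersion to estimate a prior from
        return ModeratedTPrior(d0=np.inf, s0_sq=float(s_sq[0]))
    half_d = residual_df / 2.0
    e = np.log(s_sq) - special.digamma(half_d) + np.log(half_d)
    e_mean = float(e.mean())
    if len(s_sq) < 2:
        return ModeratedTPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, half_d))
    if e_var <= 0:
        return ModeratedTPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = trigamma_inverse(e_var)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return ModeratedTPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    values: pd.DataFrame | PooledCohort,
    labels: pd.Series,
    prior: ModeratedTPrior | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t over a high/low labelling.

    Parameters
    ----------
    values
        Genes x samples matrix (or a :class:`PooledCohort`); columns are
        restricted to samples present in ``labels``.
    labels
        Per-sample "high"/"low" labels.
    prior
        Variance prior; estimated from the data when omitted.  ``d0 = 0``
        reproduces the classical pooled-variance two-sample t exactly.

    Returns a DataFrame indexed by gene: log2fc (mean high - mean low),
    s_sq, t_mod, df_total, p, q, plus a ``zero_variance`` flag (those genes
    get p = 1).
    """
    if isinstance(values, PooledCohort):
        values = values.values
    common = values.columns.intersection(labels.index)
    values = values[common]
    lab = labels.loc[common]
    hi = values.loc[:, (lab == "high").to_numpy()]
    lo = values.loc[:, (lab == "low").to_numpy()]
    n1, n2 = hi.shape[1], lo.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both classes need >= 2 samples")
    df_res = n1 + n2 - 2
    mean_hi = hi.mean(axis=1)
    mean_lo = lo.mean(axis=1)
    log2fc = mean_hi - mean_lo
    s_sq = ((n1 - 1) * hi.var(axis=1, ddof=1) + (n2 - 1) * lo.var(axis=1, ddof=1)) / df_res
    zero_var = s_sq <= 0

    if prior is None:
        prior = fit_eb_prior(s_sq.to_numpy(), df_res)
    d0 = prior.d0
    if np.isinf(d0):
        s_post = pd.Series(prior.s0_sq, index=s_sq.index)
        df_total = _DF_CAP
    else:
        s_post = (d0 * prior.s0_sq + df_res * s_sq) / (d0 + df_res)
        df_total = min(d0 + df_res, _DF_CAP)
    denom = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / denom
    t_mod = t_mod.where(~(zero_var & (denom <= 0)), 0.0)
    p = pd.Series(
        2.0 * stats.t.sf(np.abs(t_mod.to_numpy()), df_total), index=t_mod.index
    )
    p = p.where(~zero_var, 1.0)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "s_sq": s_sq,
            "t_mod": t_mod,
            "df_total": float(df_total),
            "p": p.clip(0.0, 1.0),
            "zero_variance": zero_var,
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    out.attrs["prior"] = prior
    out.attrs["n_high"] = n1
    out.attrs["n_low"] = n2
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_genes(de: pd.DataFrame, cfg: DEConfig | None = None) -> pd.DataFrame:
    """Apply the three significance gates; rows sorted by p ascending.

    A gene passes iff p < p_max, q < q_max and |log2fc| > log2(fc_min).
    The returned frame carries a ``direction`` column (up/down in the
    high class).  An empty selection is a valid outcome.
    """
    cfg = cfg or DEConfig()
    mask = (
        (de["p"] < cfg.p_max)
        & (de["q"] < cfg.q_max)
        & (de["log2fc"].abs() > cfg.log2fc_min)
    )
    sel = de[mask].sort_values("p").copy()
    sel["direction"] = np.where(sel["log2fc"] > 0, "up", "down")
    return sel


def run_de(
    pooled: PooledCohort | pd.DataFrame,
    labels: pd.Series,
    cfg: DEConfig | None = None,
    prior: ModeratedTPrior | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Moderated t + gates in one call -> (full table, selected genes)."""
    de = moderated_t(pooled, labels, prior=prior)
    de["selected"] = de.index.isin(select_genes(de, cfg).index)
    return de, select_genes(de, cfg)
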