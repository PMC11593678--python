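"""Target-gene dichotomization and clinicopathological association battery.

The target gene is split at its median across the pooled tumor series
(ties go low), and each clinical variable is tested against the resulting
high/low classes: 2x2 odds ratios with Woolf log-interval CIs and Fisher
exact p-values for binary variables, Welch t-tests for continuous ones,
chi-square for multi-level variables (with per-level target-vs-rest odds
ratios), Pearson correlation for paired continuous measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import PooledCohort


@dataclass
class DiscretizationRule:
    gene_id: str
    cutoff: float  # median over the pooled tumor reference
    tie_policy: str = "ties_low"


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "fisher"
    zero_cell_corrected: bool = False


def median_split(
    pooled: PooledCohort, gene_id: str
) -> tuple[pd.Series, DiscretizationRule]:
    """Label every sample high/low at the pooled tumor median of ``gene_id``.

    The cutoff is the median over the reference (primary tumor) samples;
    all samples — normals included — are then labelled against it, so the
    tumor-vs-normal contrast can be expressed on the same dichotomy.
    Ties at the cutoff go to ``low``.
    """
    if gene_id not in pooled.values.index:
        raise KeyError(f"gene {gene_id!r} not in pooled matrix")
    x = pooled.values.loc[gene_id]
    ref_cols = [s for s in pooled.sample_ids if s in pooled.reference_samples]
    ref = x[ref_cols] if ref_cols else x
    if np.ptp(ref.to_numpy()) == 0:
        raise ValueError(f"degenerate split: {gene_id} constant over the series")
    cutoff = float(ref.median())
    labels = pd.Series(
        np.where(x > cutoff, "high", "low"), index=x.index, name=f"{gene_id}_class"
    )
    return labels, DiscretizationRule(gene_id=gene_id, cutoff=cutoff)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Odds ratio with Woolf 95% CI and two-sided Fisher exact p.

    Table layout::

                    feature+   feature-
        class high     a          b
        class low      c          d

    OR = (a*d)/(b*c).  With a zero cell the Haldane-Anscombe +0.5
    correction is applied to the OR and CI (flagged); the Fisher p is
    always computed on the raw counts.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any() or not np.allclose(cells, np.round(cells)):
        raise ValueError("counts must be non-negative integers")
    corrected = bool((cells == 0).any())
    work = cells + 0.5 if corrected else cells
    or_ = (work[0] * work[3]) / (work[1] * work[2])
    se = float(np.sqrt((1.0 / work).sum()))
    ci_low = float(np.exp(np.log(or_) - 1.96 * se))
    ci_high = float(np.exp(np.log(or_) + 1.96 * se))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(
        table=((int(a), int(b)), (int(c), int(d))),
        odds_ratio=float(or_),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        method="fisher",
        zero_cell_corrected=corrected,
    )


def two_group_ttest(
    values: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default) -> (t, p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    x, y = (values[labels == g] for g in groups)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("degenerate groups: zero within-group variance")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def anova_oneway(
    values: np.ndarray | pd.Series, labels: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Classical one-way ANOVA F-test over k >= 3 groups -> (F, p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 3:
        raise ValueError("fewer than 3 groups: use two_group_ttest instead")
    arrays = [values[labels == g] for g in groups]
    if any(len(arr) < 2 for arr in arrays):
        raise ValueError("each group needs >= 2 observations")
    if all(np.var(arr, ddof=1) == 0 for arr in arrays):
        raise ValueError("zero within-group variance in every group")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def pearson_correlation(
    x: np.ndarray | pd.Series, y: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Pearson r with two-sided p (t transform) -> (r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


#: variable name -> (kind, target level for the OR)
DEFAULT_TABLE_VARIABLES: dict[str, tuple[str, object]] = {
    "age": ("continuous", None),
    "histology": ("categorical", "serous"),
    "figo_stage_34": ("binary", 1),
    "high_grade": ("binary", 1),
    "macroscopic_disease": ("binary", 1),
    "platinum_sensitive": ("binary", 1),
    "tp53_mutated": ("binary", 1),
    "brca_mutated": ("binary", 1),
    "clovar_subtype": ("categorical", None),
}


def association_table(
    clinical: pd.DataFrame,
    labels: pd.Series,
    variables: dict[str, tuple[str, object]] | None = None,
) -> pd.DataFrame:
    """Build a clinicopathological association table against high/low classes.

    One row per variable: available N, counts/percentages per class for the
    target level, the target-vs-rest odds ratio with 95% CI, and a p-value
    (Fisher for binary, chi-square over the full R x 2 table for
    multi-level, Welch t for continuous).  Samples with NA in a variable
    are dropped for that variable only.
    """
    if variables is None:
        variables = {
            k: v for k, v in DEFAULT_TABLE_VARIABLES.items() if k in clinical.columns
        }
    common = clinical.index.intersection(labels.index)
    clin = clinical.loc[common]
    lab = labels.loc[common]
    rows = []
    for var, (kind, target) in variables.items():
        col = clin[var].dropna()
        grp = lab.loc[col.index]
        hi, lo = grp == "high", grp == "low"
        row: dict = {"variable": var, "n": int(len(col))}
        if kind == "continuous":
            t, p = two_group_ttest(col.to_numpy(), grp.to_numpy())
            row.update(p_value=p, mean_low=float(col[lo].mean()),
                       mean_high=float(col[hi].mean()))
        else:
            if kind == "binary" and target is None:
                target = 1
            if kind == "categorical" and target is None:
                # overall chi-square only; per-level ORs reported separately
                table = pd.crosstab(col, grp)
                chi2, p, _, _ = stats.chi2_contingency(table)
                row.update(p_value=float(p))
            else:
                is_target = col == target
                a = int((is_target & hi).sum())
                b = int((~is_target & hi).sum())
                c = int((is_target & lo).sum())
                d = int((~is_target & lo).sum())
                res = odds_ratio_2x2(a, b, c, d)
                if kind == "categorical":
                    table = pd.crosstab(col, grp)
                    _, p_all, _, _ = stats.chi2_contingency(table)
                    row["p_value"] = float(p_all)
                else:
                    row["p_value"] = res.p_value
                row.update(
                    target_level=str(target),
                    n_high_target=a,
                    n_low_target=c,
                    pct_high=100.0 * a / max(a + b, 1),
                    pct_low=100.0 * c / max(c + d, 1),
                    odds_ratio=res.odds_ratio,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
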