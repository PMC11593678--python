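"""Cross-platform cohort harmonization.

Public microarray and RNA-seq ovarian-cancer cohorts arrive on incompatible
scales (already-processed two-color intensities, summarized Affymetrix
values, TPM-like RNA-seq).  This module brings each cohort onto a common
log2 scale, forces a shared within-cohort distribution (quantile
normalization), collapses probes to one row per gene (most-variant probe),
and standardizes every cohort's genes against that cohort's primary-tumor
reference before pooling.  After pooling, a gene's value is interpretable as
"SDs away from the mean primary tumor of the same dataset", which is what
makes samples comparable across laboratories.

Raw probe-level array preprocessing (CEL parsing, background correction) is
out of scope: cohorts tagged ``raw_array`` must already be summarized to one
value per feature and are then quantile-normalized here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

PLATFORM_CLASSES = ("processed_array", "raw_array", "rnaseq")


@dataclass
class ExpressionCohort:
    """One cohort's feature-by-sample expression matrix plus metadata.

    Parameters
    ----------
    cohort_id
        Unique dataset identifier (e.g. a GEO series accession).
    values
        Features (probes or genes) x samples, ``pd.DataFrame``.  Log2 scale
        once ``is_log2`` is true.
    platform_class
        One of ``processed_array`` (quantile-normalize as-is),
        ``raw_array`` (summarized raw intensities; quantile-normalize) or
        ``rnaseq`` (log2-transform first if needed).
    probe_map
        Optional ``feature_id -> gene_id`` mapping; required before
        :func:`collapse_probes` when features are probes.
    is_log2
        Whether ``values`` is already on the log2 scale.
    """

    cohort_id: str
    values: pd.DataFrame
    platform_class: str = "processed_array"
    probe_map: pd.Series | None = None
    is_log2: bool = True

    def __post_init__(self) -> None:
        if self.platform_class not in PLATFORM_CLASSES:
            raise ValueError(
                f"platform_class must be one of {PLATFORM_CLASSES}, "
                f"got {self.platform_class!r}"
            )
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in cohort {self.cohort_id}: {dupes}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PooledCohort:
    """Standardized, gene-intersected concatenation of cohorts.

    ``values`` is genes x samples in standardized units; ``dataset_of`` maps
    every sample id to its cohort; ``reference_samples`` is the primary-tumor
    population whose per-cohort moments define the standardization.
    """

    values: pd.DataFrame
    dataset_of: pd.Series
    reference_samples: frozenset = field(default_factory=frozenset)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, cohort_id: str) -> list[str]:
        return list(self.dataset_of.index[self.dataset_of == cohort_id])


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common empirical distribution.

    The target distribution is the row-wise mean of the column-sorted
    matrix; each column's values are replaced by the target value at their
    within-column rank.  Ties receive the mean of the target values at the
    tied rank positions (the convention of standard microarray pipelines).

    A matrix with fewer than two columns is returned unchanged with a
    warning: there is no between-sample distribution to equalize.
    """
    if values.shape[1] < 2:
        warnings.warn(
            "quantile normalization needs >= 2 columns; returning input unchanged",
            stacklevel=2,
        )
        return values.copy()
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("quantile_normalize: matrix contains missing values")
    n = arr.shape[0]
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, target)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log2_transform(
    values: pd.DataFrame, already_log2: bool, offset: float = 1.0
) -> pd.DataFrame:
    """``log2(x + offset)`` for linear-scale data; identity when already log2.

    The pseudo-count ``offset`` (default +1, appropriate for TPM-like
    RNA-seq values) keeps zeros finite.  Negative linear-scale input is an
    error rather than silently producing NaNs.
    """
    if already_log2:
        return values.copy()
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log2_transform: negative values on linear scale")
    return pd.DataFrame(
        np.log2(arr + offset), index=values.index, columns=values.columns
    )


def collapse_probes(
    cohort: ExpressionCohort, return_report: bool = False
) -> ExpressionCohort | tuple[ExpressionCohort, dict]:
    """Collapse probe rows to one row per gene, keeping the most variant probe.

    For every gene with multiple mapped probes, the probe with the largest
    sample variance (ddof=1) within this cohort is retained; variance ties
    break toward the lexicographically first probe id so the result is
    deterministic.  Probes absent from ``probe_map`` are dropped and counted
    in the report.  Output gene ids are sorted lexicographically.
    """
    if cohort.probe_map is None:
        raise ValueError(f"cohort {cohort.cohort_id} has no probe_map")
    pm = cohort.probe_map.dropna()
    mapped = cohort.values.index.intersection(pm.index)
    n_unmapped = cohort.values.shape[0] - len(mapped)
    if n_unmapped:
        logger.info(
            "cohort %s: dropping %d unmapped probes", cohort.cohort_id, n_unmapped
        )
    sub = cohort.values.loc[mapped]
    variances = sub.var(axis=1, ddof=1)
    # stable winner per gene: sort by probe id, then take argmax variance
    frame = pd.DataFrame({"gene": pm.loc[mapped].values, "var": variances.values},
                         index=mapped)
    frame = frame.sort_index()
    winners = frame.groupby("gene")["var"].idxmax()
    collapsed = sub.loc[winners.values]
    collapsed.index = winners.index
    collapsed = collapsed.sort_index()
    out = replace(cohort, values=collapsed, probe_map=None)
    if return_report:
        report = {
            "n_probes_in": int(cohort.values.shape[0]),
            "n_unmapped_dropped": int(n_unmapped),
            "n_genes_out": int(collapsed.shape[0]),
        }
        return out, report
    return out


def normalize_cohort(
    cohort: ExpressionCohort,
    rnaseq_offset: float = 1.0,
    include_in_quantile: pd.Index | None = None,
) -> ExpressionCohort:
    """Per-cohort normalization dispatch by platform class.

    RNA-seq cohorts are log2(x+offset)-transformed if still linear; array
    cohorts (processed or summarized-raw) are quantile-normalized.  All
    outputs are log2-scale.
    """
    if cohort.platform_class == "rnaseq":
        values = log2_transform(cohort.values, cohort.is_log2, offset=rnaseq_offset)
    else:
        values = cohort.values if cohort.is_log2 else log2_transform(
            cohort.values, False, offset=rnaseq_offset
        )
        values = quantile_normalize(values)
    return replace(cohort, values=values, is_log2=True)


def standardize_and_pool(
    cohorts: list[ExpressionCohort],
    reference_sample_ids: set,
) -> PooledCohort:
    """Standardize each cohort against its own tumor reference and pool.

    Per cohort and per gene, the mean and SD (ddof=1) are computed over that
    cohort's samples belonging to ``reference_sample_ids`` (the primary
    tumors); *all* of the cohort's samples — including normals and other
    non-reference samples — are then centered and scaled with those same
    parameters.  Genes with any missing value within a cohort, or zero
    reference SD, are dropped from that cohort before the cross-cohort gene
    intersection.
    """
    if not cohorts:
        raise ValueError("standardize_and_pool: no cohorts supplied")
    ref = set(reference_sample_ids)
    standardized: list[pd.DataFrame] = []
    dataset_of = {}
    for cohort in cohorts:
        cohort_ref = [s for s in cohort.sample_ids if s in ref]
        if not cohort_ref:
            raise ValueError(
                f"reference set contains no samples of cohort {cohort.cohort_id}"
            )
        vals = cohort.values.dropna(axis=0)
        n_na = cohort.values.shape[0] - vals.shape[0]
        if n_na:
            logger.info("cohort %s: %d genes dropped for NA", cohort.cohort_id, n_na)
        mu = vals[cohort_ref].mean(axis=1)
        sd = vals[cohort_ref].std(axis=1, ddof=1)
        degenerate = sd <= 0
        if degenerate.any():
            logger.info(
                "cohort %s: %d genes dropped for zero reference SD",
                cohort.cohort_id,
                int(degenerate.sum()),
            )
            vals, mu, sd = vals[~degenerate], mu[~degenerate], sd[~degenerate]
        standardized.append(vals.sub(mu, axis=0).div(sd, axis=0))
        for s in cohort.sample_ids:
            dataset_of[s] = cohort.cohort_id
    common = standardized[0].index
    for frame in standardized[1:]:
        common = common.intersection(frame.index)
    common = common.sort_values()
    if len(common) == 0:
        raise ValueError("standardize_and_pool: empty gene intersection")
    pooled = pd.concat([frame.loc[common] for frame in standardized], axis=1)
    return PooledCohort(
        values=pooled,
        dataset_of=pd.Series(dataset_of, name="dataset"),
        reference_samples=frozenset(s for s in pooled.columns if s in ref),
    )


def harmonize_cohorts(
    cohorts: list[ExpressionCohort],
    reference_sample_ids: set,
    rnaseq_offset: float = 1.0,
) -> PooledCohort:
    """Full harmonization: normalize -> collapse probes -> standardize & pool."""
    processed = []
    for cohort in cohorts:
        cohort = normalize_cohort(cohort, rnaseq_offset=rnaseq_offset)
        if cohort.probe_map is not None:
            cohort = collapse_probes(cohort)
        processed.append(cohort)
    return standardize_and_pool(processed, reference_sample_ids)
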