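"""Median-centroid metagene signature: build and classify.

The signature model is the per-gene median profile of the target-high
samples of the standardized learning set, restricted to the selected
differential genes.  An independent sample is classified by the sign of
the Pearson correlation between its (standardized) expression over the
signature genes and that centroid: positive -> "high_like", otherwise
"low_like".  Because Pearson correlation is invariant to positive affine
rescaling of the sample vector, the call depends only on the sample's
expression *pattern* over the signature genes, not its overall level.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import PooledCohort

#: largest tolerated fraction of signature genes absent from a validation set
MAX_MISSING_FRACTION = 0.10


@dataclass
class SignatureModel:
    """Selected gene ids + the high-class median centroid over them."""

    gene_ids: list[str]
    centroid: np.ndarray
    learning_set_id: str = "learning"

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if len(self.gene_ids) != len(self.centroid):
            raise ValueError("centroid length must match gene_ids")
        if not np.isfinite(self.centroid).all():
            raise ValueError("centroid must be finite")

    @property
    def provenance_hash(self) -> str:
        payload = json.dumps(
            {"genes": self.gene_ids, "centroid": self.centroid.tolist()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "gene_ids": self.gene_ids,
                    "centroid": self.centroid.tolist(),
                    "learning_set_id": self.learning_set_id,
                    "sha256": self.provenance_hash,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        with open(path) as fh:
            data = json.load(fh)
        model = cls(
            gene_ids=list(data["gene_ids"]),
            centroid=np.asarray(data["centroid"], dtype=float),
            learning_set_id=data.get("learning_set_id", "learning"),
        )
        stored = data.get("sha256")
        if stored and stored != model.provenance_hash:
            raise ValueError("signature file provenance hash mismatch")
        return model


def build_centroid(
    pooled_learning: PooledCohort | pd.DataFrame,
    labels: pd.Series,
    genes: list[str],
    learning_set_id: str = "learning",
) -> SignatureModel:
    """Per-gene median over the target-high learning samples.

    ``genes`` must all be present in the learning matrix; missing ids are
    reported in the error.  At least one high-labelled sample is required.
    """
    values = pooled_learning.values if isinstance(pooled_learning, PooledCohort) else pooled_learning
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"genes missing from learning set: {missing}")
    common = values.columns.intersection(labels.index)
    lab = labels.loc[common]
    high_samples = common[(lab == "high").to_numpy()]
    if len(high_samples) == 0:
        raise ValueError("no high-labelled learning samples")
    centroid = values.loc[genes, high_samples].median(axis=1).to_numpy()
    return SignatureModel(
        gene_ids=list(genes), centroid=centroid, learning_set_id=learning_set_id
    )


def classify(
    model: SignatureModel, pooled_validation: PooledCohort | pd.DataFrame
) -> pd.DataFrame:
    """Correlation-sign classification of every validation sample.

    Returns a DataFrame indexed by sample id with columns ``r``, ``label``
    (high_like iff r > 0; r = 0 breaks to low_like) and ``flag`` (set for
    constant sample vectors, which are reported as low_like with r = 0).
    Validation sets missing more than 10% of the signature genes are
    rejected; smaller gaps restrict the correlation to the intersection.
    """
    values = (
        pooled_validation.values
        if isinstance(pooled_validation, PooledCohort)
        else pooled_validation
    )
    present = [g for g in model.gene_ids if g in values.index]
    missing_frac = 1.0 - len(present) / len(model.gene_ids)
    if missing_frac > MAX_MISSING_FRACTION:
        raise ValueError(
            f"{missing_frac:.0%} of signature genes missing from validation set "
            f"(limit {MAX_MISSING_FRACTION:.0%})"
        )
    keep = [g in values.index for g in model.gene_ids]
    centroid = model.centroid[np.asarray(keep)]
    if np.ptp(centroid) == 0:
        raise ValueError("degenerate centroid: constant over signature genes")
    sub = values.loc[present].to_numpy(dtype=float)
    c = centroid - centroid.mean()
    c_norm = np.sqrt((c**2).sum())
    x = sub - sub.mean(axis=0)
    x_norm = np.sqrt((x**2).sum(axis=0))
    flags = x_norm == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x * c[:, None]).sum(axis=0) / (x_norm * c_norm)
    r = np.where(flags, 0.0, r)
    labels = np.where(r > 0, "high_like", "low_like")
    return pd.DataFrame(
        {"r": r, "label": labels, "flag": flags},
        index=pd.Index(values.columns, name="sample_id"),
    )
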