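"""End-to-end orchestration: simulate/load -> harmonize -> associate ->
differential expression -> signature -> survival, with a reproducible run
manifest.

The learning set for differential expression defaults to the largest
cohort (mirroring the use of the biggest series as training data); the
signature is built there and applied to all remaining cohorts, whose
correlation-sign calls feed the survival validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from .association import association_table, median_split
from .de import DEConfig, run_de
from .harmonize import ExpressionCohort, harmonize_cohorts, standardize_and_pool
from .signature import SignatureModel, build_centroid, classify
from .simulate import SimConfig, SimOutput, config_to_dict, simulate, write_sim_output
from .survival import cox_fit, km_estimate, logrank_test, multivariate_screen

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """One config drives the whole pipeline."""

    outdir: str = "folrsig_run"
    target_gene: str = "FOLR1"
    learning_cohort_id: str | None = None  # default: largest cohort
    de: DEConfig = field(default_factory=DEConfig)
    sim: SimConfig | None = None  # simulate when set ...
    cohort_files: dict | None = None  # ... else load these {cohort_id: path}
    clinical_file: str | None = None
    endpoint: str = "os"  # os | pfs
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "de" in data:
            data["de"] = DEConfig(**data["de"])
        if "sim" in data and data["sim"] is not None:
            sim = dict(data["sim"])
            sim.setdefault("seed", data.get("seed", 0))
            data["sim"] = SimConfig.from_dict(sim)
        cfg = cls(**data)
        if cfg.sim is None and not cfg.cohort_files:
            raise ValueError("config needs either 'sim' or 'cohort_files'")
        if cfg.cohort_files:
            for cid, p in cfg.cohort_files.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"cohort file for {cid} not found: {p}")
        return cfg

    def canonical_dict(self) -> dict:
        data = {
            "target_gene": self.target_gene,
            "learning_cohort_id": self.learning_cohort_id,
            "de": {"p_max": self.de.p_max, "q_max": self.de.q_max,
                   "fc_min": self.de.fc_min},
            "sim": config_to_dict(self.sim) if self.sim else None,
            "cohort_files": self.cohort_files,
            "clinical_file": self.clinical_file,
            "endpoint": self.endpoint,
            "seed": self.seed,
        }
        return data

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _load_inputs(config: RunConfig) -> tuple[list[ExpressionCohort], pd.DataFrame, dict | None]:
    if config.sim is not None:
        sim: SimOutput = simulate(config.sim)
        return sim.cohorts, sim.clinical, sim.truth
    cohorts = [
        ExpressionCohort(cohort_id=cid, values=fio.read_matrix(path))
        for cid, path in config.cohort_files.items()
    ]
    clinical = fio.read_clinical(config.clinical_file)
    return cohorts, clinical, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; write artifacts + manifest; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- inputs
    cohorts, clinical, truth = _stage("load")(lambda: _load_inputs(config))
    if config.sim is not None:
        write_sim_output(SimOutput(cohorts, clinical, truth), outdir / "simulated")
    tumor_ids = set(clinical.index[clinical.get("sample_type", "tumor") == "tumor"])
    manifest["stages"]["load"] = {
        "n_cohorts": len(cohorts),
        "n_samples": int(sum(c.n_samples for c in cohorts)),
        "n_tumors": len(tumor_ids),
    }

    # --- harmonize
    pooled = _stage("harmonize")(lambda: harmonize_cohorts(cohorts, tumor_ids))
    fio.write_expression_tsv(pooled.values, outdir / "pooled.tsv")
    manifest["stages"]["harmonize"] = {
        "n_genes": len(pooled.gene_ids),
        "n_samples": len(pooled.sample_ids),
    }

    # --- median split + associations
    labels, rule = _stage("associate")(lambda: median_split(pooled, config.target_gene))
    tumor_labels = labels[labels.index.isin(tumor_ids)]
    assoc = association_table(clinical, tumor_labels)
    assoc.to_csv(outdir / "associations.tsv", sep="\t")
    manifest["stages"]["associate"] = {
        "cutoff": rule.cutoff,
        "n_high": int((tumor_labels == "high").sum()),
        "n_low": int((tumor_labels == "low").sum()),
    }

    # --- differential expression on the learning cohort
    learning_id = config.learning_cohort_id
    if learning_id is None:
        tumor_cohorts = [c for c in cohorts if set(c.sample_ids) & tumor_ids]
        learning_id = max(tumor_cohorts, key=lambda c: c.n_samples).cohort_id
    learn_samples = [s for s in pooled.samples_of(learning_id) if s in tumor_ids]
    if not learn_samples:
        raise RuntimeError(f"pipeline stage 'de' failed: learning cohort "
                           f"{learning_id!r} has no tumor samples")
    learn_values = pooled.values[learn_samples].drop(index=config.target_gene,
                                                     errors="ignore")
    de_table, selected = _stage("de")(
        lambda: run_de(learn_values, labels[learn_samples], config.de)
    )
    de_table.sort_values("p").to_csv(outdir / "de_table.tsv", sep="\t")
    selected.to_csv(outdir / "selected_genes.tsv", sep="\t")
    manifest["stages"]["de"] = {
        "learning_cohort": learning_id,
        "n_selected": int(len(selected)),
        "prior_d0": float(de_table.attrs["prior"].d0),
        "prior_s0_sq": float(de_table.attrs["prior"].s0_sq),
    }

    # --- signature build + validation classification
    validation_samples = [
        s for s in pooled.sample_ids if s not in learn_samples and s in tumor_ids
    ]
    calls = None
    if len(selected) >= 2:
        model = _stage("signature")(
            lambda: build_centroid(
                pooled.values[learn_samples], labels[learn_samples],
                list(selected.index), learning_set_id=learning_id,
            )
        )
        model.to_json(outdir / "signature.json")
        calls = classify(model, pooled.values[validation_samples])
        calls.to_csv(outdir / "signature_calls.tsv", sep="\t")
        manifest["stages"]["signature"] = {
            "n_genes": len(model.gene_ids),
            "n_classified": int(len(calls)),
            "n_high_like": int((calls["label"] == "high_like").sum()),
            "sha256": model.provenance_hash,
        }
    else:
        manifest["stages"]["signature"] = {"skipped": "fewer than 2 selected genes"}

    # --- survival on the validation calls
    tcol, ecol = f"{config.endpoint}_months", f"{config.endpoint}_event"
    if calls is not None and tcol in clinical.columns:
        surv = clinical.loc[calls.index.intersection(clinical.index)]
        surv = surv[[tcol, ecol]].dropna()
        surv["signature_high_like"] = (
            calls.loc[surv.index, "label"] == "high_like"
        ).astype(int)
        chi2, p = logrank_test(surv[tcol], surv[ecol], surv["signature_high_like"])
        fit = cox_fit(surv, tcol, ecol, ["signature_high_like"])
        km_high = km_estimate(
            surv.loc[surv["signature_high_like"] == 1, tcol],
            surv.loc[surv["signature_high_like"] == 1, ecol],
        )
        km_low = km_estimate(
            surv.loc[surv["signature_high_like"] == 0, tcol],
            surv.loc[surv["signature_high_like"] == 0, ecol],
        )
        fit.summary.to_csv(outdir / "survival_cox.tsv", sep="\t")
        manifest["stages"]["survival"] = {
            "endpoint": config.endpoint,
            "n": fit.n,
            "n_events": fit.n_events,
            "logrank_chi2": chi2,
            "logrank_p": p,
            "hr_high_like": fit.hr("signature_high_like"),
            "rate_60mo_high_like": km_high.rates.get(60.0, (float("nan"),) * 3)[0],
            "rate_60mo_low_like": km_low.rates.get(60.0, (float("nan"),) * 3)[0],
        }
    else:
        manifest["stages"]["survival"] = {"skipped": "no calls or no survival data"}

    manifest_json = json.dumps(manifest, indent=1, sort_keys=True)
    manifest["manifest_hash"] = hashlib.sha256(manifest_json.encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
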