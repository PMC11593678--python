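"""Multi-cohort expression, clinical and survival simulator.

Generates data with the statistical structure the analysis pipeline
assumes: several tumor cohorts with cohort-specific location/scale
distortions, one anchor gene (FOLR1 by default) whose latent level defines
a high/low class, a planted module of genes shifted by a stated log2 fold
change in anchor-high samples (half up-, half down-regulated), binary
clinicopathological covariates tied to the anchor class at stated odds
ratios, a small normal-tissue cohort with the anchor shifted down, and
exponential proportional-hazards survival times in which the module-high
class enjoys a planted hazard ratio.

Default effect sizes mirror the pooled ovarian-carcinoma series the
pipeline targets: 187 module genes, a protective module hazard ratio of
0.71, and covariate odds ratios / baseline prevalences matching the
clinicopathological association table (serous 2.45, FIGO III-IV 1.71,
high grade 1.45, macroscopic residue 1.10, platinum sensitivity 1.03,
TP53 mutation 1.17).

Expression is gene-wise Gaussian on the log2 scale with per-gene variances
drawn from a scaled inverse-chi-square, so the empirical-Bayes variance
prior downstream is estimable and recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import ExpressionCohort
from . import io as fio

#: covariate -> (odds ratio of the target level in anchor-high vs anchor-low,
#:               prevalence of the target level in anchor-low samples)
DEFAULT_COVARIATE_ODDS: dict[str, tuple[float, float]] = {
    "serous": (2.45, 0.89),
    "figo_stage_34": (1.71, 0.85),
    "high_grade": (1.45, 0.71),
    "macroscopic_disease": (1.10, 0.66),
    "platinum_sensitive": (1.03, 0.88),
    "tp53_mutated": (1.17, 0.97),
}

CLOVAR_SUBTYPES = ("differentiated", "immunoreactive", "mesenchymal", "proliferative")
CLOVAR_PROBS = (0.285, 0.229, 0.238, 0.248)

_MAX_FOLLOWUP_MONTHS = 243.0


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_cohorts: int = 4
    samples_per_cohort: int = 120
    n_genes: int = 2000
    n_module_genes: int = 187
    anchor_gene_id: str = "FOLR1"
    module_log2fc: float = 1.0
    anchor_noise_sd: float = 0.3
    cohort_shift_sd: float = 0.5
    cohort_scale_range: tuple[float, float] = (0.8, 1.25)
    covariate_odds: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_ODDS)
    )
    baseline_hazard: float = 0.015  # events per month; median OS ~ 46 months
    signature_hr: float = 0.71
    censor_rate: float = 0.3
    n_normals: int = 30
    normal_anchor_offset: float = 2.0  # log2 units the anchor drops in normals
    var_prior_df: float = 4.0  # d0 of the scaled-inv-chi2 gene-variance prior
    var_prior_scale: float = 0.25  # s0^2 of that prior
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cohorts", "samples_per_cohort", "n_genes",
                     "n_module_genes", "n_normals"):
            if int(getattr(self, name)) < (0 if name == "n_normals" else 1):
                raise ValueError(f"invalid SimConfig.{name}: must be >= 1")
        if self.n_module_genes >= self.n_genes:
            raise ValueError("invalid SimConfig.n_module_genes: must be < n_genes")
        if self.signature_hr <= 0:
            raise ValueError("invalid SimConfig.signature_hr: must be > 0")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("invalid SimConfig.censor_rate: must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("invalid SimConfig.baseline_hazard: must be > 0")
        lo, hi = self.cohort_scale_range
        if not (0 < lo <= hi):
            raise ValueError("invalid SimConfig.cohort_scale_range: need 0 < lo <= hi")
        for cov, (orr, prev) in self.covariate_odds.items():
            if orr <= 0 or not (0 < prev < 1):
                raise ValueError(f"invalid SimConfig.covariate_odds[{cov!r}]")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        if "cohort_scale_range" in data:
            data["cohort_scale_range"] = tuple(data["cohort_scale_range"])
        if "covariate_odds" in data:
            data["covariate_odds"] = {
                k: tuple(v) for k, v in data["covariate_odds"].items()
            }
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class SimOutput:
    """Simulated cohorts + clinical table + ground truth."""

    cohorts: list[ExpressionCohort]
    clinical: pd.DataFrame  # indexed by sample_id
    truth: dict

    @property
    def tumor_sample_ids(self) -> set:
        return set(self.clinical.index[self.clinical["sample_type"] == "tumor"])


def _gene_ids(n: int, anchor: str) -> tuple[list[str], list[str]]:
    ids = [f"G{i:05d}" for i in range(1, n)]
    return [anchor] + ids, ids


def simulate(config: SimConfig) -> SimOutput:
    """Draw one full multi-cohort dataset. Deterministic given ``config.seed``."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # fixed spawn order => per-stage reproducibility
    keys = ("genes", "biology", "cohort_fx", "covariates", "survival", "normals")
    streams = dict(zip(keys, (np.random.default_rng(s) for s in root.spawn(len(keys)))))

    n_tumors = config.n_cohorts * config.samples_per_cohort
    gene_ids, non_anchor = _gene_ids(config.n_genes, config.anchor_gene_id)

    rng_g = streams["genes"]
    base_mean = rng_g.normal(7.0, 1.0, size=config.n_genes)
    # scaled inverse chi-square: s0^2 * d0 / chi2_d0
    gene_var = (
        config.var_prior_scale
        * config.var_prior_df
        / rng_g.chisquare(config.var_prior_df, size=config.n_genes)
    )
    gene_sd = np.sqrt(gene_var)

    module_genes = sorted(rng_g.choice(non_anchor, size=config.n_module_genes,
                                       replace=False))
    module_dir = {
        g: (1 if i < (config.n_module_genes + 1) // 2 else -1)
        for i, g in enumerate(module_genes)
    }

    rng_b = streams["biology"]
    anchor_latent = rng_b.normal(0.0, 1.0, size=n_tumors)
    anchor_high = anchor_latent > np.median(anchor_latent)

    gi = {g: k for k, g in enumerate(gene_ids)}
    expr = base_mean[:, None] + gene_sd[:, None] * rng_b.normal(
        size=(config.n_genes, n_tumors)
    )
    for g in module_genes:
        expr[gi[g], anchor_high] += module_dir[g] * config.module_log2fc
    a = gi[config.anchor_gene_id]
    expr[a] = (
        base_mean[a]
        + anchor_latent
        + rng_b.normal(0.0, config.anchor_noise_sd, size=n_tumors)
    )

    sample_ids = [f"S{i:05d}" for i in range(1, n_tumors + 1)]
    cohort_of = np.repeat(
        [f"cohort_{c + 1:02d}" for c in range(config.n_cohorts)],
        config.samples_per_cohort,
    )

    # cohort effects applied after biology: per-cohort per-gene location
    # shift and a global per-cohort scale around the gene grand mean
    rng_c = streams["cohort_fx"]
    cohorts: list[ExpressionCohort] = []
    cohort_fx: list[tuple[np.ndarray, float]] = []
    lo, hi = config.cohort_scale_range
    for c in range(config.n_cohorts):
        cid = f"cohort_{c + 1:02d}"
        cols = cohort_of == cid
        shift = rng_c.normal(0.0, config.cohort_shift_sd, size=config.n_genes)
        scale = rng_c.uniform(lo, hi)
        cohort_fx.append((shift, scale))
        block = expr[:, cols]
        block = scale * (block - base_mean[:, None]) + base_mean[:, None] + shift[:, None]
        frame = pd.DataFrame(
            block, index=gene_ids, columns=[s for s, m in zip(sample_ids, cols) if m]
        )
        cohorts.append(ExpressionCohort(cohort_id=cid, values=frame,
                                        platform_class="processed_array", is_log2=True))

    # covariates tied to the anchor class at the target odds ratios
    rng_cov = streams["covariates"]
    clinical = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    clinical["dataset_id"] = cohort_of
    clinical["sample_type"] = "tumor"
    clinical["age"] = np.clip(rng_cov.normal(59.0, 10.0, size=n_tumors), 21, 90).round(1)
    for cov, (orr, p_low) in config.covariate_odds.items():
        odds_low = p_low / (1.0 - p_low)
        p_high = orr * odds_low / (1.0 + orr * odds_low)
        p = np.where(anchor_high, p_high, p_low)
        clinical[cov] = (rng_cov.uniform(size=n_tumors) < p).astype(int)
    subtype_draw = rng_cov.choice(len(CLOVAR_SUBTYPES), size=n_tumors, p=CLOVAR_PROBS)
    clinical["clovar_subtype"] = [CLOVAR_SUBTYPES[k] for k in subtype_draw]
    if "serous" in clinical.columns:
        others = ("clear_cell", "endometrioid", "mucinous", "other")
        alt = rng_cov.choice(len(others), size=n_tumors)
        clinical["histology"] = np.where(
            clinical["serous"] == 1, "serous", [others[k] for k in alt]
        )
    clinical["brca_mutated"] = (rng_cov.uniform(size=n_tumors) < 0.22).astype(int)

    # exponential PH survival: module-high class carries the planted HR
    rng_s = streams["survival"]
    hazard_class = anchor_high  # the module shifts with the anchor class
    for endpoint, base in (("os", config.baseline_hazard),
                           ("pfs", config.baseline_hazard * 1.6)):
        lam = base * np.where(hazard_class, config.signature_hr, 1.0)
        t_event = rng_s.exponential(1.0 / lam)
        if config.censor_rate > 0:
            lam_c = config.censor_rate / (1.0 - config.censor_rate) * lam.mean()
            t_cens = rng_s.exponential(1.0 / lam_c, size=n_tumors)
        else:
            t_cens = np.full(n_tumors, np.inf)
        t_cens = np.minimum(t_cens, _MAX_FOLLOWUP_MONTHS)
        time = np.minimum(t_event, t_cens)
        clinical[f"{endpoint}_months"] = np.maximum(time, 1e-3).round(3)
        clinical[f"{endpoint}_event"] = (t_event <= t_cens).astype(int)

    # normal-tissue samples: anchor shifted down, module at baseline.
    # They join the first cohort (sharing its batch effects), as normals in
    # public series co-occur with tumors — a lone normals-only cohort would
    # have no tumor reference to standardize against.
    if config.n_normals > 0:
        rng_n = streams["normals"]
        nexpr = base_mean[:, None] + gene_sd[:, None] * rng_n.normal(
            size=(config.n_genes, config.n_normals)
        )
        nexpr[a] = (
            base_mean[a]
            - config.normal_anchor_offset
            + rng_n.normal(0.0, 1.0, size=config.n_normals)
        )
        shift, scale = cohort_fx[0]
        nexpr = scale * (nexpr - base_mean[:, None]) + base_mean[:, None] + shift[:, None]
        normal_ids = [f"N{i:04d}" for i in range(1, config.n_normals + 1)]
        host = cohorts[0]
        merged = pd.concat(
            [host.values,
             pd.DataFrame(nexpr, index=gene_ids, columns=normal_ids)], axis=1
        )
        cohorts[0] = ExpressionCohort(
            cohort_id=host.cohort_id, values=merged,
            platform_class=host.platform_class, is_log2=True,
        )
        normal_clin = pd.DataFrame(index=pd.Index(normal_ids, name="sample_id"))
        normal_clin["dataset_id"] = host.cohort_id
        normal_clin["sample_type"] = "normal"
        clinical = pd.concat([clinical, normal_clin])

    truth = {
        "module_genes": list(module_genes),
        "module_directions": {g: int(d) for g, d in module_dir.items()},
        "anchor_class": {
            s: ("high" if h else "low") for s, h in zip(sample_ids, anchor_high)
        },
        "hazard_class": {
            s: ("high" if h else "low") for s, h in zip(sample_ids, hazard_class)
        },
    }
    return SimOutput(cohorts=cohorts, clinical=clinical, truth=truth)


def write_sim_output(sim: SimOutput, outdir: str | Path) -> None:
    """Write one expression TSV per cohort, clinical.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cohort in sim.cohorts:
        fio.write_expression_tsv(cohort.values, outdir / f"{cohort.cohort_id}.tsv")
    fio.write_clinical(sim.clinical, outdir / "clinical.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sim.truth, fh, indent=1, sort_keys=True)


def config_to_dict(config: SimConfig) -> dict:
    data = asdict(config)
    data["cohort_scale_range"] = list(config.cohort_scale_range)
    data["covariate_odds"] = {k: list(v) for k, v in config.covariate_odds.items()}
    return data
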