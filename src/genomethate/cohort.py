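"""Synthetic input cohort emulating the real lipid-lowering trial data.

The real genotype/methylation/phenotype files are access-restricted, so this
module builds a statistically similar stand-in from published parameters:
717 unrelated subjects; per-SNP dosages ~ Binomial(2, coded allele frequency);
causal-CpG visit-2 betas from clipped Normals with the published means/SDs;
red-herring and background CpG betas from a Beta distribution; log-normal
triglycerides with a modest treatment decline; treatment durations under 30
days (visit 1/2 and visit 3/4 pairs one day apart); and whole-array visit-4
methylation missingness for a configurable fraction of subjects.

Subjects are simulated as unrelated founders — the source study's family
structure matters for power studies, not for the simulator's equations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylation import MethylationPanel
from .spec import ModelSpec

__all__ = ["CohortConfig", "CohortData", "gen_genotypes", "gen_methylation",
           "gen_phenotypes", "gen_cohort"]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort.

    TG log-moments are not published; ln(120) mg/dL baseline with SD 0.5 and a
    mean treatment decline of -0.25 log-units (SD 0.15) give realistic
    triglyceride ranges for a hypertriglyceridemic trial population.  The
    within-pair jitter (SD 0.05) is the day-to-day biological/measurement
    variation between the two visits of a pair.  The real fraction of subjects
    lacking a visit-4 methylation array is not published; 0.5 exercises both
    anchoring branches.
    """

    n_subjects: int = 717
    n_background_cpgs: int = 10
    background_beta_a: float = 2.0
    background_beta_b: float = 2.0
    tg_log_mean: float = math.log(120.0)
    tg_log_sd: float = 0.5
    tg_delta_mean: float = -0.25
    tg_delta_sd: float = 0.15
    tg_pair_jitter_sd: float = 0.05
    days_range: tuple[int, int] = (14, 28)
    v4_missing_frac: float = 0.5
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        lo, hi = self.days_range
        if not (0 < lo <= hi < 30):
            raise ValueError("days_range must lie within (0, 30)")
        if not 0 <= self.v4_missing_frac <= 1:
            raise ValueError("v4_missing_frac must be in [0, 1]")


@dataclass
class CohortData:
    """Raw per-subject inputs the simulator consumes."""

    genotypes: pd.DataFrame  # subjects x SNPs, additive dosages
    methylation: MethylationPanel
    phenotypes: pd.DataFrame  # subject_id, TG1..TG4, DRAWDATE_V2..V4
    config: CohortConfig | None = None

    @property
    def subjects(self) -> pd.Index:
        return self.genotypes.index


def _subject_ids(n: int) -> pd.Index:
    return pd.Index([f"S{j + 1:04d}" for j in range(n)], name="subject_id")


def gen_genotypes(
    spec: ModelSpec, cfg: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Independent dosages ~ Binomial(2, coded_af) per SNP; monomorphic
    columns are redrawn so every SNP is polymorphic in the sample."""
    n = cfg.n_subjects
    cols = {}
    for snp in spec.snps:
        d = rng.binomial(2, snp.coded_allele_freq, size=n)
        while d.std() == 0:  # near-fixed alleles can come out constant
            d = rng.binomial(2, snp.coded_allele_freq, size=n)
        cols[snp.marker_name] = d
    return pd.DataFrame(cols, index=_subject_ids(n), dtype=float)


def gen_methylation(
    spec: ModelSpec, cfg: CohortConfig, rng: np.random.Generator
) -> MethylationPanel:
    """Visit-2 betas for every named site (plus generic background sites) and
    visit-4 betas for the subjects who "have" a real visit-4 array."""
    n = cfg.n_subjects
    ids = _subject_ids(n)

    def causal_draw(site):
        if site.v2_mean is None or site.v2_sd is None:
            raise ValueError(f"{site.cpg_name}: causal site lacks v2 moments")
        return np.clip(rng.normal(site.v2_mean, site.v2_sd, size=n), 0.0, 1.0)

    def beta_draw():
        return rng.beta(cfg.background_beta_a, cfg.background_beta_b, size=n)

    bg_names = [f"cg_bg_{i + 1:04d}" for i in range(cfg.n_background_cpgs)]
    v2, v4 = {}, {}
    for site in spec.cpgs:
        if site.site_class == "causal":
            v2[site.cpg_name] = causal_draw(site)
            v4[site.cpg_name] = causal_draw(site)
        else:
            v2[site.cpg_name] = beta_draw()
            v4[site.cpg_name] = beta_draw()
    for name in bg_names:
        v2[name] = beta_draw()
        v4[name] = beta_draw()

    v2_df = pd.DataFrame(v2, index=ids)
    v4_df = pd.DataFrame(v4, index=ids)
    has_v4 = rng.random(n) >= cfg.v4_missing_frac  # whole-array missingness
    return MethylationPanel(v2=v2_df, v4=v4_df.loc[has_v4])


def gen_phenotypes(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Log-normal TG at the four visits plus draw-day numbers.

    Visits 1/2 and 3/4 are one day apart; the mean of the visit-3/4 days minus
    the visit-2 day is uniform over ``days_range``.
    """
    n = cfg.n_subjects
    pre = rng.normal(cfg.tg_log_mean, cfg.tg_log_sd, size=n)
    post = pre + rng.normal(cfg.tg_delta_mean, cfg.tg_delta_sd, size=n)
    jit = lambda: rng.normal(0.0, cfg.tg_pair_jitter_sd, size=n)
    tg1, tg2 = np.exp(pre + jit()), np.exp(pre + jit())
    tg3, tg4 = np.exp(post + jit()), np.exp(post + jit())

    v2_day = rng.integers(1, 301, size=n)
    lo, hi = cfg.days_range
    # v3 = v2 + m, v4 = v3 + 1 => daysRx = m + 0.5, kept inside [lo, hi]
    m = rng.integers(lo, hi, size=n)
    v3_day = v2_day + m
    v4_day = v3_day + 1

    return pd.DataFrame(
        {
            "subject_id": _subject_ids(n),
            "TG1": tg1, "TG2": tg2, "TG3": tg3, "TG4": tg4,
            "DRAWDATE_V2": v2_day, "DRAWDATE_V3": v3_day, "DRAWDATE_V4": v4_day,
        }
    )


def gen_cohort(spec: ModelSpec, cfg: CohortConfig | None = None) -> CohortData:
    """Generate a complete synthetic cohort (deterministic in cfg.seed)."""
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    genotypes = gen_genotypes(spec, cfg, rng)
    methylation = gen_methylation(spec, cfg, rng)
    phenotypes = gen_phenotypes(cfg, rng)
    return CohortData(genotypes, methylation, phenotypes, cfg)
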