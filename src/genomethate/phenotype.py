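"""From simulated methylation + genotypes to simulated slopes and TG values.

The standardized drug-response slope for subject j in replicate k is

    slope[j,k] = sum_{i in major} (1 - meth[j,i,k]) * sqrt(hg2_i) * SSNP[j,i]
               + sum_{i in background}              sqrt(hg2_i) * SSNP[j,i]
               + zenv[j,k] * sqrt(1 - sum_i hg2_i)

where SSNP is the column-standardized dosage matrix and meth is the simulated
(truncated) visit-4 beta of the CpG gating each major SNP: fully methylated
silences the SNP, partial methylation attenuates it proportionally.  The slope
is then blended with the standardized baseline to induce the observed
slope/baseline correlation, rescaled to the observed slope scale, projected to
a post-treatment log-TG level, and finally exponentiated into visit-3/4 TG
values that preserve each subject's real within-pair visit deviation.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .spec import ModelSpec, effect_coefficient

__all__ = [
    "MonomorphicSnpError",
    "standardize_genotypes",
    "draw_zenv",
    "draw_slope",
    "apply_baseline_correlation",
    "rescale_slope",
    "project_postRx",
    "emit_tg",
]

_ZENV_STREAM = 2  # substream tag; methylation noise uses 1


class MonomorphicSnpError(ValueError):
    """A SNP column has zero variance and cannot be standardized."""


def standardize_genotypes(dosage: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise z-scores of the additive dosage matrix (n-1 SD)."""
    vals = dosage.to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("dosage matrix contains missing values")
    sd = vals.std(axis=0, ddof=ddof)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise MonomorphicSnpError(
            f"monomorphic SNP(s): {list(dosage.columns[flat])}"
        )
    z = (vals - vals.mean(axis=0)) / sd
    return pd.DataFrame(z, index=dosage.index, columns=dosage.columns)


def draw_zenv(spec: ModelSpec, k: int, n_subjects: int) -> np.ndarray:
    """Residual N(0,1) draws for replicate k, from a dedicated stream.

    Kept separate from the methylation stream so methylation and phenotype
    noise can be replayed independently.
    """
    rng = np.random.default_rng([spec.base_seed, k, _ZENV_STREAM])
    return rng.standard_normal(n_subjects)


def draw_slope(
    ssnp: pd.DataFrame,
    causal_meth: pd.DataFrame,
    spec: ModelSpec,
    zenv: np.ndarray,
    force_meth: float | None = None,
) -> np.ndarray:
    """Standardized simulated slope per subject for one replicate.

    ``causal_meth`` must contain a column for each causal CpG.  ``force_meth``
    replaces every causal methylation value with a constant before it enters
    the attenuation term (an intervention used by validation: 0 exposes the
    full genetic effects, 1 silences them), without touching the methylation
    output itself.
    """
    missing = [s.marker_name for s in spec.major_snps if s.marker_name not in ssnp.columns]
    missing += [s.marker_name for s in spec.background_snps if s.marker_name not in ssnp.columns]
    if missing:
        raise ValueError(f"SSNP matrix lacks SNPs named in the spec: {missing[:5]}")

    n = len(ssnp)
    slope = np.zeros(n)
    for snp in spec.major_snps:
        cpg = spec.causal_cpg_for_snp(snp.marker_name)
        if force_meth is None:
            if cpg.cpg_name not in causal_meth.columns:
                raise ValueError(
                    f"simulated methylation lacks causal CpG {cpg.cpg_name}"
                )
            meth = causal_meth[cpg.cpg_name].to_numpy(float)
        else:
            meth = np.full(n, float(force_meth))
        slope += (1.0 - meth) * effect_coefficient(snp) * ssnp[snp.marker_name].to_numpy(float)
    for snp in spec.background_snps:
        slope += effect_coefficient(snp) * ssnp[snp.marker_name].to_numpy(float)
    return slope + np.asarray(zenv, float) * spec.residual_scale


def apply_baseline_correlation(
    slope: np.ndarray, preZ: np.ndarray, corr_baseline: float
) -> np.ndarray:
    """Blend the slope with the standardized baseline:
    corrz = corr * preZ + sqrt(1 - corr^2) * slope."""
    if not abs(corr_baseline) < 1:
        raise ValueError(f"|corr_baseline| must be < 1, got {corr_baseline}")
    return corr_baseline * np.asarray(preZ, float) + math.sqrt(
        1.0 - corr_baseline**2
    ) * np.asarray(slope, float)


def rescale_slope(corrz: np.ndarray, mean_slope: float, sd_slope: float) -> np.ndarray:
    """Affine map from the standardized scale to observed log-TG/day units."""
    if sd_slope <= 0:
        raise ValueError("sd of observed slopes must be positive")
    return np.asarray(corrz, float) * sd_slope + mean_slope


def project_postRx(
    sim_slope: np.ndarray, daysRx: np.ndarray, preRx: np.ndarray
) -> np.ndarray:
    """Linear growth-curve projection: post = slope * days + pre (log scale).

    Missing daysRx or preRx propagates to a missing projection.
    """
    return np.asarray(sim_slope, float) * np.asarray(daysRx, float) + np.asarray(
        preRx, float
    )


def emit_tg(
    sim_postRx: np.ndarray,
    tg3: np.ndarray,
    tg4: np.ndarray,
    postRx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-transform to visit-3/4 TG (mg/dL), keeping each subject's real
    within-pair deviation:

        sim_TG3 = exp[sim_postRx + (ln TG3 - O_postRx)]
        sim_TG4 = exp[sim_postRx + (ln TG4 - O_postRx)]

    so mean(ln sim_TG3, ln sim_TG4) == sim_postRx exactly.  Missing real
    post-treatment data propagates to missing outputs.
    """
    sim_postRx = np.asarray(sim_postRx, float)
    postRx = np.asarray(postRx, float)
    with np.errstate(invalid="ignore"):
        sim_tg3 = np.exp(sim_postRx + (np.log(np.asarray(tg3, float)) - postRx))
        sim_tg4 = np.exp(sim_postRx + (np.log(np.asarray(tg4, float)) - postRx))
    return sim_tg3, sim_tg4
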