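"""Replicate orchestration: cohort in, simulated methylation + TG out.

One replicate = one independent re-draw of all post-treatment data (visit-4
methylation, then the slope and visit-3/4 TG) for the same fixed cohort
baseline.  Replicates are seeded individually from (base_seed, k) so they can
be produced in any order, or in parallel, with identical results.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .baseline import ObservedBaseline, derive_baseline
from .cohort import CohortData
from .methylation import SimulatedMethylation, simulate_v4
from .phenotype import (
    apply_baseline_correlation,
    draw_slope,
    draw_zenv,
    emit_tg,
    project_postRx,
    rescale_slope,
    standardize_genotypes,
)
from .spec import ModelSpec

__all__ = ["ReplicateOutput", "SimulationRun", "prepare_run", "simulate_replicate",
           "simulate_replicates"]


@dataclass
class ReplicateOutput:
    """Everything simulated for one replicate.

    ``tg`` has columns subject_id, SIMTG3, SIMTG4 (mg/dL); ``diagnostics``
    (optional) adds the standardized slope, baseline-correlated slope,
    rescaled slope and projected post-treatment log-TG.
    """

    replicate: int
    methylation: SimulatedMethylation
    tg: pd.DataFrame
    diagnostics: pd.DataFrame | None = None


@dataclass
class SimulationRun:
    """Cohort-level quantities computed once and reused by every replicate."""

    cohort: CohortData
    spec: ModelSpec
    baseline: ObservedBaseline
    ssnp: pd.DataFrame


def prepare_run(cohort: CohortData, spec: ModelSpec) -> SimulationRun:
    baseline = derive_baseline(cohort.phenotypes)
    ssnp = standardize_genotypes(cohort.genotypes)
    return SimulationRun(cohort, spec, baseline, ssnp)


def simulate_replicate(
    run: SimulationRun,
    k: int,
    force_meth: float | None = None,
    keep_raw: bool = False,
    diagnostics: bool = False,
) -> ReplicateOutput:
    """Simulate replicate k end to end.

    ``force_meth`` overrides the causal methylation entering the slope model
    (0 = no silencing, 1 = full silencing) without changing the methylation
    output files; it is a validation intervention, not a data edit.
    """
    spec = run.spec
    base = run.baseline.table
    sim_meth = simulate_v4(run.cohort.methylation, spec, k, keep_raw=keep_raw)

    zenv = draw_zenv(spec, k, len(run.ssnp))
    slope = draw_slope(run.ssnp, sim_meth.v4_sim, spec, zenv, force_meth=force_meth)
    corrz = apply_baseline_correlation(
        slope, base["O_preZ"].to_numpy(), spec.corr_baseline
    )
    sim_slope = rescale_slope(corrz, run.baseline.mean_slope, run.baseline.sd_slope)
    sim_post = project_postRx(
        sim_slope, base["O_daysRx"].to_numpy(), base["O_preRx_TG"].to_numpy()
    )
    pheno = run.cohort.phenotypes
    sim_tg3, sim_tg4 = emit_tg(
        sim_post,
        pheno["TG3"].to_numpy(float),
        pheno["TG4"].to_numpy(float),
        base["O_postRx_TG"].to_numpy(),
    )

    tg = pd.DataFrame(
        {"subject_id": pheno["subject_id"].to_numpy(), "SIMTG3": sim_tg3, "SIMTG4": sim_tg4}
    )
    diag = None
    if diagnostics:
        diag = pd.DataFrame(
            {
                "subject_id": pheno["subject_id"].to_numpy(),
                "slope_jk": slope,
                "corrz_jk": corrz,
                "sim_slope_jk": sim_slope,
                "sim_postRx_TG_jk": sim_post,
            }
        )
    return ReplicateOutput(k, sim_meth, tg, diag)


def simulate_replicates(
    cohort: CohortData,
    spec: ModelSpec,
    replicates: range | list[int] | None = None,
    force_meth: float | None = None,
    keep_raw: bool = False,
    diagnostics: bool = False,
) -> Iterator[ReplicateOutput]:
    """Yield ReplicateOutput for k = 1..R (or the given replicate indices)."""
    run = prepare_run(cohort, spec)
    if replicates is None:
        replicates = range(1, spec.n_replicates + 1)
    for k in replicates:
        yield simulate_replicate(
            run, k, force_meth=force_meth, keep_raw=keep_raw, diagnostics=diagnostics
        )
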