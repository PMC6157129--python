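"""Simulated visit-4 methylation: anchor + N(0, sd_i) noise, clipped to [0, 1].

Per subject j, CpG site i and replicate k the simulated visit-4 beta value is

    sim_meth_v4[j,i,k] = clip(anchor[j,i] + sd_i * Z1[j,i,k], 0, 1)

with one independent standard-normal draw per (j, i, k).  The anchor is the
subject's real visit-2 value for causal sites (always — the treatment response
is modelled as a fresh excursion from the pre-treatment state), and the real
visit-4 value for non-causal sites when the subject has a visit-4 array,
falling back to visit 2 otherwise.  sd_i is 0.4 for causal and red-herring
sites and 0.03 (measurement-error level) for everything else, so on average
treatment does not move methylation — it only spreads it.

Truncation is censoring: out-of-range values are clamped to the boundary, not
redrawn.  This is what produces the heavy ~0.33 visit-4 SDs from a 0.4 noise
SD on interior anchors.

Reproducibility contract: the noise for replicate k comes from a dedicated
stream seeded by (base_seed, k), drawn subject-major / site-minor, so any
subset of replicates can be regenerated in any order bit-identically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._defaults import SD_BACKGROUND
from .spec import CpgSite, ModelSpec

__all__ = [
    "MethylationPanel",
    "SimulatedMethylation",
    "site_for",
    "base_value",
    "anchor_matrix",
    "simulate_v4",
    "v4_moments",
]

_METH_STREAM = 1  # substream tag; the phenotype residual stream uses 2


@dataclass
class MethylationPanel:
    """Real methylation input: visit-2 betas for everyone, visit-4 for some.

    ``v2`` is subjects x sites; ``v4`` holds only the rows of subjects who
    have a real visit-4 array (whole-array missingness — a subject either has
    every site at visit 4 or none).
    """

    v2: pd.DataFrame
    v4: pd.DataFrame

    def __post_init__(self) -> None:
        missing_sites = set(self.v4.columns) - set(self.v2.columns)
        if missing_sites:
            raise ValueError(f"v4 has sites absent from v2: {sorted(missing_sites)}")
        extra = set(self.v4.index) - set(self.v2.index)
        if extra:
            raise ValueError(f"v4 has subjects absent from v2: {sorted(extra)[:5]}")
        for name, df in (("v2", self.v2), ("v4", self.v4)):
            vals = df.to_numpy(float)
            if np.isnan(vals).any():
                raise ValueError(f"{name} contains missing values within an array")
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{name} beta values outside [0, 1]")

    @property
    def sites(self) -> list[str]:
        return list(self.v2.columns)

    @property
    def subjects(self) -> pd.Index:
        return self.v2.index

    def has_v4(self) -> pd.Series:
        return pd.Series(self.v2.index.isin(self.v4.index), index=self.v2.index)


@dataclass
class SimulatedMethylation:
    """One replicate's simulated visit-4 betas (and optionally the raw,
    pre-truncation values for diagnostics)."""

    replicate: int
    v4_sim: pd.DataFrame
    raw_v4: pd.DataFrame | None = None


def site_for(name: str, spec: ModelSpec) -> CpgSite:
    """Resolve a panel column to its CpgSite.

    Columns not named in the spec are background sites (sd 0.03) — the model
    only singles out the 5 causal and 5 red-herring sites, everything else on
    the array behaves identically.
    """
    try:
        return spec.cpg(name)
    except KeyError:
        return CpgSite(name, 0, 0, "background", SD_BACKGROUND)


def base_value(site: CpgSite, subject, panel: MethylationPanel) -> float:
    """Anchor of the simulated visit-4 value for one subject and site.

    Causal sites always anchor on visit 2; other sites anchor on the real
    visit 4 when the subject has one, else on visit 2.
    """
    if site.cpg_name not in panel.v2.columns:
        raise ValueError(f"subject {subject!r} has no visit-2 value for {site.cpg_name}")
    if site.site_class != "causal" and subject in panel.v4.index:
        return float(panel.v4.at[subject, site.cpg_name])
    return float(panel.v2.at[subject, site.cpg_name])


def anchor_matrix(panel: MethylationPanel, spec: ModelSpec) -> pd.DataFrame:
    """Vectorized anchors for every subject and panel site."""
    anchors = panel.v2.copy().astype(float)
    if len(panel.v4):
        v4_subjects = panel.v4.index
        for name in panel.sites:
            if site_for(name, spec).site_class == "causal":
                continue
            if name in panel.v4.columns:
                anchors.loc[v4_subjects, name] = panel.v4[name].astype(float)
    return anchors


def noise_sd_vector(panel: MethylationPanel, spec: ModelSpec) -> np.ndarray:
    return np.array([site_for(name, spec).sd_response for name in panel.sites])


def simulate_v4(
    panel: MethylationPanel,
    spec: ModelSpec,
    k: int,
    keep_raw: bool = False,
) -> SimulatedMethylation:
    """Simulate one replicate of visit-4 methylation for the whole panel."""
    rng = np.random.default_rng([spec.base_seed, k, _METH_STREAM])
    anchors = anchor_matrix(panel, spec).to_numpy(float)
    sd = noise_sd_vector(panel, spec)
    z = rng.standard_normal(anchors.shape)  # row-major: subject-major, site-minor
    raw = anchors + sd[np.newaxis, :] * z
    sim = np.clip(raw, 0.0, 1.0)
    frame = lambda a: pd.DataFrame(a, index=panel.subjects, columns=panel.sites)
    return SimulatedMethylation(
        replicate=k,
        v4_sim=frame(sim),
        raw_v4=frame(raw) if keep_raw else None,
    )


def v4_moments(
    sims: SimulatedMethylation | list[SimulatedMethylation],
    site: str,
) -> tuple[float, float]:
    """Mean and SD (n-1) of simulated visit-4 betas at one site.

    With a single replicate the moments are across subjects (matching how the
    published per-site visit-4 moments read); with a list they are pooled
    across subjects and replicates.
    """
    if isinstance(sims, SimulatedMethylation):
        vals = sims.v4_sim[site].to_numpy(float)
    else:
        vals = np.concatenate([s.v4_sim[site].to_numpy(float) for s in sims])
    return float(vals.mean()), float(vals.std(ddof=1))
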