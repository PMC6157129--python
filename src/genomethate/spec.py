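"""Model specification: the causal architecture of the simulation.

The simulator's behaviour is fully determined by a :class:`ModelSpec` — which
SNPs drive the drug-response slope and how strongly (``hg2``), which CpG site
gates each major SNP, what noise each CpG class carries, the slope/baseline
correlation constant, and the replicate count and seed.  The defaults compiled
into :func:`default_spec` reproduce the published architecture: 5 major causal
SNPs paired with their nearest CpG sites, 100 background polygenic SNPs with
hg2 = 0.001, and 5 red-herring CpG sites.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import _defaults as D

__all__ = [
    "SnpEffect",
    "CpgSite",
    "ModelSpec",
    "SpecError",
    "default_spec",
    "load_spec",
    "serialize_spec",
    "effect_coefficient",
]


class SpecError(ValueError):
    """A model specification violates one of its invariants."""


@dataclass(frozen=True)
class SnpEffect:
    """One SNP's contribution to the standardized drug-response slope.

    ``hg2`` is the fraction of slope variance the SNP explains when its gating
    CpG (if any) is fully unmethylated; the regression coefficient applied to
    the standardized dosage is ``sqrt(hg2)``.
    """

    marker_name: str
    chromosome: int
    position_bp: int
    role: str  # "major" | "background"
    hg2: float
    coded_allele_freq: float = 0.3

    def __post_init__(self) -> None:
        if self.role not in ("major", "background"):
            raise SpecError(f"{self.marker_name}: unknown role {self.role!r}")
        if self.hg2 < 0 or self.hg2 >= 1:
            raise SpecError(f"{self.marker_name}: hg2 must be in [0, 1), got {self.hg2}")
        if not 0 < self.coded_allele_freq < 1:
            raise SpecError(
                f"{self.marker_name}: coded_allele_freq must be in (0, 1), "
                f"got {self.coded_allele_freq}"
            )


@dataclass(frozen=True)
class CpgSite:
    """A CpG site and its role in the simulation.

    ``site_class`` decides both the noise SD of the simulated visit-4 value
    (0.4 for causal and red_herring, 0.03 for background) and, for causal
    sites, which major SNP's effect the site's methylation level silences.
    ``v2_mean``/``v2_sd`` are the published visit-2 beta moments used by the
    synthetic-cohort generator; ``v4_ref_mean``/``v4_ref_sd`` are the published
    simulated visit-4 moments kept for validation.
    """

    cpg_name: str
    chromosome: int
    position_bp: int
    site_class: str  # "causal" | "red_herring" | "background"
    sd_response: float
    linked_snp: str | None = None
    v2_mean: float | None = None
    v2_sd: float | None = None
    v4_ref_mean: float | None = None
    v4_ref_sd: float | None = None

    def __post_init__(self) -> None:
        if self.site_class not in ("causal", "red_herring", "background"):
            raise SpecError(f"{self.cpg_name}: unknown site_class {self.site_class!r}")
        if self.sd_response < 0:
            raise SpecError(f"{self.cpg_name}: sd_response must be >= 0")
        if self.site_class == "causal" and not self.linked_snp:
            raise SpecError(f"{self.cpg_name}: causal CpG site needs a linked_snp")


@dataclass
class ModelSpec:
    """Complete causal architecture plus global simulation constants."""

    snps: list[SnpEffect]
    cpgs: list[CpgSite]
    corr_baseline: float = D.CORR_BASELINE
    n_replicates: int = D.N_REPLICATES
    base_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views -----------------------------------------------------
    @property
    def major_snps(self) -> list[SnpEffect]:
        return [s for s in self.snps if s.role == "major"]

    @property
    def background_snps(self) -> list[SnpEffect]:
        return [s for s in self.snps if s.role == "background"]

    @property
    def causal_cpgs(self) -> list[CpgSite]:
        return [c for c in self.cpgs if c.site_class == "causal"]

    @property
    def red_herring_cpgs(self) -> list[CpgSite]:
        return [c for c in self.cpgs if c.site_class == "red_herring"]

    @property
    def total_hg2(self) -> float:
        return sum(s.hg2 for s in self.snps)

    @property
    def residual_scale(self) -> float:
        """sqrt(1 - sum hg2): SD of the residual slope component.

        Always recomputed from ``snps`` so it can never go stale.
        """
        return math.sqrt(1.0 - self.total_hg2)

    def snp(self, name: str) -> SnpEffect:
        for s in self.snps:
            if s.marker_name == name:
                return s
        raise KeyError(name)

    def cpg(self, name: str) -> CpgSite:
        for c in self.cpgs:
            if c.cpg_name == name:
                return c
        raise KeyError(name)

    def causal_cpg_for_snp(self, marker_name: str) -> CpgSite:
        for c in self.causal_cpgs:
            if c.linked_snp == marker_name:
                return c
        raise KeyError(f"no causal CpG linked to {marker_name}")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        snp_names = [s.marker_name for s in self.snps]
        dup = {n for n in snp_names if snp_names.count(n) > 1}
        if dup:
            raise SpecError(f"duplicate SNP marker names: {sorted(dup)}")
        cpg_names = [c.cpg_name for c in self.cpgs]
        dup = {n for n in cpg_names if cpg_names.count(n) > 1}
        if dup:
            raise SpecError(f"duplicate CpG names: {sorted(dup)}")
        majors = {s.marker_name for s in self.major_snps}
        for c in self.causal_cpgs:
            if c.linked_snp not in majors:
                raise SpecError(
                    f"{c.cpg_name}: linked_snp {c.linked_snp!r} is not a major SNP"
                )
        if self.total_hg2 >= 1:
            worst = max(self.snps, key=lambda s: s.hg2)
            raise SpecError(
                f"sum of hg2 is {self.total_hg2:.4f} >= 1 "
                f"(largest contribution: {worst.marker_name} with {worst.hg2})"
            )
        if not abs(self.corr_baseline) < 1:
            raise SpecError(f"|corr_baseline| must be < 1, got {self.corr_baseline}")
        if self.n_replicates < 1:
            raise SpecError("n_replicates must be >= 1")


def effect_coefficient(snp: SnpEffect) -> float:
    """Regression coefficient of the standardized dosage: sqrt(hg2)."""
    if snp.hg2 < 0:
        raise SpecError(f"{snp.marker_name}: negative hg2")
    return math.sqrt(snp.hg2)


def default_spec(base_seed: int = 0) -> ModelSpec:
    """The published default architecture (105 SNPs, 10 named CpG sites)."""
    snps = [
        SnpEffect(name, chrom, pos, "major", hg2)
        for (name, chrom, pos, hg2) in D.MAJOR_SNPS
    ]
    snps += [
        SnpEffect(name, chrom, pos, "background", D.BACKGROUND_HG2, af)
        for (name, chrom, pos, af) in D.BACKGROUND_SNPS
    ]
    cpgs = [
        CpgSite(name, chrom, pos, "causal", D.SD_CAUSAL, linked_snp=snp,
                v2_mean=m2, v2_sd=s2, v4_ref_mean=m4, v4_ref_sd=s4)
        for (name, chrom, pos, m2, s2, m4, s4, snp) in D.CAUSAL_CPGS
    ]
    cpgs += [
        CpgSite(name, chrom, pos, "red_herring", D.SD_CAUSAL)
        for (name, chrom, pos) in D.RED_HERRING_CPGS
    ]
    return ModelSpec(snps=snps, cpgs=cpgs, base_seed=base_seed)


def _build_snp(entry: Mapping[str, Any]) -> SnpEffect:
    return SnpEffect(
        marker_name=entry["marker_name"],
        chromosome=int(entry.get("chromosome", 0)),
        position_bp=int(entry.get("position_bp", 0)),
        role=entry.get("role", "background"),
        hg2=float(entry.get("hg2", D.BACKGROUND_HG2)),
        coded_allele_freq=float(entry.get("coded_allele_freq", 0.3)),
    )


def _build_cpg(entry: Mapping[str, Any]) -> CpgSite:
    cls = entry.get("site_class", "background")
    default_sd = D.SD_CAUSAL if cls in ("causal", "red_herring") else D.SD_BACKGROUND
    return CpgSite(
        cpg_name=entry["cpg_name"],
        chromosome=int(entry.get("chromosome", 0)),
        position_bp=int(entry.get("position_bp", 0)),
        site_class=cls,
        sd_response=float(entry.get("sd_response", default_sd)),
        linked_snp=entry.get("linked_snp"),
        v2_mean=entry.get("v2_mean"),
        v2_sd=entry.get("v2_sd"),
        v4_ref_mean=entry.get("v4_ref_mean"),
        v4_ref_sd=entry.get("v4_ref_sd"),
    )


def load_spec(config_source: str | Path | Mapping[str, Any] | None = None) -> ModelSpec:
    """Build a validated ModelSpec from a YAML/JSON config, dict, or nothing.

    Omitted fields take the compiled-in defaults, so an empty (or absent)
    config reproduces the published model exactly.  Recognized keys:
    ``corr_baseline``, ``n_replicates``, ``base_seed``, ``snps`` (full list of
    SNP mappings, replacing the default list), ``cpgs`` (likewise), and
    ``hg2`` — a mapping of marker name to heritability override, where the
    key ``"*"`` applies to every SNP.
    """
    if config_source is None:
        cfg: Mapping[str, Any] = {}
    elif isinstance(config_source, (str, Path)):
        with open(config_source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = config_source

    base = default_spec()
    snps = [_build_snp(e) for e in cfg["snps"]] if "snps" in cfg else list(base.snps)
    cpgs = [_build_cpg(e) for e in cfg["cpgs"]] if "cpgs" in cfg else list(base.cpgs)

    if "hg2" in cfg:
        overrides = dict(cfg["hg2"])
        star = overrides.pop("*", None)
        known = {s.marker_name for s in snps}
        missing = set(overrides) - known
        if missing:
            raise SpecError(f"hg2 override names unknown markers: {sorted(missing)}")
        snps = [
            SnpEffect(
                s.marker_name, s.chromosome, s.position_bp, s.role,
                float(overrides.get(s.marker_name, star if star is not None else s.hg2)),
                s.coded_allele_freq,
            )
            for s in snps
        ]

    return ModelSpec(
        snps=snps,
        cpgs=cpgs,
        corr_baseline=float(cfg.get("corr_baseline", D.CORR_BASELINE)),
        n_replicates=int(cfg.get("n_replicates", D.N_REPLICATES)),
        base_seed=int(cfg.get("base_seed", 0)),
    )


def serialize_spec(spec: ModelSpec, path: str | Path | None = None) -> str:
    """Serialize a spec to YAML; load_spec(serialize_spec(s)) round-trips."""
    doc = {
        "corr_baseline": spec.corr_baseline,
        "n_replicates": spec.n_replicates,
        "base_seed": spec.base_seed,
        "snps": [asdict(s) for s in spec.snps],
        "cpgs": [asdict(c) for c in spec.cpgs],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
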