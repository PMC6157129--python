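"""Readers/writers for the delimited-text cohort and output formats.

All tables are UTF-8 CSV with a header row; missing values are empty fields;
floats are written with 12 significant digits so a read/write/read cycle is
value-stable.  Replicate indices are zero-padded in file names (rep001, ...,
rep200).  Every run directory gets a ``manifest.json`` recording the config,
seed, tool version and per-file SHA-256 checksums, which suffices to
reproduce the run bit-exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortConfig, CohortData
from .methylation import MethylationPanel
from .pipeline import ReplicateOutput

__all__ = [
    "write_table",
    "read_table",
    "write_cohort",
    "read_cohort",
    "write_replicate",
    "write_manifest",
    "replicate_paths",
]

FLOAT_FORMAT = "%.12g"

COHORT_FILES = {
    "genotypes": "genotypes.csv",
    "methylation_v2": "methylation_v2.csv",
    "methylation_v4": "methylation_v4.csv",
    "phenotypes": "phenotypes.csv",
}


def write_table(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)
    return path


def read_table(path: Path, index_col=None) -> pd.DataFrame:
    try:
        return pd.read_csv(path, index_col=index_col)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed input table {path}: {exc}") from exc


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: Path,
    files: list[Path],
    base_seed: int,
    config: dict | None = None,
    replicates: list[int] | None = None,
) -> Path:
    manifest = {
        "tool": "genomethate",
        "version": __version__,
        "base_seed": base_seed,
        "config": config or {},
        "replicates": replicates,
        "checksums": {p.name: _checksum(p) for p in sorted(files)},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_cohort(cohort: CohortData, out_dir: str | Path, base_seed: int | None = None) -> list[Path]:
    """Write genotype, methylation (v2 + partial v4) and phenotype tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = [
        write_table(cohort.genotypes, out / COHORT_FILES["genotypes"], index=True),
        write_table(cohort.methylation.v2, out / COHORT_FILES["methylation_v2"], index=True),
        write_table(cohort.methylation.v4, out / COHORT_FILES["methylation_v4"], index=True),
        write_table(cohort.phenotypes, out / COHORT_FILES["phenotypes"]),
    ]
    cfg = dataclasses.asdict(cohort.config) if cohort.config else {}
    seed = base_seed if base_seed is not None else (cohort.config.seed if cohort.config else 0)
    write_manifest(out, files, seed, config=cfg)
    return files


def read_cohort(in_dir: str | Path) -> CohortData:
    src = Path(in_dir)
    for f in COHORT_FILES.values():
        if not (src / f).exists():
            raise FileNotFoundError(f"cohort directory {src} lacks {f}")
    genotypes = read_table(src / COHORT_FILES["genotypes"], index_col=0)
    v2 = read_table(src / COHORT_FILES["methylation_v2"], index_col=0)
    v4 = read_table(src / COHORT_FILES["methylation_v4"], index_col=0)
    phenotypes = read_table(src / COHORT_FILES["phenotypes"])
    config = None
    manifest = src / "manifest.json"
    if manifest.exists():
        cfg = json.loads(manifest.read_text()).get("config") or {}
        if cfg:
            cfg = {k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}
            try:
                config = CohortConfig(**cfg)
            except TypeError:
                config = None
    return CohortData(genotypes, MethylationPanel(v2, v4), phenotypes, config)


def replicate_paths(out_dir: str | Path, k: int) -> tuple[Path, Path]:
    out = Path(out_dir)
    return (
        out / f"sim_methylation_v4_rep{k:03d}.csv",
        out / f"sim_tg_rep{k:03d}.csv",
    )


def write_replicate(
    rep: ReplicateOutput, out_dir: str | Path, diagnostics: bool = False
) -> list[Path]:
    """One methylation file and one TG file per replicate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meth_path, tg_path = replicate_paths(out, rep.replicate)
    write_table(rep.methylation.v4_sim, meth_path, index=True)
    tg = rep.tg
    if diagnostics and rep.diagnostics is not None:
        tg = rep.tg.merge(rep.diagnostics, on="subject_id")
    write_table(tg, tg_path)
    return [meth_path, tg_path]
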