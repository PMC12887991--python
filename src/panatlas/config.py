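"""Pipeline configuration: every threshold applied anywhere in the build.

Defaults follow common practice for Orbitrap shotgun reprocessing: tryptic
digestion with up to two missed cleavages, a minimum peptide length of
seven residues, a very strict per-run open-search PSM FDR of 0.05%, a site
localization score cutoff of 20, a 1% protein-level FDR, and homology
clustering at 70% sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    core_proteome_id: str
    min_peptide_length: int = 7
    max_missed_cleavages: int = 2
    open_psm_fdr: float = 0.0005
    closed_psm_fdr: float | None = None  # closed search assumed pre-filtered
    min_loc_score: float = 20.0
    protein_fdr: float = 0.01
    cluster_identity: float = 0.70
    detectability_mass_window: tuple[float, float] = (500.0, 5000.0)
    enzyme: str = "trypsin"  # or "trypsin/lysc" (cleaves K even before P)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        for name in ("open_psm_fdr", "protein_fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not 0.0 < self.cluster_identity <= 1.0:
            raise ValueError("cluster_identity must lie in (0,1]")
        lo, hi = self.detectability_mass_window
        if not (0 < lo < hi):
            raise ValueError("detectability_mass_window must satisfy 0 < low < high")
        if self.enzyme not in ("trypsin", "trypsin/lysc"):
            raise ValueError(f"unknown enzyme mode {self.enzyme!r}")
        if not self.core_proteome_id:
            raise ValueError("core_proteome_id is required")


_TUPLE_FIELDS = {"detectability_mass_window"}


def read_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key=value`` configuration file."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()

    kwargs: dict[str, object] = {}
    type_by_name = {f.name: f.type for f in fields(PipelineConfig)}
    for key, value in raw.items():
        if key not in type_by_name:
            raise ValueError(f"unknown configuration key {key!r}")
        if key in _TUPLE_FIELDS:
            lo, hi = (float(x) for x in value.split(","))
            kwargs[key] = (lo, hi)
        elif key in ("min_peptide_length", "max_missed_cleavages", "random_seed"):
            kwargs[key] = int(value)
        elif key in ("open_psm_fdr", "closed_psm_fdr", "min_loc_score",
                     "protein_fdr", "cluster_identity"):
            kwargs[key] = None if value.lower() == "none" else float(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)  # type: ignore[arg-type]


def write_config(config: PipelineConfig, path: str | Path) -> None:
    lines = []
    for f in fields(PipelineConfig):
        v = getattr(config, f.name)
        if f.name in _TUPLE_FIELDS:
            v = f"{v[0]},{v[1]}"
        lines.append(f"{f.name}={v}")
    Path(path).write_text("\n".join(lines) + "\n")
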