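"""Project configuration: defaults, limits, file round-trip.

All tool-level limits are data, not code: the five-set Venn ceiling, the
200-genome on-the-fly cap reserved for whole-genome nucleotide identity
runs, and the three-genome minimum project size live here and are enforced
by the owning operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .distances import PocpCriteria
from .orthology import OrthologyCriteria

#: hard limits of the tool surface
VENN_MAX_SETS = 5
FASTANI_MAX_GENOMES = 200  # on-the-fly nucleotide-identity cap (external tool; API parity)
MIN_PROJECT_GENOMES = 3

_KNOWN_KEYS = {
    "name", "genomes", "outdir", "backend", "hits_table", "cmd_template",
    "srv_cutoff", "max_evalue", "pocp_variant", "chunk_size", "workers",
    "seed", "compression",
}


@dataclass
class ProjectConfig:
    """Everything needed to set up and run a project, round-trippable as YAML."""

    name: str = "project"
    genomes: list[dict] = field(default_factory=list)  # [{path, name, format?}]
    outdir: str = "orthopan_out"
    backend: str = "table"  # {table, synthetic, external}
    hits_table: str | None = None
    cmd_template: str | None = None
    srv_cutoff: float = 0.3
    max_evalue: float = 1e-10
    pocp_variant: str = "strict"
    chunk_size: int = 500
    workers: int = 1
    seed: int = 0
    compression: bool = True

    @property
    def orthology_criteria(self) -> OrthologyCriteria:
        return OrthologyCriteria(srv_cutoff=self.srv_cutoff, max_evalue=self.max_evalue)

    @property
    def pocp_criteria(self) -> PocpCriteria:
        return PocpCriteria(variant=self.pocp_variant)

    @property
    def store_prefix(self) -> Path:
        return Path(self.outdir) / "hits"

    @property
    def manifest_dir(self) -> Path:
        return Path(self.outdir) / "manifests"

    @classmethod
    def load(cls, path: str | Path) -> "ProjectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
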