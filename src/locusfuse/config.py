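"""Pipeline configuration: the handful of constants the consolidation
rules depend on, plus input/output paths.

The file representation is a flat ``key = value`` document that
round-trips losslessly; CLI flags override file values and the effective
config is echoed into the report, so every number in a report can be
traced to a configuration.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # inputs
    transcripts_fasta: str = ""
    predictions_gff3: str = ""
    alignments_psl: str = ""
    domain_tables: dict[str, str] = field(default_factory=dict)  # genome_id -> path
    outdir: str = "locusfuse_out"
    # the consolidation constants
    vicinity_bp: int = 50
    min_protein_aa: int = 40
    cluster_identity: float = 0.97
    min_intron_bp: int = 20
    min_cover_bp: int = 1
    fold_threshold: float = 3.0
    strand_aware: bool = False
    transcript_vicinity_rule: bool = True
    best_alignment_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vicinity_bp < 0:
            raise ValueError("vicinity_bp must be >= 0")
        if not 0 < self.cluster_identity <= 1:
            raise ValueError("cluster_identity must be in (0, 1]")
        if self.min_intron_bp < 1:
            raise ValueError("min_intron_bp must be >= 1")
        if self.min_cover_bp < 1:
            raise ValueError("min_cover_bp must be >= 1")

    # -- flat key=value round-trip ------------------------------------------

    def to_file(self, path: str | os.PathLike) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "domain_tables":
                v = ",".join(f"{g}:{p}" for g, p in v.items())
            elif isinstance(v, bool):
                v = "true" if v else "false"
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, str]) -> "PipelineConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            if key == "domain_tables":
                tables: dict[str, str] = {}
                if isinstance(value, dict):
                    tables = dict(value)
                elif value:
                    for token in str(value).split(","):
                        genome, _, p = token.partition(":")
                        if not p:
                            raise ValueError(
                                f"domain_tables entries must be genome:path, got {token!r}"
                            )
                        tables[genome.strip()] = p.strip()
                kwargs[key] = tables
            elif types[key] == "bool" or isinstance(getattr(cls(), key), bool):
                kwargs[key] = str(value).lower() in ("true", "1", "yes")
            elif isinstance(getattr(cls(), key), int):
                kwargs[key] = int(value)
            elif isinstance(getattr(cls(), key), float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = str(value)
        return cls(**kwargs)

    def to_echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d
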