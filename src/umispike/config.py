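"""Run configuration: one flat file driving a whole reproducible run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Everything a full run needs besides the input files.

    Round-trips losslessly through a flat YAML file; the master seed fans
    out to per-stage seeds (logged in the manifest) so any stage can be
    rerun in isolation.
    """

    seed: int = 0
    outdir: str = "out"
    small: bool = True
    vaf_levels: list = field(default_factory=lambda: [0.005, 0.01, 0.02,
                                                      0.04, 0.05, 0.075])
    depth_targets: list = field(default_factory=lambda: [200.0, 450.0, 850.0])
    replicates: int = 5
    umi_mode: str = "label"
    umi_lambda: float = 0.5
    dialect: str = "rx_tag"
    min_depth: int = 50
    min_qual: float = 50.0
    dbsnp_af_cutoff: float = 0.05
    cosmic_min_samples: int = 3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.umi_mode not in ("label", "carve"):
            raise ValueError("umi_mode must be 'label' or 'carve'")
        if self.dialect not in ("three_file", "prepended", "rx_tag"):
            raise ValueError("unknown dialect " + self.dialect)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
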