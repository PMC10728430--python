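"""Pipeline configuration with YAML round-trip.

All tunable constants used by the classifiers live here so that a single
YAML file can reproduce or vary an analysis.  Coordinates are 1-based,
end-inclusive (GRCh38).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

#: Pure-state region betas (h19, icr2) used by the purity mixture model.
DEFAULT_PURE_STATE_BETA: dict[str, tuple[float, float]] = {
    "ROI": (0.5, 0.5),
    "LOI": (1.0, 0.5),
    "LOH": (1.0, 0.0),
}


@dataclass
class PipelineConfig:
    # imprinting classifier (strict inequalities on both thresholds)
    h19_threshold: float = 0.7
    icr2_threshold: float = 0.3
    gom_sd_multiplier: float = 2.0
    m_clip_eps: float = 1e-6
    normal_h19_beta: float = 0.5
    normal_icr2_beta: float = 0.5
    pure_state_beta: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_PURE_STATE_BETA.items()}
    )
    # top-variable-probe plumbing
    top_n_probes: int = 10_000
    exclude_chroms: tuple = ("chrX", "chrY")
    rank_on_m_values: bool = False
    # germline triage
    vaf_alpha: float = 0.05
    vaf_min_delta: float = 0.15
    # pair concordance
    atypical_shared_count: int = 20
    atypical_cnv_similarity: float = 0.9
    cnv_bin_size: int = 1_000_000
    breakpoint_tol_bp: int = 10_000
    # cohort statistics
    pairwise_correction: str = "holm"

    def __post_init__(self) -> None:
        if not 0 < self.h19_threshold < 1 or not 0 < self.icr2_threshold < 1:
            raise ConfigError("imprinting thresholds must lie in (0, 1)")
        if self.gom_sd_multiplier <= 0:
            raise ConfigError("gom_sd_multiplier must be positive")
        if self.cnv_bin_size <= 0 or self.breakpoint_tol_bp < 0:
            raise ConfigError("CNV bin size / breakpoint tolerance out of range")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["exclude_chroms"] = list(self.exclude_chroms)
        data["pure_state_beta"] = {k: list(v) for k, v in self.pure_state_beta.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_chroms" in data:
            data["exclude_chroms"] = tuple(data["exclude_chroms"])
        if "pure_state_beta" in data:
            data["pure_state_beta"] = {
                k: tuple(v) for k, v in data["pure_state_beta"].items()
            }
        return cls(**data)
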