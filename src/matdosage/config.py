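"""Configuration for the synthetic maternal-transcriptome cohort.

The defaults encode the biology the downstream analysis assumes: a
GV-arrested maternal transcriptome from which a maturation degradation
wave removes ~20% of total RNA (expected linear-scale MII/GV mass ratio
= sum of class_fraction * class_retention = 0.7996 under the defaults),
with a small set of motif-bearing knockout-target genes that escape
degradation when the m6A reader is deleted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, asdict

import yaml

MATURATION_CLASSES = ("stabilized", "destabilized", "unchanged")

# a motif pattern is plain RNA letters plus [..] alternative groups
_PATTERN_RE = re.compile(r"^(?:[ACGU]|\[[ACGU]{2,4}\])+$")


@dataclass
class SyntheticConfig:
    n_genes: int = 6000
    flank_len: int = 400
    motif_pattern: str = "GAC[UA]"
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "stabilized": 0.08, "destabilized": 0.12, "unchanged": 0.80,
        }
    )
    class_retention_means: dict[str, float] = field(
        default_factory=lambda: {
            "stabilized": 1.10, "destabilized": 0.33, "unchanged": 0.84,
        }
    )
    retention_sd_log2: float = 0.25
    ko_target_fraction: float = 0.04
    ko_retention_boost: float = 2.0
    target_motif_rate: float = 3.0
    background_motif_rate: float = 0.5
    motif_position_sd: float = 50.0
    n_replicates: int = 3
    noise_sd_log2: float = 0.2
    gv_mean_log2: float = 8.0
    gv_sd_log2: float = 1.5
    # m6A-peak emulation (twelve public samples in the emulated resource)
    n_peak_samples: int = 12
    peak_width: int = 150
    peak_position_sd: float = 50.0
    background_peak_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")
        if set(self.class_fractions) != set(MATURATION_CLASSES):
            raise ValueError(f"class_fractions must have keys {MATURATION_CLASSES}")
        if set(self.class_retention_means) != set(MATURATION_CLASSES):
            raise ValueError(
                f"class_retention_means must have keys {MATURATION_CLASSES}"
            )
        total = sum(self.class_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_fractions must sum to 1 (got {total})")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class_fractions must be non-negative")
        if any(v <= 0 for v in self.class_retention_means.values()):
            raise ValueError("all class retentions must be > 0")
        if not 0 <= self.ko_target_fraction <= 1:
            raise ValueError("ko_target_fraction must be in [0, 1]")
        if self.ko_retention_boost <= 0:
            raise ValueError("ko_retention_boost must be > 0")
        for name in ("retention_sd_log2", "noise_sd_log2", "target_motif_rate",
                     "background_motif_rate", "motif_position_sd",
                     "background_peak_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_peak_samples < 1 or self.peak_width < 1:
            raise ValueError("n_peak_samples and peak_width must be >= 1")
        if not _PATTERN_RE.match(self.motif_pattern):
            raise ValueError(
                f"motif_pattern {self.motif_pattern!r} is not a valid "
                "RNA pattern over A/C/G/U with [..] alternatives"
            )

    @property
    def expected_mass_ratio(self) -> float:
        """Expected linear-scale total MII/GV retention (0.7996 at defaults)."""
        return sum(
            self.class_fractions[c] * self.class_retention_means[c]
            for c in MATURATION_CLASSES
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown SyntheticConfig fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
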