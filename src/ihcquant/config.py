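"""Pipeline configuration.

All tunable behaviour lives here with defaults equal to the published
parameter tables; the CLI loads overrides from a YAML document whose
``pipeline:`` section maps onto these fields.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields


@dataclass(frozen=True)
class PipelineConfig:
    # preprocessing
    probe_window: int = 3            # window of the probe median used for the PSNR decision
    # segmentation
    segment_on: str = "amplified"    # "amplified" = literal gain-adjusted chain, or "filtered"
    opening_iterations: int = 2
    background_dilation_iterations: int = 3
    distance_fraction: float = 0.4
    min_object_px: int = 30
    # intensity coefficient
    intensity_source: str = "original"   # "original" or "amplified"
    intensity_channel: str = "luma"      # "luma" or "inverted_luma"
    # subtype rules
    unqualified_ki_binding: str = "her2"     # biomarker the bare "KI = 1" condition binds to
    her2_area_direction: str = "less"        # printed direction of the HER2-area condition

    def __post_init__(self) -> None:
        if self.probe_window % 2 == 0 or self.probe_window < 3:
            raise ValueError("probe_window must be an odd integer >= 3")
        if self.segment_on not in ("amplified", "filtered"):
            raise ValueError("segment_on must be 'amplified' or 'filtered'")
        if self.intensity_source not in ("original", "amplified"):
            raise ValueError("intensity_source must be 'original' or 'amplified'")
        if self.intensity_channel not in ("luma", "inverted_luma"):
            raise ValueError("intensity_channel must be 'luma' or 'inverted_luma'")
        if self.unqualified_ki_binding not in ("her2", "er", "ki67"):
            raise ValueError("unqualified_ki_binding must be 'her2', 'er' or 'ki67'")
        if self.her2_area_direction not in ("less", "greater"):
            raise ValueError("her2_area_direction must be 'less' or 'greater'")
        if not 0.0 < self.distance_fraction < 1.0:
            raise ValueError("distance_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Stable digest of the effective parameters; changes iff any field changes."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
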