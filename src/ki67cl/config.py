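"""Run-level configuration shared by the CLI subcommands.

Defaults are the pipeline's operating constants: 300-px cluster
agglomeration threshold, 10,000-cell clustering subsample, 15-px
cross-channel merge radius, 20-px detection-matching radius, 252-px patch
tiling, decile cutoff grid with a 10% minimum group fraction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    distance_threshold_px: float = 300.0
    subsample_max: int = 10_000
    merge_radius_px: float = 15.0
    match_radius_px: float = 20.0
    patch_px: int = 252
    sigma_px: float = 3.0
    min_probability: float = 0.5
    cutoff_quantiles: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))
    min_group_fraction: float = 0.10
    cv_folds: int = 3
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat JSON key-value config file; kwargs override file values."""
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "cutoff_quantiles" in data:
            data["cutoff_quantiles"] = tuple(data["cutoff_quantiles"])
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoff_quantiles"] = list(d["cutoff_quantiles"])
        return d

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
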