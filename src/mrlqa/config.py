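"""QA run configuration, loadable from YAML/JSON.

Defaults pin the verification thresholds used clinically: gamma 1 mm / 1%
with a 10% low-fluence threshold and a PASS bar of strictly more than 98%
per gantry angle, and a Pearson correlation PASS at r >= 0.985.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import UsageError
from .gamma import GammaCriteria
from .geometry import MachineGeometry, default_geometry

__all__ = ["QAConfig"]


@dataclass
class QAConfig:
    resolution_mm: float = 0.1
    dta_mm: float = 1.0
    dd_percent: float = 1.0
    threshold_fraction: float = 0.10
    gamma_pass_percent: float = 98.0  # strict: exactly 98.0 is a FAIL
    pearson_pass_r: float = 0.985  # inclusive
    combine_pearson_in_verdict: bool = True
    gantry_tol_deg: float = 0.5
    pearson_mask: str = "union_above_threshold"
    exclude_closed_pairs: bool = True
    grid_margin_mm: float = 10.0
    full_field: bool = False
    swap_leaf_banks: bool = False
    geometry_overrides: dict = field(default_factory=dict)

    def geometry(self) -> MachineGeometry:
        if not self.geometry_overrides:
            return default_geometry()
        allowed = {"sad_cm", "field_x_mm", "field_y_mm", "n_leaf_pairs"}
        bad = set(self.geometry_overrides) - allowed
        if bad:
            raise UsageError(f"unknown geometry override(s): {sorted(bad)}")
        return MachineGeometry(**self.geometry_overrides)

    def criteria(self) -> GammaCriteria:
        return GammaCriteria(
            dta_mm=self.dta_mm,
            dd_percent=self.dd_percent,
            threshold_fraction=self.threshold_fraction,
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "QAConfig":
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise UsageError(f"unknown config key(s): {sorted(bad)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QAConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise UsageError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
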