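"""Pipeline configuration: every tunable, serialised losslessly to YAML.

Defaults follow the published analysis wherever it states a value: the YC3.6
calibration constants, the >20 um / >=3 spines segment filter, and the 95th-
percentile overload rule.  The printed overload thresholds from the original
cohort (dendrites 2.14, spines 2.24) are shipped as reference constants; the
pipeline recomputes thresholds from whatever control data it is given.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationParams, DEFAULT_CALIBRATION
from .morphology import SpineDetectorParams

__all__ = ["PipelineConfig", "REFERENCE_THRESHOLDS"]

#: Overload thresholds reported for the original control cohort (YC ratio).
#: Reference values only — not recomputable without the original raw data.
REFERENCE_THRESHOLDS = {"dendrite": 2.14, "spine": 2.24}


@dataclass
class PipelineConfig:
    """All pipeline tunables with their defaults."""

    calibration: CalibrationParams = DEFAULT_CALIBRATION
    estimate_bounds: bool = False          # re-estimate r_min/r_max from control ratios
    background_method: str = "percentile"  # "percentile" | "fixed"
    background_percentile: float = 50.0
    background_fixed: tuple[float, float] | None = None  # (b_cfp, b_yfp)
    background_shared: bool = False        # one scalar for both channels
    ratio_eps: float = 1e-6
    # ROI ratio estimator.  "ratio_of_sums" (ratio of background-subtracted
    # channel sums, i.e. the denominator-weighted per-voxel ratio mean) is the
    # default: the unweighted per-voxel mean ("ratio_first") is biased upward
    # by shot noise (Jensen term ~ r * Var(CFP)/E[CFP]^2) at realistic photon
    # budgets.  "ratio_first" mirrors measuring the mean of a ratio image.
    roi_method: str = "ratio_of_sums"
    detector: SpineDetectorParams = SpineDetectorParams()
    min_segment_length_um: float = 20.0
    min_spines: int = 3
    overload_percentile: float = 95.0
    equal_var: bool = True                 # Student (True) vs Welch t-test
    voxel_size: tuple[float, float, float] = (0.8, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_method not in ("percentile", "fixed"):
            raise ValueError(f"unknown background_method {self.background_method!r}")
        if self.roi_method not in ("ratio_first", "ratio_of_sums"):
            raise ValueError(f"unknown roi_method {self.roi_method!r}")
        if self.background_method == "fixed" and self.background_fixed is None:
            raise ValueError("background_method='fixed' requires background_fixed")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_size"] = list(self.voxel_size)
        if self.background_fixed is not None:
            d["background_fixed"] = list(self.background_fixed)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "calibration" in d and isinstance(d["calibration"], dict):
            d["calibration"] = CalibrationParams(**d["calibration"])
        if "detector" in d and isinstance(d["detector"], dict):
            d["detector"] = SpineDetectorParams(**d["detector"])
        if "voxel_size" in d:
            d["voxel_size"] = tuple(d["voxel_size"])
        if d.get("background_fixed") is not None:
            d["background_fixed"] = tuple(d["background_fixed"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
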