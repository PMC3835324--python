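"""Hill-equation calibration between YC (YFP/CFP) ratios and calcium concentration.

The yellow cameleon 3.6 indicator reports intracellular calcium through FRET:
calcium binding raises the YFP/CFP emission ratio R monotonically between the
calcium-free ratio ``r_min`` and the saturating ratio ``r_max``.  Concentration
follows the Hill binding isotherm

    [Ca2+] = Kd * ((R - r_min) / (r_max - R)) ** (1 / hill)

with apparent dissociation constant ``kd`` (nM) and Hill coefficient ``hill``.
The empirical bounds ``r_min``/``r_max`` are estimated from a control ratio
population as the medians of its extreme 5% tails.

All concentrations in this package are in nM; ratios are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationParams",
    "CalciumValue",
    "DEFAULT_CALIBRATION",
    "ratio_to_calcium",
    "calcium_to_ratio",
    "estimate_rmin_rmax",
    "batch_convert",
    "InsufficientDataError",
    "DegenerateCalibrationError",
]


class InsufficientDataError(ValueError):
    """Too few observations to estimate a calibration quantity."""


class DegenerateCalibrationError(ValueError):
    """Estimated calibration bounds collapsed (r_min == r_max)."""


@dataclass(frozen=True)
class CalibrationParams:
    """Constants of the indicator's binding curve.

    Parameters
    ----------
    kd : float
        Apparent dissociation constant in nM (concentration at half-saturation).
    hill : float
        Hill cooperativity coefficient, dimensionless.
    r_min, r_max : float
        Indicator ratio at zero and at saturating calcium.
    """

    kd: float = 277.0
    hill: float = 1.1
    r_min: float = 1.36
    r_max: float = 2.48

    def __post_init__(self) -> None:
        vals = (self.kd, self.hill, self.r_min, self.r_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"calibration constants must be finite, got {vals}")
        if self.kd <= 0 or self.hill <= 0:
            raise ValueError("kd and hill must be positive")
        if not self.r_min < self.r_max:
            raise ValueError(f"require r_min < r_max, got {self.r_min} >= {self.r_max}")

    def replace(self, **kw) -> "CalibrationParams":
        return replace(self, **kw)


#: Published YC3.6 in-vivo calibration used as the package default.
DEFAULT_CALIBRATION = CalibrationParams()


@dataclass(frozen=True)
class CalciumValue:
    """A converted concentration with its conversion regime.

    Exactly one regime applies: *valid* (finite concentration from a ratio
    strictly inside the calibration range), *saturated* (ratio at/above
    ``r_max``; the isotherm diverges, so no finite concentration is claimed)
    or *subfloor* (ratio below ``r_min``, mapped to 0 nM: physically
    calcium-free, with the flag preserving that the ratio undershot the floor).
    """

    concentration: float
    saturated: bool = False
    subfloor: bool = False

    @property
    def valid(self) -> bool:
        return not (self.saturated or self.subfloor)


def ratio_to_calcium(r: float, params: CalibrationParams = DEFAULT_CALIBRATION) -> CalciumValue:
    """Convert a YC ratio to calcium concentration (nM) via the Hill isotherm.

    Ratios at or above ``r_max`` return a saturated flag (concentration NaN);
    ratios below ``r_min`` return 0 nM with a subfloor flag; ``r == r_min``
    returns exactly 0 nM unflagged.

    Raises
    ------
    ValueError
        If ``r`` is non-finite or non-positive.
    """
    r = float(r)
    if not math.isfinite(r) or r <= 0:
        raise ValueError(f"invalid ratio {r!r}: must be finite and > 0")
    p = params
    if r >= p.r_max:
        return CalciumValue(math.nan, saturated=True)
    if r < p.r_min:
        return CalciumValue(0.0, subfloor=True)
    if r == p.r_min:
        return CalciumValue(0.0)
    conc = p.kd * ((r - p.r_min) / (p.r_max - r)) ** (1.0 / p.hill)
    return CalciumValue(conc)


def calcium_to_ratio(c: float, params: CalibrationParams = DEFAULT_CALIBRATION) -> float:
    """Analytic inverse of :func:`ratio_to_calcium`.

    For concentration ``c`` >= 0 (nM) returns the ratio
    ``(r_min + r_max * x) / (1 + x)`` with ``x = (c / kd) ** hill``, which lies
    in ``[r_min, r_max)``; ``c = 0`` maps to exactly ``r_min``.
    """
    c = float(c)
    if not math.isfinite(c) or c < 0:
        raise ValueError(f"invalid concentration {c!r}: must be finite and >= 0")
    if c == 0.0:
        return params.r_min
    x = (c / params.kd) ** params.hill
    return (params.r_min + params.r_max * x) / (1.0 + x)


def estimate_rmin_rmax(control_ratios: Iterable[float], tail_fraction: float = 0.05) -> tuple[float, float]:
    """Estimate (r_min, r_max) from a control ratio population.

    Each bound is the median of the extreme ``tail_fraction`` tail: the
    ``ceil(tail_fraction * n)`` smallest (largest) values after an ascending
    sort, so "the lowest 5%" always resolves to an integer count.  The median
    of an even-sized tail is the mean of its two central values.

    Raises
    ------
    InsufficientDataError
        Fewer than 40 values (each 5% tail must hold at least 2).
    DegenerateCalibrationError
        If the two medians coincide (e.g. constant input).
    """
    x = np.asarray(sorted(float(v) for v in control_ratios), dtype=float)
    n = x.size
    if n < 40:
        raise InsufficientDataError(f"need >= 40 control ratios to estimate bounds, got {n}")
    k = math.ceil(tail_fraction * n)
    r_min = float(np.median(x[:k]))
    r_max = float(np.median(x[-k:]))
    if not r_min < r_max:
        raise DegenerateCalibrationError(
            f"degenerate calibration: tail medians coincide (r_min={r_min}, r_max={r_max})"
        )
    return r_min, r_max


def batch_convert(
    measurements: pd.DataFrame,
    params: CalibrationParams = DEFAULT_CALIBRATION,
    ratio_column: str = "mean_ratio",
) -> tuple[pd.DataFrame, dict]:
    """Convert a table of ROI mean ratios to calcium, preserving order.

    Adds ``calcium_nM``, ``saturated`` and ``subfloor`` columns.  Returns the
    augmented copy together with summary statistics (mean/SD of concentration
    over the valid, unflagged subset, plus flagged-record counts).

    An empty table yields an empty table and zero counts, not an error.
    """
    out = measurements.copy()
    if len(out) == 0:
        out["calcium_nM"] = pd.Series(dtype=float)
        out["saturated"] = pd.Series(dtype=bool)
        out["subfloor"] = pd.Series(dtype=bool)
        return out, {"n": 0, "n_valid": 0, "n_saturated": 0, "n_subfloor": 0,
                     "mean_nM": math.nan, "sd_nM": math.nan}

    converted = [ratio_to_calcium(r, params) for r in out[ratio_column].to_numpy()]
    out["calcium_nM"] = [c.concentration for c in converted]
    out["saturated"] = [c.saturated for c in converted]
    out["subfloor"] = [c.subfloor for c in converted]

    valid = out.loc[~(out["saturated"] | out["subfloor"]), "calcium_nM"]
    summary = {
        "n": len(out),
        "n_valid": int(valid.size),
        "n_saturated": int(out["saturated"].sum()),
        "n_subfloor": int(out["subfloor"].sum()),
        "mean_nM": float(valid.mean()) if valid.size else math.nan,
        "sd_nM": float(valid.std(ddof=1)) if valid.size > 1 else math.nan,
    }
    return out, summary
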