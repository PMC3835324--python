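"""Colour-coded concentration renderings of ratio stacks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .calibration import CalibrationParams, DEFAULT_CALIBRATION
from .imaging import RatioStack

__all__ = ["concentration_projection", "save_concentration_png"]


def concentration_projection(
    ratio_stack: RatioStack,
    params: CalibrationParams = DEFAULT_CALIBRATION,
    vmax_nM: float = 500.0,
) -> np.ndarray:
    """Maximum-intensity z-projection of per-voxel calcium (nM).

    Saturated and invalid voxels are NaN; concentrations are clipped at
    ``vmax_nM`` for display.
    """
    r = ratio_stack.ratio
    conc = np.full(r.shape, np.nan)
    with np.errstate(all="ignore"):
        inside = ratio_stack.valid_mask & (r > params.r_min) & (r < params.r_max)
        conc[inside] = params.kd * (
            (r[inside] - params.r_min) / (params.r_max - r[inside])
        ) ** (1.0 / params.hill)
        conc[ratio_stack.valid_mask & (r <= params.r_min)] = 0.0
        conc = np.clip(conc, 0.0, vmax_nM)
        return np.nanmax(conc, axis=0)


def save_concentration_png(
    ratio_stack: RatioStack,
    path: str | Path,
    params: CalibrationParams = DEFAULT_CALIBRATION,
    vmax_nM: float = 500.0,
) -> Path:
    """Write a colour-coded calcium projection (viridis, colourbar in nM)."""
    proj = concentration_projection(ratio_stack, params, vmax_nM)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(proj, cmap="viridis", vmin=0, vmax=vmax_nM, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="[Ca$^{2+}$] (nM)")
    ax.set_axis_off()
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
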