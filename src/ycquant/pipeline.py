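"""End-to-end orchestration: dataset -> measurements -> statistics -> report.

``quantify_dataset`` walks a dataset directory (one sub-directory per imaged
volume holding the two channel TIFFs, the ROI label volume + CSV and the SWC
traces), builds background-subtracted ratio stacks, measures ROI mean YC
ratios, converts them to calcium, detects spines and assembles dendrite
records.  ``analyze_tables`` runs the cohort statistics — overload
thresholds and classification, the mixed-effects genotype comparison, the
per-animal spine-density t-test and the density-vs-ratio correlation — and
returns a serialisable report.  Statistics run in ratio space; conversion to
concentration happens only afterwards, and the report carries both.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import io as ycio
from .calibration import batch_convert, estimate_rmin_rmax
from .config import PipelineConfig
from .imaging import (
    compute_ratio_stack,
    estimate_background,
    measure_rois,
    measure_rois_ratio_of_sums,
    merge_channels,
)
from .morphology import (
    compute_density,
    detect_spines,
    filter_segments,
    pair_density_with_ratio,
    records_to_frame,
)
from .stats import (
    OverloadThresholds,
    SeparationError,
    check_normality,
    classify_overload,
    compare_density,
    compute_thresholds,
    correlate_density_ratio,
    fit_overload_model,
)

log = logging.getLogger(__name__)

__all__ = ["quantify_dataset", "analyze_tables", "AnalysisReport"]


def _scene_dirs(dataset_dir: Path) -> list[Path]:
    scenes = sorted((dataset_dir / "scenes").glob("*"))
    scenes = [s for s in scenes if s.is_dir()]
    if not scenes:
        raise FileNotFoundError(f"no scene directories under {dataset_dir / 'scenes'}")
    return scenes


def quantify_dataset(
    dataset_dir: str | Path, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every scene of a dataset directory.

    Returns ``(measurements, dendrite_records)``: per-ROI mean ratios with
    calcium conversions, and per-dendrite spine-density records paired with
    the shaft's YC ratio.
    """
    dataset_dir = Path(dataset_dir)
    all_measurements, all_records = [], []
    for scene_dir in _scene_dirs(dataset_dir):
        stack = ycio.read_stack(scene_dir, voxel_size=config.voxel_size)
        if config.background_method == "fixed":
            b_cfp, b_yfp = config.background_fixed
        else:
            b_cfp, b_yfp = estimate_background(stack, config.background_percentile)
        if config.background_shared:
            b_cfp = b_yfp = 0.5 * (b_cfp + b_yfp)

        labels, meta = ycio.read_label_volume(scene_dir)
        rois = ycio.rois_from_labels(labels, meta)
        if config.roi_method == "ratio_of_sums":
            measurements = measure_rois_ratio_of_sums(stack, b_cfp, b_yfp, rois, eps=config.ratio_eps)
        else:
            rstack = compute_ratio_stack(stack, b_cfp, b_yfp, eps=config.ratio_eps)
            measurements = measure_rois(rstack, rois)
        n_nosignal = int(measurements["no_signal"].sum())
        if n_nosignal:
            log.info("%s: %d ROI(s) with no valid voxels flagged no-signal", scene_dir.name, n_nosignal)
        measurements.insert(0, "scene_id", scene_dir.name)
        all_measurements.append(measurements)

        merged = merge_channels(stack)
        for swc in sorted((scene_dir / "traces").glob("*.swc")):
            trace = ycio.read_swc(swc)
            spines = detect_spines(merged, trace, config.voxel_size, config.detector)
            rec = compute_density(
                trace, spines,
                min_length=config.min_segment_length_um, min_spines=config.min_spines,
            )
            all_records.append(rec)

    measurements = pd.concat(all_measurements, ignore_index=True)
    signal = measurements[~measurements["no_signal"]].copy()
    signal, conv_summary = batch_convert(signal, config.calibration)
    measurements = measurements.merge(
        signal[["scene_id", "roi_id", "calcium_nM", "saturated", "subfloor"]],
        on=["scene_id", "roi_id"], how="left",
    )
    log.info("converted %d ROI measurements (%d saturated, %d subfloor)",
             conv_summary["n"], conv_summary["n_saturated"], conv_summary["n_subfloor"])

    records = pair_density_with_ratio(all_records, measurements)
    return measurements, records_to_frame(records)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None  # NaN/inf are not valid JSON
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


@dataclass
class AnalysisReport:
    """Every statistic the pipeline reports, plus provenance to recompute it."""

    thresholds: OverloadThresholds
    overload_fractions: pd.DataFrame
    overload_comparisons: dict          # compartment -> GroupComparison or {"error": ...}
    density_comparison: object          # DensityComparison or {"error": ...}
    correlation_tau: object             # CorrelationResult or {"error": ...}
    ratio_summary: pd.DataFrame
    calcium_summary: pd.DataFrame
    normality: dict
    counts: dict
    config: dict
    version: str = _version

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(_jsonable(dataclasses.asdict(self)), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [
            f"ycquant analysis report (v{self.version})",
            "",
            f"Overload thresholds (95th pct of control YC ratios): "
            f"dendrite {self.thresholds.thr_dend:.3f}, spine {self.thresholds.thr_spine:.3f}",
            "",
            "Overload fractions (genotype x compartment):",
        ]
        for row in self.overload_fractions.itertuples(index=False):
            lines.append(f"  {row.genotype:>8} {row.compartment:>9}: "
                         f"{row.fraction:6.1%}  ({row.n_overload}/{row.n})")
        lines.append("")
        for comp, gc in self.overload_comparisons.items():
            if isinstance(gc, dict):
                lines.append(f"Overload model ({comp}): not fit — {gc['error']}")
            else:
                lines.append(
                    f"Overload model ({comp}): tau vs control log-odds "
                    f"{gc.effect_estimate:+.3f} ± {gc.std_error:.3f}, p = {gc.p_value:.4f}"
                )
        dc = self.density_comparison
        lines.append("")
        if isinstance(dc, dict):
            lines.append(f"Spine density comparison: not computed — {dc['error']}")
        else:
            lines.append(
                "Spine density (per-animal means, spines/um): "
                f"control {dc.mean_density_control:.3f} vs tau {dc.mean_density_tau:.3f} "
                f"({dc.percent_reduction:+.1f}% reduction), "
                f"t = {dc.t_statistic:.3f}, p = {dc.p_value:.4f}"
            )
        cr = self.correlation_tau
        if isinstance(cr, dict):
            lines.append(f"Density-ratio correlation (tau): not computed — {cr['error']}")
        else:
            lines.append(
                "Density vs parent-dendrite ratio (tau dendrites): "
                f"R^2 = {cr.r_squared:.3f} (OLS p = {cr.ols_p_value:.3f}), "
                f"Spearman rho = {cr.spearman_rho:.3f} (p = {cr.p_value:.3f}), n = {cr.n}"
            )
        lines.append("")
        lines.append(f"Counts: {json.dumps(self.counts)}")
        return "\n".join(lines)


def analyze_tables(
    measurements: pd.DataFrame,
    records: pd.DataFrame,
    config: PipelineConfig,
) -> AnalysisReport:
    """Run the full cohort statistics on quantification tables.

    Expects the column layout :func:`quantify_dataset` (or the synthetic
    fast path) produces.  Ratio-space analyses use all measurable ROIs,
    including saturated ratios; concentration summaries use only valid
    conversions.
    """
    usable = measurements[
        ~measurements.get("no_signal", pd.Series(False, index=measurements.index))
        & measurements["mean_ratio"].notna()
    ].copy()
    control = usable[usable["genotype"] == "control"]

    cal = config.calibration
    if config.estimate_bounds:
        r_min, r_max = estimate_rmin_rmax(control["mean_ratio"])
        cal = cal.replace(r_min=r_min, r_max=r_max)

    thresholds = compute_thresholds(control, q=config.overload_percentile)
    flagged, fractions = classify_overload(usable, thresholds)

    comparisons = {}
    for comp in ("dendrite", "spine"):
        sub = flagged[flagged["compartment"] == comp]
        try:
            comparisons[comp] = fit_overload_model(
                sub["overload"], sub["genotype"], sub["animal_id"]
            )
        except (ValueError, SeparationError) as exc:
            comparisons[comp] = {"error": str(exc)}

    try:
        density_cmp = compare_density(records, equal_var=config.equal_var)
    except ValueError as exc:
        density_cmp = {"error": str(exc)}

    try:
        correlation = correlate_density_ratio(records[records["genotype"] == "tau"])
    except ValueError as exc:
        correlation = {"error": str(exc)}

    ratio_summary = (
        usable.groupby(["genotype", "compartment"])["mean_ratio"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
    )
    conv, _ = batch_convert(usable, cal)
    valid = conv[~(conv["saturated"] | conv["subfloor"])]
    calcium_summary = (
        valid.groupby(["genotype", "compartment"])["calcium_nM"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
    )

    normality = {}
    inc = records[records["included"]]
    for geno, grp in inc.groupby("genotype"):
        per_animal = grp.groupby("animal_id")["density_per_um"].mean().to_numpy()
        if 3 <= per_animal.size <= 5000:
            w, p = check_normality(per_animal)
            normality[f"density_per_animal_{geno}"] = {"W": w, "p": p}

    counts = {
        "n_measurements": int(len(measurements)),
        "n_usable": int(len(usable)),
        "n_no_signal": int(len(measurements) - len(usable)),
        "n_saturated": int(conv["saturated"].sum()),
        "n_subfloor": int(conv["subfloor"].sum()),
        "n_dendrite_records": int(len(records)),
        "n_included_records": int(records["included"].sum()),
    }
    return AnalysisReport(
        thresholds=thresholds,
        overload_fractions=fractions,
        overload_comparisons=comparisons,
        density_comparison=density_cmp,
        correlation_tau=correlation,
        ratio_summary=ratio_summary,
        calcium_summary=calcium_summary,
        normality=normality,
        counts=counts,
        config=config.to_dict(),
    )
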