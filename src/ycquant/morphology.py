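"""Dendritic spine detection, segment filters and spine-density records.

Spine density (spines per micrometre of dendritic shaft) is the package's
synapse-loss proxy.  Dendrite shafts are given as traced 3-D polylines with a
shaft radius; spines are detected on the intensity volume as laterally
protruding blobs: after a median blur, voxels above an adaptive threshold and
clear of the shaft surface are connected-component labelled, and a component
whose intensity-weighted centroid protrudes 0.2–3 um from the shaft surface
counts as one spine.  Only segments longer than 20 um bearing at least three
spines enter the density statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

__all__ = [
    "DendriteTrace",
    "SpineDetection",
    "DendriteRecord",
    "SpineDetectorParams",
    "detect_spines",
    "compute_density",
    "filter_segments",
    "pair_density_with_ratio",
    "records_to_frame",
]

log = logging.getLogger(__name__)

MIN_SEGMENT_LENGTH_UM = 20.0  # segments must exceed this to be analysed
MIN_SPINES_PER_SEGMENT = 3


@dataclass
class DendriteTrace:
    """A traced dendrite shaft: ordered 3-D points (z, y, x in um) + radius."""

    dendrite_id: str
    polyline: np.ndarray  # (n, 3) points in um, (z, y, x)
    radius: float  # shaft radius, um
    animal_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.polyline = np.atleast_2d(np.asarray(self.polyline, dtype=float))
        if self.polyline.shape[0] < 2 or self.polyline.shape[1] != 3:
            raise ValueError(f"trace {self.dendrite_id}: polyline needs >= 2 3-D points")
        seg = np.diff(self.polyline, axis=0)
        if (np.linalg.norm(seg, axis=1) == 0).any():
            raise ValueError(f"trace {self.dendrite_id}: consecutive points must be distinct")
        if self.radius <= 0:
            raise ValueError(f"trace {self.dendrite_id}: radius must be positive")

    @property
    def length(self) -> float:
        """Arc length in um (sum of segment lengths)."""
        return float(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1).sum())


@dataclass(frozen=True)
class SpineDetection:
    """One detected spine: centroid position (um), parent id, protrusion."""

    position: tuple[float, float, float]
    attached_to: str
    protrusion_length: float  # distance from the shaft surface, um


@dataclass
class DendriteRecord:
    """Per-dendrite morphology summary paired with the shaft's YC ratio."""

    dendrite_id: str
    animal_id: str
    genotype: str
    length: float
    n_spines: int
    spine_density: float
    parent_ratio: float = math.nan
    included: bool = False


@dataclass(frozen=True)
class SpineDetectorParams:
    """Tunables of the protrusion detector.

    ``threshold_k`` scales the background-subtracted shaft intensity to set the
    detection threshold; protrusion bounds are distances from the shaft
    *surface* in um; ``median_size`` is the median-blur kernel in voxels.
    """

    threshold_k: float = 0.3
    min_protrusion: float = 0.2
    max_protrusion: float = 3.0
    median_size: int = 3
    background_percentile: float = 50.0
    halo_quantile: float = 0.25  # radial-profile quantile; low so sparse spines don't inflate it
    halo_bin_um: float = 0.2
    end_margin: float = 0.5      # um of arc excluded at each trace end (shaft end-cap blur)
    max_axial_offset: float = 0.6  # um; spines are counted from lateral protrusions only —
    # the axial PSF of in-vivo two-photon imaging cannot resolve z-projecting spines,
    # and its smear of the shaft into neighbouring planes would otherwise mimic them
    split_touching: bool = True    # watershed-split components with multiple intensity peaks
    min_peak_separation: float = 1.6  # um; lateral peak distance below which blobs stay merged
    # (a single blurred head spans ~1.5 um above threshold, so noise maxima
    # closer than ~0.8 um must not split it; closer true pairs are handled by
    # the footprint multiplicity below)
    neighbor_margin: float = 0.0      # um; shrink own territory at boundaries with other traces
    extent_multiplicity: bool = True  # split sub-resolution fusions by arc-length footprint
    single_spine_extent: float = 1.0  # um; above-threshold footprint of one blurred spine head


def _dist_arc_to_polyline(
    points_um: np.ndarray, polyline: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance from each point (um) to a 3-D polyline, the arc-length
    position of the closest point, and the closest point itself."""
    p = np.atleast_2d(points_um)[:, None, :]  # (n, 1, 3)
    a = polyline[None, :-1, :]  # (1, s, 3)
    b = polyline[None, 1:, :]
    ab = b - a
    seg_len = np.sqrt((ab * ab).sum(-1))  # (1, s)
    t = ((p - a) * ab).sum(-1) / (seg_len**2)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[..., None] * ab
    d = np.linalg.norm(p - closest, axis=-1)  # (n, s)
    i = d.argmin(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len[0])])
    rows = np.arange(d.shape[0])
    return d[rows, i], cum[i] + t[rows, i] * seg_len[0][i], closest[rows, i]


def _dist_to_polyline(points_um: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point (um) to a 3-D polyline."""
    return _dist_arc_to_polyline(points_um, polyline)[0]


def _dist_to_polyline_per_segment(point_um: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Distance from one point to each individual segment of a polyline."""
    p = np.asarray(point_um, dtype=float)
    a, b = polyline[:-1], polyline[1:]
    ab = b - a
    t = np.clip(((p - a) * ab).sum(1) / (ab * ab).sum(1), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[:, None] * ab), axis=1)


def detect_spines(
    intensity_volume: np.ndarray,
    trace: DendriteTrace,
    voxel_size: tuple[float, float, float],
    params: SpineDetectorParams = SpineDetectorParams(),
    other_traces: Sequence[DendriteTrace] = (),
) -> list[SpineDetection]:
    """Detect spines as lateral intensity protrusions along a traced shaft.

    Pipeline: median blur; shaft-halo suppression (the PSF smears the bright
    shaft into a radially decaying sleeve, estimated as a low quantile of
    intensity per radial-distance bin and subtracted, so that only signal in
    excess of the halo counts); adaptive residual threshold at
    ``k * (shaft_intensity - background)``; exclusion of an ``end_margin``
    of arc at the trace ends (the shaft's blurred end-caps protrude past the
    polyline and mimic spines); 26-connected component labelling of the
    surviving voxels within ``max_protrusion`` of the shaft surface; one
    detection per component at its residual-weighted centroid, kept when the
    centroid protrudes ``[min_protrusion, max_protrusion]`` from the shaft
    surface.  Deterministic given identical inputs.

    ``other_traces`` are the remaining dendrites of the field of view: a
    candidate voxel must lie closer to this shaft's surface than to any
    other's (nearest-territory rule), so a passing neighbour's body, halo and
    spines are never counted here — the automated counterpart of confirming
    that a counted spine connects to this shaft and not to a neighbour.

    Raises
    ------
    ValueError
        If the trace polyline leaves the volume.
    """
    vol = np.asarray(intensity_volume, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    extent = np.asarray(vol.shape) * vs
    if (trace.polyline < 0).any() or (trace.polyline >= extent).any():
        raise ValueError(f"trace {trace.dendrite_id} lies outside the volume extent {extent}")

    filt = ndimage.median_filter(vol, size=params.median_size)
    background = float(np.percentile(filt, params.background_percentile))

    # candidate voxels: above floor and inside the trace's dilated bounding box
    reach = trace.radius + params.max_protrusion + 0.5
    lo_vox = np.maximum(((trace.polyline.min(0) - reach) / vs).astype(int), 0)
    hi_vox = np.minimum(((trace.polyline.max(0) + reach) / vs).astype(int) + 1, vol.shape)
    box = tuple(slice(lo, hi) for lo, hi in zip(lo_vox, hi_vox))
    idx = np.argwhere(filt[box] > background) + lo_vox
    if idx.size == 0:
        return []
    coords_um = (idx + 0.5) * vs
    d_axis, arc, closest = _dist_arc_to_polyline(coords_um, trace.polyline)
    axial_offset = np.abs(coords_um[:, 0] - closest[:, 0])
    shaft_sel = d_axis <= trace.radius
    if not shaft_sel.any():
        return []
    shaft_intensity = float(filt[tuple(idx[shaft_sel].T)].mean())
    resid_threshold = params.threshold_k * (shaft_intensity - background)

    # radial halo profile of a blurred shaft: low quantile of intensity per
    # distance bin (spines are sparse along the shaft, so a low quantile
    # tracks the shaft's own halo, not the spines riding on it)
    intens = filt[tuple(idx.T)]

    def radial_halo(d: np.ndarray, radius: float) -> np.ndarray:
        r_out = radius + params.max_protrusion
        edges = np.arange(radius, r_out + 2 * params.halo_bin_um, params.halo_bin_um)
        centers, profile = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (d > lo) & (d <= hi)
            if sel.sum() >= 5:
                centers.append(0.5 * (lo + hi))
                profile.append(np.quantile(intens[sel], params.halo_quantile))
        if not centers:
            return np.full(d.shape, background)
        return np.interp(d, centers, profile, left=profile[0], right=background)

    # the expected non-spine signal at a voxel sums the background and every
    # shaft's halo excess — where dendrites approach or cross, their sleeves
    # add, and testing the residual against this trace's halo alone would
    # turn the neighbours' sleeves into spurious spines
    halo = np.maximum(radial_halo(d_axis, trace.radius), background)
    surf_own = d_axis - trace.radius
    territory = np.ones(d_axis.shape, dtype=bool)
    for other in other_traces:
        if other.dendrite_id == trace.dendrite_id:
            continue
        d_other = _dist_to_polyline(coords_um, other.polyline)
        halo = halo + np.clip(radial_halo(d_other, other.radius) - background, 0.0, None)
        territory &= (d_other - other.radius) > surf_own + params.neighbor_margin

    length = trace.length
    cand_sel = (
        (intens - halo > resid_threshold)
        & (d_axis > trace.radius + params.min_protrusion)
        & (d_axis <= trace.radius + params.max_protrusion)
        & (axial_offset <= params.max_axial_offset)
        & (arc >= params.end_margin)
        & (arc <= length - params.end_margin)
        & territory
    )
    cand = idx[cand_sel]
    if cand.shape[0] == 0:
        return []
    mask = np.zeros(vol.shape, dtype=bool)
    mask[tuple(cand.T)] = True
    resid = np.zeros(vol.shape)
    resid[tuple(idx.T)] = np.clip(intens - halo, 0.0, None)
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))

    if params.split_touching and n_comp:
        # neighbouring spines blur into one component; split at intensity
        # peaks more than min_peak_separation apart (marker-based watershed).
        # A tiny deterministic ramp breaks the plateaus of median-filtered
        # count data, which would otherwise yield one "peak" per tied voxel.
        ramp = np.linspace(0.0, 1e-3, resid.size).reshape(resid.shape)
        resid_tb = np.where(resid > 0, resid + ramp, 0.0)
        h = max(int(round(0.5 * params.min_peak_separation / vs[1])), 1)
        peaks = peak_local_max(resid_tb, footprint=np.ones((1, 2 * h + 1, 2 * h + 1)), labels=labels)
        if len(peaks):
            markers = np.zeros(vol.shape, dtype=int)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            labels = watershed(-resid_tb, markers, mask=mask)
            n_comp = len(peaks)

    regions = []
    for comp in range(1, n_comp + 1):
        comp_idx = np.argwhere(labels == comp)
        w = resid[tuple(comp_idx.T)]
        if w.sum() <= 0:
            continue
        centroid_um = ((comp_idx + 0.5) * vs * w[:, None]).sum(0) / w.sum()
        protrusion = float(_dist_to_polyline(centroid_um[None, :], trace.polyline)[0]) - trace.radius
        if params.min_protrusion <= protrusion <= params.max_protrusion:
            regions.append((comp_idx, w, centroid_um))

    # two spines closer than the optical resolution fuse into one blob with no
    # intensity dip, but the blob's footprint along the shaft still stretches;
    # a blob spanning well over one single-spine extent along the local shaft
    # direction counts as several.  Footprint, unlike integrated mass, is
    # independent of spine brightness and of how much of the blob the
    # exclusion zone hides.  The single-spine reference is taken from the
    # dendrite's own regions (their median footprint — most blobs are
    # singles), since the absolute footprint depends on how far above the
    # halo the scene's threshold landed.
    seg_vec = np.diff(trace.polyline, axis=0)
    seg_unit = seg_vec / np.linalg.norm(seg_vec, axis=1, keepdims=True)
    projections = []
    for comp_idx, w, centroid_um in regions:
        # tangent of the segment closest to the blob centre
        i_seg = int(np.argmin(_dist_to_polyline_per_segment(centroid_um, trace.polyline)))
        projections.append(((comp_idx + 0.5) * vs) @ seg_unit[i_seg])
    ref_extent = params.single_spine_extent
    if params.extent_multiplicity and len(regions) >= 5:
        ref_extent = float(
            np.clip(np.median([np.ptp(p) for p in projections]),
                    0.7 * params.single_spine_extent, 1.6 * params.single_spine_extent)
        )
    detections: list[SpineDetection] = []
    for (comp_idx, w, centroid_um), proj in zip(regions, projections):
        mult = 1
        if params.extent_multiplicity and ref_extent > 0:
            mult = max(1, int(round(np.ptp(proj) / ref_extent)))
        pieces = [(comp_idx, w)]
        if mult > 1:
            # split along the shaft direction into contiguous groups of ~equal mass
            order = np.argsort(proj, kind="stable")
            cum = np.cumsum(w[order])
            bounds = np.searchsorted(cum, cum[-1] * np.arange(1, mult) / mult)
            pieces = [
                (comp_idx[part], w[part])
                for part in np.split(order, bounds)
                if part.size and w[part].sum() > 0
            ]
        for part_idx, part_w in pieces:
            centroid_um = ((part_idx + 0.5) * vs * part_w[:, None]).sum(0) / part_w.sum()
            protrusion = float(_dist_to_polyline(centroid_um[None, :], trace.polyline)[0]) - trace.radius
            detections.append(
                SpineDetection(
                    position=tuple(float(c) for c in centroid_um),
                    attached_to=trace.dendrite_id,
                    protrusion_length=protrusion,
                )
            )
    detections.sort(key=lambda s: s.position)
    return detections


def compute_density(
    trace: DendriteTrace,
    spines: Sequence[SpineDetection],
    min_length: float = MIN_SEGMENT_LENGTH_UM,
    min_spines: int = MIN_SPINES_PER_SEGMENT,
) -> DendriteRecord:
    """Spine density = count / arc length, with the segment-inclusion flag.

    A segment is ``included`` iff its length strictly exceeds ``min_length``
    (default 20 um) AND it bears at least ``min_spines`` (default 3) spines.
    """
    for s in spines:
        if s.attached_to != trace.dendrite_id:
            raise ValueError(f"spine attached to {s.attached_to!r}, not {trace.dendrite_id!r}")
    length = trace.length
    if length <= 0:
        raise ValueError(f"trace {trace.dendrite_id}: zero length")
    n = len(spines)
    return DendriteRecord(
        dendrite_id=trace.dendrite_id,
        animal_id=trace.animal_id,
        genotype=trace.genotype,
        length=length,
        n_spines=n,
        spine_density=n / length,
        included=(length > min_length and n >= min_spines),
    )


def filter_segments(records: Iterable[DendriteRecord]) -> list[DendriteRecord]:
    """Keep only records passing the inclusion rule; log exclusion counts."""
    records = list(records)
    kept = [r for r in records if r.included]
    n_short = sum(1 for r in records if r.length <= MIN_SEGMENT_LENGTH_UM)
    n_sparse = sum(1 for r in records if r.n_spines < MIN_SPINES_PER_SEGMENT)
    log.info(
        "filter_segments: kept %d/%d (%d with length <= %g um, %d with < %d spines)",
        len(kept), len(records), n_short, MIN_SEGMENT_LENGTH_UM, n_sparse, MIN_SPINES_PER_SEGMENT,
    )
    return kept


def pair_density_with_ratio(
    records: Iterable[DendriteRecord],
    measurements: pd.DataFrame,
) -> list[DendriteRecord]:
    """Fill each record's parent_ratio from the matching dendrite ROI measurement.

    ``measurements`` must hold dendrite-compartment rows with ``roi_id`` equal
    to the dendrite_id.  Records without a measurement are excluded with a
    logged warning; duplicate measurement ids raise an ambiguity error.
    """
    dend = measurements[measurements["compartment"] == "dendrite"]
    if dend["roi_id"].duplicated().any():
        dups = dend.loc[dend["roi_id"].duplicated(), "roi_id"].tolist()
        raise ValueError(f"duplicate dendrite measurements for ids {dups}")
    lookup = dict(zip(dend["roi_id"], dend["mean_ratio"]))
    out: list[DendriteRecord] = []
    for rec in records:
        if rec.dendrite_id not in lookup or not math.isfinite(lookup[rec.dendrite_id]):
            log.warning("dendrite %s has no ratio measurement; excluded from pairing", rec.dendrite_id)
            continue
        out.append(replace(rec, parent_ratio=float(lookup[rec.dendrite_id])))
    return out


def records_to_frame(records: Iterable[DendriteRecord]) -> pd.DataFrame:
    """Tabulate records with the CSV column layout the pipeline emits."""
    return pd.DataFrame(
        [
            {
                "dendrite_id": r.dendrite_id,
                "animal_id": r.animal_id,
                "genotype": r.genotype,
                "length_um": r.length,
                "n_spines": r.n_spines,
                "density_per_um": r.spine_density,
                "parent_ratio": r.parent_ratio,
                "included": r.included,
            }
            for r in records
        ],
        columns=["dendrite_id", "animal_id", "genotype", "length_um", "n_spines",
                 "density_per_um", "parent_ratio", "included"],
    )
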