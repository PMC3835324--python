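"""Ground-truth cohort simulation and two-channel stack rendering.

This module emulates the study conditions the pipeline is meant to analyse:
a cohort of 6 control and 9 tau-overexpressing animals, ~10 imaged volumes
per animal, dendrites bearing spines at a genotype-dependent density
(control 0.6 spines/um; tau reduced 30% by default), and per-structure
resting calcium drawn from a log-normal distribution moment-matched to a
control-like mean of 125.3 nM and SD of 101 nM — identical across genotypes
by default, encoding a calcium-independent spine-loss effect.  An optional
tau "overload" mixture (a high component at 3x the median) exists only to
give the overload statistics a detectable alternative for power testing.

Two forward models are provided:

* :func:`render_scene` — the full imaging physics: true calcium maps to a
  YC ratio through the calibration inverse; channels are set so YFP/CFP
  equals that ratio inside each structure at the configured photon budget;
  per-channel background is added, a Gaussian PSF applied, and Poisson shot
  noise drawn.  This is what the image-level pipeline must undo.
* :func:`simulate_measurement_tables` — a statistical shortcut that draws
  per-ROI mean-ratio measurements directly from the same ground-truth model
  with noise at the photon-statistics scale, for replicate studies where
  rendering thousands of volumes would be pointless.

Every stochastic call derives from a single integer seed and is bit-
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import CalibrationParams, DEFAULT_CALIBRATION, calcium_to_ratio
from .imaging import DEFAULT_VOXEL_SIZE, Roi, TwoChannelStack
from .morphology import DendriteTrace, _dist_to_polyline

__all__ = [
    "CohortConfig",
    "GroundTruthScene",
    "lognormal_params_from_moments",
    "sample_cohort",
    "render_scene",
    "scene_rois",
    "export_truth",
    "simulate_measurement_tables",
    "make_fixture_suite",
]


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("moments must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


_CA_MU, _CA_SIGMA = lognormal_params_from_moments(125.3, 101.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and imaging-physics parameters of the simulated cohort.

    Defaults reproduce the analysed study conditions: 6 control + 9 tau
    animals, 10 volumes each, ~31 dendrite ROIs per volume (~4650 dendrites
    in total) and ~77 spine ROIs per animal (~1155 spines); control spine
    density 0.6/um with a 30% tau reduction and 10% between-animal CV;
    resting calcium log-normal with mean 125.3 nM / SD 101 nM in both
    genotypes.  ``overload_fraction_tau`` defaults to 0 (no calcium effect).
    """

    # cohort design
    n_control_animals: int = 6
    n_tau_animals: int = 9
    volumes_per_animal: int = 10
    dendrites_per_volume: int = 31
    spine_rois_per_animal: int = 77
    dendrites_for_spine_analysis: int = 8

    # biology
    control_density: float = 0.6            # spines per um, control
    tau_density_factor: float = 0.7         # tau density = factor * control
    animal_density_cv: float = 0.10         # between-animal CV of density
    calcium_log_mean: float = _CA_MU        # log-normal mu of resting calcium (nM)
    calcium_log_sd: float = _CA_SIGMA       # log-normal sigma
    overload_fraction_tau: float = 0.0      # tau mixture weight of the high component
    overload_calcium_factor: float = 3.0    # high component scale (x median)
    min_spine_spacing: float = 0.4          # um, hard-core placement constraint

    # rendered-scene geometry
    volume_shape: tuple[int, int, int] = (16, 160, 160)      # voxels (z, y, x)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE  # um
    rendered_dendrites_per_volume: int = 3
    min_trace_separation: float = 3.0       # um; dendrites cannot interpenetrate
    segment_length_range: tuple[float, float] = (22.0, 28.0)  # um
    shaft_radius: float = 0.5               # um
    spine_head_radius: float = 0.45         # um (mushroom-spine head ~0.9 um across)
    spine_protrusion_range: tuple[float, float] = (0.8, 1.5)  # um from shaft surface

    # imaging physics
    photon_budget: float = 500.0            # expected counts/voxel in-structure
    background: tuple[float, float] = (40.0, 60.0)  # (CFP, YFP) offsets, counts
    psf_sigma: tuple[float, float, float] = (0.6, 0.25, 0.25)  # um (z, y, x)

    # fast-path measurement noise (effective voxels averaged per ROI)
    roi_voxels_dendrite: int = 100
    roi_voxels_spine: int = 20

    calibration: CalibrationParams = DEFAULT_CALIBRATION
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_control_animals, self.n_tau_animals, self.volumes_per_animal,
                  self.dendrites_per_volume, self.rendered_dendrites_per_volume)
        if any(c <= 0 for c in counts):
            raise ValueError("cohort counts must be positive")
        if not 0 < self.tau_density_factor <= 1:
            raise ValueError("tau_density_factor must be in (0, 1]")
        if not 0 <= self.overload_fraction_tau < 1:
            raise ValueError("overload_fraction_tau must be in [0, 1)")
        if self.control_density <= 0 or self.photon_budget < 0:
            raise ValueError("control_density must be > 0 and photon_budget >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic call")

    def animal_ids(self) -> list[tuple[str, str]]:
        """(animal_id, genotype) pairs, controls first."""
        out = [(f"ctl{i+1:02d}", "control") for i in range(self.n_control_animals)]
        out += [(f"tau{i+1:02d}", "tau") for i in range(self.n_tau_animals)]
        return out

    def density_for(self, genotype: str) -> float:
        return self.control_density * (self.tau_density_factor if genotype == "tau" else 1.0)


@dataclass
class GroundTruthScene:
    """One imaged volume's ground truth: traces, spines, per-structure calcium."""

    scene_id: str
    animal_id: str
    genotype: str
    traces: list[DendriteTrace]
    spines: dict[str, np.ndarray]        # dendrite_id -> (n, 3) positions, um
    true_calcium: dict[str, float]       # structure_id -> nM
    spine_arc: dict[str, np.ndarray]     # dendrite_id -> arc positions, um

    def spine_ids(self, dendrite_id: str) -> list[str]:
        return [f"{dendrite_id}_s{j:03d}" for j in range(len(self.spines[dendrite_id]))]


def _sample_calcium(rng: np.random.Generator, n: int, config: CohortConfig, genotype: str) -> np.ndarray:
    """Resting calcium draws (nM); tau optionally mixes in a high component."""
    c = rng.lognormal(config.calcium_log_mean, config.calcium_log_sd, size=n)
    if genotype == "tau" and config.overload_fraction_tau > 0:
        hot = rng.random(n) < config.overload_fraction_tau
        c[hot] = rng.lognormal(
            config.calcium_log_mean + math.log(config.overload_calcium_factor),
            config.calcium_log_sd,
            size=int(hot.sum()),
        )
    return c


def _place_spines(
    rng: np.random.Generator, length: float, rate: float, spacing: float,
    end_margin: float = 0.5,
) -> np.ndarray:
    """Arc positions of spines: Poisson count at ``rate``/um, positions uniform
    on the interior of the segment (an ``end_margin`` is kept clear at each
    end) subject to the hard-core spacing (rejection sampling, deterministic
    even-spacing fallback when the draw is too crowded to place)."""
    n = rng.poisson(rate * length)
    lo, hi = end_margin, max(length - end_margin, end_margin + 1e-6)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return rng.uniform(lo, hi, size=1)
    for _ in range(200):
        pos = np.sort(rng.uniform(lo, hi, size=n))
        if np.diff(pos).min() >= spacing:
            return pos
    # crowded draw: evenly spread with jitter inside each slot
    slot = (hi - lo) / n
    jitter = rng.uniform(0.0, max(slot - spacing, 0.0), size=n)
    return lo + np.arange(n) * slot + jitter


def _sample_trace(
    rng: np.random.Generator, config: CohortConfig, dendrite_id: str,
    animal_id: str, genotype: str,
) -> DendriteTrace:
    """A smooth 3-D polyline inside the volume, near one z-plane of voxel
    centres (two-photon dendrite segments run roughly parallel to the
    cortical surface)."""
    vz, vy, vx = config.voxel_size
    nz, ny, nx = config.volume_shape
    extent_y, extent_x = ny * vy, nx * vx
    margin = 3.0
    z_plane = rng.integers(3, nz - 3)
    z0 = (z_plane + 0.5) * vz
    length = rng.uniform(*config.segment_length_range)
    step = 2.0
    n_steps = max(int(round(length / step)), 2)
    theta = rng.uniform(0, 2 * math.pi)
    p = np.array([z0, rng.uniform(margin, extent_y - margin), rng.uniform(margin, extent_x - margin)])
    pts = [p.copy()]
    for _ in range(n_steps):
        theta += rng.normal(0.0, math.radians(8.0))
        d = np.array([0.0, math.sin(theta), math.cos(theta)])
        cand = p + step * d
        # steer back inside the margin box instead of leaving it
        for ax, lo, hi in ((1, margin, extent_y - margin), (2, margin, extent_x - margin)):
            if not lo <= cand[ax] <= hi:
                d[ax] = -d[ax]
                theta = math.atan2(d[1], d[2])
                cand = p + step * d
        cand[0] = z0 + rng.normal(0.0, 0.05)
        pts.append(cand)
        p = cand
    return DendriteTrace(
        dendrite_id=dendrite_id,
        polyline=np.asarray(pts),
        radius=config.shaft_radius,
        animal_id=animal_id,
        genotype=genotype,
    )


def _arc_to_point(trace: DendriteTrace, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point on the polyline at arc length ``s`` and the local unit tangent."""
    seg = np.diff(trace.polyline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg_len) - 1)
    t = (s - cum[i]) / seg_len[i]
    return trace.polyline[i] + t * seg[i], seg[i] / seg_len[i]


def sample_cohort(config: CohortConfig) -> list[GroundTruthScene]:
    """Draw the full rendered-scene ground truth for every animal and volume.

    Per scene: ``rendered_dendrites_per_volume`` smooth traces, spine
    positions along each trace (Poisson count at the genotype's density,
    hard-core spacing), and an independent log-normal calcium draw for every
    structure (shaft and each spine).  Bit-reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    scenes: list[GroundTruthScene] = []
    for animal_id, genotype in config.animal_ids():
        density_mult = max(rng.normal(1.0, config.animal_density_cv), 0.1)
        for v in range(config.volumes_per_animal):
            scene_id = f"{animal_id}_v{v:02d}"
            traces, spines, spine_arc, calcium = [], {}, {}, {}
            for d in range(config.rendered_dendrites_per_volume):
                dendrite_id = f"{scene_id}_d{d:02d}"
                # dendrites are solid objects: resample until the new trace
                # keeps clear of the ones already in the field of view
                for _ in range(50):
                    trace = _sample_trace(rng, config, dendrite_id, animal_id, genotype)
                    if all(
                        _dist_to_polyline(trace.polyline, t.polyline).min()
                        >= config.min_trace_separation
                        for t in traces
                    ):
                        break
                traces.append(trace)
                arc = _place_spines(
                    rng, trace.length,
                    config.density_for(genotype) * density_mult,
                    config.min_spine_spacing,
                )
                positions = []
                for s in arc:
                    centre, tangent = _arc_to_point(trace, s)
                    side = rng.choice([-1.0, 1.0])
                    normal = np.array([0.0, -tangent[2], tangent[1]])  # in-plane normal
                    normal /= np.linalg.norm(normal)
                    protrusion = rng.uniform(*config.spine_protrusion_range)
                    offset = trace.radius + protrusion
                    pos = centre + side * offset * normal
                    # on the inside of a bend the normal offset can fall back
                    # onto another stretch of the shaft; a spine must protrude
                    # from the surface, so prefer the side where it does
                    if _dist_to_polyline(pos[None, :], trace.polyline)[0] < trace.radius + 0.8 * protrusion:
                        alt = centre - side * offset * normal
                        if (_dist_to_polyline(alt[None, :], trace.polyline)[0]
                                > _dist_to_polyline(pos[None, :], trace.polyline)[0]):
                            pos = alt
                    positions.append(pos)
                spine_arc[dendrite_id] = arc
                spines[dendrite_id] = (
                    np.asarray(positions) if positions else np.empty((0, 3))
                )
                calcium[dendrite_id] = float(_sample_calcium(rng, 1, config, genotype)[0])
                for sid, c in zip(
                    [f"{dendrite_id}_s{j:03d}" for j in range(len(arc))],
                    _sample_calcium(rng, len(arc), config, genotype),
                ):
                    calcium[sid] = float(c)
            scenes.append(
                GroundTruthScene(
                    scene_id=scene_id, animal_id=animal_id, genotype=genotype,
                    traces=traces, spines=spines, true_calcium=calcium,
                    spine_arc=spine_arc,
                )
            )
    return scenes


def _paint_structures(scene: GroundTruthScene, config: CohortConfig):
    """Rasterise structure masks.  Returns (structure_id, mask) pairs with the
    shafts first so that spines override at overlaps."""
    nzyx = config.volume_shape
    vs = np.asarray(config.voxel_size)
    coords = np.stack(
        np.meshgrid(*[(np.arange(n) + 0.5) * v for n, v in zip(nzyx, vs)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    out = []
    for trace in scene.traces:
        d = np.empty(coords.shape[0])
        for lo in range(0, coords.shape[0], 100_000):
            d[lo:lo + 100_000] = _dist_to_polyline(coords[lo:lo + 100_000], trace.polyline)
        out.append((trace.dendrite_id, (d <= trace.radius).reshape(nzyx), d.reshape(nzyx)))
    for trace in scene.traces:
        for sid, pos in zip(scene.spine_ids(trace.dendrite_id), scene.spines[trace.dendrite_id]):
            dist = np.linalg.norm(coords - pos, axis=1).reshape(nzyx)
            out.append((sid, dist <= config.spine_head_radius, dist))
    return out


def render_scene(
    scene: GroundTruthScene,
    config: CohortConfig,
    seed: int | None = None,
    apply_psf: bool = True,
    apply_noise: bool = True,
) -> tuple[TwoChannelStack, np.ndarray, pd.DataFrame]:
    """Render a scene's two-channel stack plus its ROI label volume.

    For every structure, the true ratio ``r* = calcium_to_ratio(true_calcium)``
    fixes the channel split: CFP = photon_budget / (1 + r*), YFP = r* x CFP, so
    YFP/CFP = r* exactly inside the structure.  Per-channel background is
    added, both channels convolved with the Gaussian PSF, then Poisson shot
    noise drawn (each stage can be disabled for exactness tests).

    ROI label cores sit inside each structure (shaft: within 80% of the
    radius; spine: within the head radius) so that PSF blur at structure
    edges does not contaminate the ROI mean.

    Returns ``(stack, labels, roi_meta)``; label ``k`` in the volume belongs
    to ``roi_meta`` row with ``label == k``.
    """
    rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)
    cfp = np.zeros(config.volume_shape, dtype=float)
    yfp = np.zeros(config.volume_shape, dtype=float)
    labels = np.zeros(config.volume_shape, dtype=np.uint16)
    meta_rows = []
    label_cores: dict[int, np.ndarray] = {}
    structures = _paint_structures(scene, config)
    spine_parent = {
        sid: t.dendrite_id for t in scene.traces for sid in scene.spine_ids(t.dendrite_id)
    }
    label = 0
    for sid, mask, dist in structures:
        if not mask.any():
            # sub-voxel structure fell between voxel centres: claim the nearest voxel
            mask = mask.copy()
            mask[np.unravel_index(np.argmin(dist), mask.shape)] = True
        c_true = scene.true_calcium[sid]
        r_star = calcium_to_ratio(c_true, config.calibration)
        cfp_val = config.photon_budget / (1.0 + r_star)
        yfp_val = r_star * cfp_val
        cfp[mask] = cfp_val
        yfp[mask] = yfp_val
        is_spine = sid in spine_parent
        core = dist <= (config.spine_head_radius if is_spine else 0.8 * config.shaft_radius)
        core &= mask
        if not core.any():
            core = mask
        label += 1
        labels[core] = label
        core_order = np.argwhere(core)
        core_dist = dist[tuple(core_order.T)]
        label_cores[label] = core_order[np.argsort(core_dist, kind="stable")]
        meta_rows.append(
            {
                "label": label,
                "roi_id": sid,
                "compartment": "spine" if is_spine else "dendrite",
                "animal_id": scene.animal_id,
                "genotype": scene.genotype,
                "parent_id": spine_parent.get(sid, ""),
            }
        )
    # overlapping cores paint over each other (close spine pairs); make sure
    # every ROI keeps at least one voxel, reclaiming its centre-most voxel
    for _ in range(10):
        present = set(np.unique(labels))
        missing = [lb for lb in label_cores if lb not in present]
        if not missing:
            break
        for lb in missing:
            z, y, x = label_cores[lb][0]
            labels[z, y, x] = lb

    b_cfp, b_yfp = config.background
    cfp += b_cfp
    yfp += b_yfp
    if apply_psf and any(s > 0 for s in config.psf_sigma):
        sigma_vox = [s / v for s, v in zip(config.psf_sigma, config.voxel_size)]
        cfp = ndimage.gaussian_filter(cfp, sigma_vox)
        yfp = ndimage.gaussian_filter(yfp, sigma_vox)
    if apply_noise:
        cfp = rng.poisson(cfp).astype(float)
        yfp = rng.poisson(yfp).astype(float)
    stack = TwoChannelStack(cfp=cfp, yfp=yfp, voxel_size=config.voxel_size)
    return stack, labels, pd.DataFrame(meta_rows)


def scene_rois(labels: np.ndarray, meta: pd.DataFrame) -> list[Roi]:
    """Roi objects for a rendered scene (thin wrapper kept here for symmetry)."""
    from .io import rois_from_labels

    return rois_from_labels(labels, meta)


def export_truth(scenes: Sequence[GroundTruthScene]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth tables keyed by the ids the pipeline emits.

    Returns ``(structures, dendrites)``: one row per structure (shaft or
    spine) with its true calcium, and one row per dendrite with true length,
    spine count and density.
    """
    s_rows, d_rows = [], []
    for scene in scenes:
        for trace in scene.traces:
            did = trace.dendrite_id
            n_sp = len(scene.spines[did])
            s_rows.append(
                {
                    "structure_id": did, "scene_id": scene.scene_id,
                    "animal_id": scene.animal_id, "genotype": scene.genotype,
                    "compartment": "dendrite", "parent_id": "",
                    "true_calcium_nM": scene.true_calcium[did],
                }
            )
            for sid in scene.spine_ids(did):
                s_rows.append(
                    {
                        "structure_id": sid, "scene_id": scene.scene_id,
                        "animal_id": scene.animal_id, "genotype": scene.genotype,
                        "compartment": "spine", "parent_id": did,
                        "true_calcium_nM": scene.true_calcium[sid],
                    }
                )
            d_rows.append(
                {
                    "dendrite_id": did, "scene_id": scene.scene_id,
                    "animal_id": scene.animal_id, "genotype": scene.genotype,
                    "true_length_um": trace.length, "true_n_spines": n_sp,
                    "true_density_per_um": n_sp / trace.length,
                }
            )
    return pd.DataFrame(s_rows), pd.DataFrame(d_rows)


def _ratio_noise_sd(r: np.ndarray, photon_budget: float, n_voxels: int) -> np.ndarray:
    """Shot-noise SD of an ROI-mean ratio estimate.

    With the photon budget split so YFP/CFP = r, per-voxel counts are
    N_yfp = rN/(1+r) and N_cfp = N/(1+r); first-order error propagation gives
    Var(r_hat) = r^2 (1/N_yfp + 1/N_cfp) / n = r (1+r)^2 / (N n).
    """
    if photon_budget <= 0:
        return np.full_like(np.asarray(r, dtype=float), np.inf)
    return np.sqrt(r * (1.0 + r) ** 2 / (photon_budget * n_voxels))


def simulate_measurement_tables(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Statistical forward model: per-ROI measurements without voxel rendering.

    Draws, per animal, ``volumes_per_animal * dendrites_per_volume`` dendrite
    ROIs and ``spine_rois_per_animal`` spine ROIs.  Each ROI's true calcium
    maps to a true ratio through the calibration inverse; the observed mean
    ratio adds Gaussian noise with the shot-noise SD of a mean over the
    configured effective ROI voxel count at the configured photon budget.
    Spine-density records are drawn for ``dendrites_for_spine_analysis``
    dendrites per animal (segment lengths uniform on 21-60 um, Poisson spine
    counts at the animal's density).

    Returns ``(measurements, dendrite_records)`` with the same columns the
    image-level pipeline emits, enabling identical downstream statistics.
    """
    rng = np.random.default_rng(config.seed)
    cal = config.calibration
    m_rows, d_rows = [], []
    for animal_id, genotype in config.animal_ids():
        density_mult = max(rng.normal(1.0, config.animal_density_cv), 0.1)
        density = config.density_for(genotype) * density_mult

        n_dend = config.volumes_per_animal * config.dendrites_per_volume
        for comp, n_roi, n_vox in (
            ("dendrite", n_dend, config.roi_voxels_dendrite),
            ("spine", config.spine_rois_per_animal, config.roi_voxels_spine),
        ):
            c_true = _sample_calcium(rng, n_roi, config, genotype)
            r_true = np.array([calcium_to_ratio(c, cal) for c in c_true])
            r_obs = r_true + rng.normal(
                0.0, _ratio_noise_sd(r_true, config.photon_budget, n_vox)
            )
            r_obs = np.clip(r_obs, 1e-6, None)
            for i in range(n_roi):
                m_rows.append(
                    {
                        "roi_id": f"{animal_id}_{comp[0]}{i:04d}",
                        "animal_id": animal_id, "genotype": genotype,
                        "compartment": comp, "parent_id": "",
                        "mean_ratio": float(r_obs[i]),
                        "n_valid_voxels": n_vox, "no_signal": False,
                        "true_calcium_nM": float(c_true[i]),
                    }
                )

        for j in range(config.dendrites_for_spine_analysis):
            length = rng.uniform(21.0, 60.0)
            n_spines = int(rng.poisson(density * length))
            c_shaft = float(_sample_calcium(rng, 1, config, genotype)[0])
            r_shaft = calcium_to_ratio(c_shaft, cal) + float(
                rng.normal(0.0, _ratio_noise_sd(
                    np.array(calcium_to_ratio(c_shaft, cal)),
                    config.photon_budget, config.roi_voxels_dendrite))
            )
            d_rows.append(
                {
                    "dendrite_id": f"{animal_id}_sd{j:03d}",
                    "animal_id": animal_id, "genotype": genotype,
                    "length_um": length, "n_spines": n_spines,
                    "density_per_um": n_spines / length,
                    "parent_ratio": max(r_shaft, 1e-6),
                    "included": length > 20.0 and n_spines >= 3,
                    "true_density_per_um": density,
                }
            )
    return pd.DataFrame(m_rows), pd.DataFrame(d_rows)


def make_fixture_suite(outdir: str | Path, seed: int = 20230) -> "Path":
    """Write a miniature rendered cohort (2+2 animals, 2 volumes each) to disk.

    The suite exercises every on-disk format the pipeline consumes (channel
    TIFFs, ROI label volumes + CSV, SWC traces, truth CSVs, config YAML,
    checksum manifest) and regenerates bit-identically from its seed.
    """
    from . import io as ycio
    from .config import PipelineConfig

    outdir = Path(outdir)
    # 2 animals x 4 volumes x 3 dendrites gives 24 control dendrite ROIs —
    # above the overload-threshold minimum of 20 — at the field-of-view
    # crowding the detector is validated for, so the full
    # simulate -> quantify -> analyze chain runs green on the suite
    config = replace(
        CohortConfig(seed=seed),
        n_control_animals=2, n_tau_animals=2,
        volumes_per_animal=4, rendered_dendrites_per_volume=3,
    )
    scenes = sample_cohort(config)
    scene_seeds = np.random.default_rng(seed + 1).integers(0, 2**31 - 1, size=len(scenes))
    for scene, sseed in zip(scenes, scene_seeds):
        stack, labels, meta = render_scene(scene, config, seed=int(sseed))
        scene_dir = outdir / "scenes" / scene.scene_id
        ycio.write_stack(scene_dir, stack)
        ycio.write_label_volume(scene_dir, labels, meta)
        traces_dir = scene_dir / "traces"
        traces_dir.mkdir(parents=True, exist_ok=True)
        for trace in scene.traces:
            ycio.write_swc(traces_dir / f"{trace.dendrite_id}.swc", trace)
    structures, dendrites = export_truth(scenes)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    structures.to_csv(truth_dir / "structures.csv", index=False)
    dendrites.to_csv(truth_dir / "dendrites.csv", index=False)
    PipelineConfig(seed=seed).to_yaml(outdir / "config.yaml")
    ycio.write_manifest(outdir, extra={"seed": seed, "n_scenes": len(scenes)})
    return outdir
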