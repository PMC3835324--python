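"""File formats the pipeline consumes and emits.

Stacks are multi-page TIFF, one file per channel (float or integer counts).
ROIs travel as an integer label volume (TIFF) keyed to a CSV metadata table;
dendrite traces as SWC (one file per dendrite, coordinates in micrometres).
Dataset directories carry a JSON manifest with SHA-256 checksums so that
seeded regeneration can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import DEFAULT_VOXEL_SIZE, Roi, TwoChannelStack
from .morphology import DendriteTrace

__all__ = [
    "write_stack", "read_stack",
    "write_label_volume", "read_label_volume", "rois_from_labels",
    "write_swc", "read_swc",
    "write_manifest", "verify_manifest", "sha256_file",
]


def write_stack(directory: str | Path, stack: TwoChannelStack) -> dict[str, Path]:
    """Write the two channels as ``cfp.tif`` / ``yfp.tif`` (float32)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in (("cfp", stack.cfp), ("yfp", stack.yfp)):
        p = directory / f"{name}.tif"
        tifffile.imwrite(p, vol.astype(np.float32))
        paths[name] = p
    return paths


def read_stack(
    directory: str | Path,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> TwoChannelStack:
    """Read ``cfp.tif`` / ``yfp.tif`` from a scene directory."""
    directory = Path(directory)
    try:
        cfp = tifffile.imread(directory / "cfp.tif")
        yfp = tifffile.imread(directory / "yfp.tif")
    except (FileNotFoundError, tifffile.TiffFileError, ValueError) as exc:
        raise OSError(f"cannot read channel TIFFs in {directory}: {exc}") from exc
    return TwoChannelStack(cfp=np.asarray(cfp), yfp=np.asarray(yfp), voxel_size=voxel_size)


def write_label_volume(directory: str | Path, labels: np.ndarray, meta: pd.DataFrame) -> None:
    """Write an ROI label volume (uint16 TIFF) plus its CSV metadata table.

    ``meta`` must have a ``label`` column mapping positive integer labels to
    roi_id / compartment / animal_id / genotype / parent_id.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 ROI labels in one volume")
    tifffile.imwrite(directory / "roi_labels.tif", labels.astype(np.uint16))
    meta.to_csv(directory / "rois.csv", index=False)


def read_label_volume(directory: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    directory = Path(directory)
    labels = np.asarray(tifffile.imread(directory / "roi_labels.tif"))
    meta = pd.read_csv(directory / "rois.csv", dtype={"label": int})
    return labels, meta


def rois_from_labels(labels: np.ndarray, meta: pd.DataFrame) -> list[Roi]:
    """Materialise Roi objects from a label volume and its metadata table."""
    rois = []
    for row in meta.itertuples(index=False):
        vox = np.argwhere(labels == row.label)
        if vox.shape[0] == 0:
            raise ValueError(f"label {row.label} ({row.roi_id}) absent from the label volume")
        parent = getattr(row, "parent_id", None)
        if parent is not None and (pd.isna(parent) or parent == ""):
            parent = None
        rois.append(
            Roi(
                roi_id=str(row.roi_id),
                compartment=str(row.compartment),
                voxels=vox,
                animal_id=str(row.animal_id),
                genotype=str(row.genotype),
                parent_id=None if parent is None else str(parent),
            )
        )
    return rois


def write_swc(path: str | Path, trace: DendriteTrace) -> None:
    """Write a trace as SWC: ``id type x y z radius parent`` in um.

    Our polylines are (z, y, x); SWC stores (x, y, z).  The shaft radius is
    attached to every node.  Type code 3 marks a (basal) dendrite.
    """
    lines = [f"# dendrite_id={trace.dendrite_id} animal_id={trace.animal_id} genotype={trace.genotype}"]
    for i, (z, y, x) in enumerate(trace.polyline, start=1):
        parent = i - 1 if i > 1 else -1
        lines.append(f"{i} 3 {x:.6f} {y:.6f} {z:.6f} {trace.radius:.6f} {parent}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> DendriteTrace:
    meta = {"dendrite_id": Path(path).stem, "animal_id": "", "genotype": ""}
    points, radii = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("#"):
            for token in line.lstrip("#").split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    if k in meta:
                        meta[k] = v
            continue
        if not line:
            continue
        _, _, x, y, z, r, _ = line.split()
        points.append((float(z), float(y), float(x)))
        radii.append(float(r))
    return DendriteTrace(
        dendrite_id=meta["dendrite_id"],
        polyline=np.asarray(points),
        radius=float(np.median(radii)),
        animal_id=meta["animal_id"],
        genotype=meta["genotype"],
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(root: str | Path, extra: dict | None = None) -> Path:
    """Checksum every file under ``root`` into ``manifest.json``."""
    root = Path(root)
    files = sorted(
        p.relative_to(root).as_posix()
        for p in root.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": {f: sha256_file(root / f) for f in files},
        **(extra or {}),
    }
    out = root / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def verify_manifest(root: str | Path) -> list[str]:
    """Return the list of files whose checksum disagrees with the manifest."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    return [
        f for f, digest in manifest["files"].items()
        if not (root / f).is_file() or sha256_file(root / f) != digest
    ]
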