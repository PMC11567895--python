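"""Reading and writing of scene bundles, masks and result tables.

A *scene bundle* is a directory with one multi-page TIFF per channel and
nucleus, a label-mask TIFF, a delimited annotation table and (for synthetic
scenes) a JSON ground-truth sidecar. All voxel coordinates in files are
0-based with axis order (z, y, x); this is asserted on load.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from skimage.measure import label as _sklabel

from .config import BIN_CENTRES
from .profiling import BinnedProfile, MaskError
from .synthetic import SyntheticScene

__all__ = [
    "NucleusRecord",
    "DimensionMismatchError",
    "MissingAnnotationError",
    "AnnotationOutsideMaskError",
    "save_scene_bundle",
    "load_scene_bundle",
    "central_plane_from_3d",
    "write_profiles",
    "read_profiles",
    "write_table",
]


class DimensionMismatchError(ValueError):
    """Stacks and masks of one nucleus disagree in shape."""


class MissingAnnotationError(KeyError):
    """A nucleus has no nucleolus-centre annotation."""


class AnnotationOutsideMaskError(ValueError):
    """The nucleolus-centre annotation falls outside the nucleus mask."""


@dataclass
class NucleusRecord:
    """One nucleus: masks, annotation and labels."""

    nucleus_id: str
    tissue: str
    condition: str
    annotation: Tuple[int, int, int]          # (z, y, x), 0-based voxels
    mask2d: np.ndarray
    mask3d: Optional[np.ndarray] = None
    central_z: Optional[int] = None
    replicate: str = ""


def central_plane_from_3d(mask3d: np.ndarray) -> Tuple[int, np.ndarray]:
    """Central z slice of a 3D mask: the z of its centroid, rounded.

    A centroid exactly halfway between two slices rounds toward the lower z
    for determinism. Returns (z index, 2D mask at that slice).
    """
    mask = np.asarray(mask3d, dtype=bool)
    if not mask.any():
        raise MaskError("empty 3D mask")
    zc = float(np.nonzero(mask)[0].mean())
    z_index = int(math.ceil(zc - 0.5))  # half rounds down
    return z_index, mask[z_index]


# ---------------------------------------------------------------------------
# scene bundles


def save_scene_bundle(scenes: Sequence[SyntheticScene], path) -> None:
    """Write scenes as TIFF channels + masks, an annotation CSV and truth JSON."""
    if len(scenes) == 0:
        raise ValueError("no scenes to write")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    meta = {
        "voxel_xy": scenes[0].config.voxel_xy,
        "voxel_z": scenes[0].config.voxel_z,
        "axis_order": "zyx",
        "coordinate_base": 0,
    }
    for scene in scenes:
        sid = scene.nucleus_id
        tifffile.imwrite(out / f"{sid}_chromatin.tif",
                         scene.chromatin.astype(np.float32))
        tifffile.imwrite(out / f"{sid}_nucleolus.tif",
                         scene.nucleolus.astype(np.float32))
        if scene.spot is not None:
            tifffile.imwrite(out / f"{sid}_spot.tif",
                             scene.spot.astype(np.float32))
        tifffile.imwrite(out / f"{sid}_mask3d.tif",
                         scene.mask3d.astype(np.uint8))
        z, y, x = scene.annotation
        rows.append(
            {
                "nucleus_id": sid,
                "z": z, "y": y, "x": x,
                "condition": scene.condition,
                "tissue": scene.config.tissue,
            }
        )
        truth = dataclasses.asdict(scene.truth)
        truth["ring_params"] = dataclasses.asdict(scene.truth.ring_params)
        with open(out / f"{sid}_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=float)
    pd.DataFrame(rows).to_csv(out / "annotations.csv", index=False)
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_scene_bundle(path) -> Tuple[Dict[str, Dict[str, np.ndarray]],
                                     List[NucleusRecord]]:
    """Load a scene bundle directory into channel stacks and nucleus records.

    Returns ``(channels, records)`` where ``channels[nucleus_id]`` maps
    channel name -> stack. Validates shapes against masks
    (:class:`DimensionMismatchError`), presence of annotations
    (:class:`MissingAnnotationError`) and annotation location
    (:class:`AnnotationOutsideMaskError`). A nucleus with only a 3D mask gets
    its 2D mask from :func:`central_plane_from_3d`.
    """
    root = Path(path)
    ann_path = root / "annotations.csv"
    if not ann_path.exists():
        raise MissingAnnotationError(f"no annotations.csv in {root}")
    ann = pd.read_csv(ann_path)
    channels: Dict[str, Dict[str, np.ndarray]] = {}
    records: List[NucleusRecord] = []
    ids_with_files = {
        p.name.rsplit("_", 1)[0] for p in root.glob("*_*.tif")
    }
    annotated_ids = set(ann["nucleus_id"].astype(str))
    missing = ids_with_files - annotated_ids
    if missing:
        raise MissingAnnotationError(
            f"nuclei without annotation: {sorted(missing)}"
        )

    for _, row in ann.iterrows():
        sid = str(row["nucleus_id"])
        chans: Dict[str, np.ndarray] = {}
        for tif in sorted(root.glob(f"{sid}_*.tif")):
            name = tif.stem[len(sid) + 1 :]
            if name.startswith("mask"):
                continue
            chans[name] = tifffile.imread(tif)
        mask3d = mask2d = None
        p3 = root / f"{sid}_mask3d.tif"
        p2 = root / f"{sid}_mask2d.tif"
        if p3.exists():
            mask3d = tifffile.imread(p3).astype(bool)
        if p2.exists():
            mask2d = tifffile.imread(p2).astype(bool)
        if mask3d is None and mask2d is None:
            raise DimensionMismatchError(f"nucleus {sid} has no mask")

        ref_shape = mask3d.shape if mask3d is not None else None
        for name, stack in chans.items():
            if ref_shape is not None and stack.shape != ref_shape:
                raise DimensionMismatchError(
                    f"channel {name!r} of nucleus {sid}: shape {stack.shape} "
                    f"!= mask shape {ref_shape}"
                )
            if mask2d is not None and stack.shape[-2:] != mask2d.shape:
                raise DimensionMismatchError(
                    f"channel {name!r} of nucleus {sid} mismatches the 2D mask"
                )

        central_z = None
        if mask3d is not None:
            if _sklabel(mask3d, connectivity=3).max() != 1:
                raise MaskError(f"nucleus {sid}: mask is not a single region")
            central_z, derived2d = central_plane_from_3d(mask3d)
            if mask2d is None:
                mask2d = derived2d
        annotation = (int(row["z"]), int(row["y"]), int(row["x"]))
        inside = (
            mask3d[annotation]
            if mask3d is not None
            else mask2d[annotation[1], annotation[2]]
        )
        if not inside:
            raise AnnotationOutsideMaskError(
                f"nucleus {sid}: annotation {annotation} outside the mask"
            )
        channels[sid] = chans
        records.append(
            NucleusRecord(
                nucleus_id=sid,
                tissue=str(row.get("tissue", "")),
                condition=str(row.get("condition", "")),
                annotation=annotation,
                mask2d=mask2d,
                mask3d=mask3d,
                central_z=central_z,
                replicate=str(row.get("replicate", "")),
            )
        )
    return channels, records


# ---------------------------------------------------------------------------
# result tables


def write_profiles(profiles: Sequence[BinnedProfile], path,
                   long_path=None) -> None:
    """Write profiles as a heat-map matrix CSV plus a tidy long table.

    The matrix has one row per nucleus and 20 columns named by bin centre
    (2.5 ... 97.5); row order preserves input order. The long table
    (``<path stem>_long.csv`` by default) has one row per (nucleus, bin).
    Values round-trip at full precision.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to write")
    path = Path(path)
    cols = [f"{c:g}" for c in BIN_CENTRES]
    wide = pd.DataFrame(
        [p.values for p in profiles], columns=cols
    )
    wide.insert(0, "nucleus_id", [p.nucleus_id for p in profiles])
    wide.insert(1, "condition", [p.condition for p in profiles])
    wide.insert(2, "normalized", [p.normalized for p in profiles])
    wide.insert(3, "mean_ray_length", [p.mean_ray_length for p in profiles])
    wide.to_csv(path, index=False, float_format="%.17g")

    if long_path is None:
        long_path = path.with_name(path.stem + "_long" + path.suffix)
    long = wide.melt(
        id_vars=["nucleus_id", "condition", "normalized", "mean_ray_length"],
        var_name="bin_centre_pct",
        value_name="intensity",
    )
    long["bin_centre_pct"] = long["bin_centre_pct"].astype(float)
    long.to_csv(long_path, index=False, float_format="%.17g")


def read_profiles(path) -> List[BinnedProfile]:
    """Read a heat-map matrix CSV back into profiles."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [f"{c:g}" for c in BIN_CENTRES]
    out = []
    for _, row in df.iterrows():
        out.append(
            BinnedProfile(
                values=row[cols].to_numpy(dtype=float),
                normalized=bool(row.get("normalized", True)),
                nucleus_id=str(row.get("nucleus_id", "")),
                condition=str(row.get("condition", "")),
                mean_ray_length=float(row.get("mean_ray_length", float("nan"))),
            )
        )
    return out


def write_table(rows, path) -> None:
    """Write a list of dict rows (or a DataFrame) as CSV; empty input errors."""
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("refusing to write an empty table")
    df.to_csv(Path(path), index=False)
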