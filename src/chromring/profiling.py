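"""Radial chromatin profiling of single nuclei.

From a 2D central-plane image, a nucleus mask and a nucleolus-centre
annotation, the pipeline is:

1. extract the ordered pixel contour of the nucleus mask;
2. cast one ray from the nucleolus centre to every contour point, sampling
   intensities by bilinear interpolation every 0.5 px;
3. normalize each ray's sample distances by its centre-to-contour length
   (0% = centre, 100% = contour);
4. pool all samples into twenty 5%-wide bins (centres 2.5%, 7.5%, ... 97.5%)
   and average per bin;
5. divide the binned profile by its maximum.

The result is the single-nucleus chromatin profile (SNCP). Profiles of many
nuclei under one condition are averaged with a 95% confidence band. An
absolute-distance variant re-expresses each sample as micrometres beyond the
nucleolar edge. Rays whose nucleolar-edge-to-contour span is below the
resolution limit can be filtered out before binning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import Point, Polygon
from skimage.measure import label as _sklabel

from .config import BIN_CENTRES

__all__ = [
    "RadialRay",
    "BinnedProfile",
    "ConditionProfile",
    "EdgeProfile",
    "MaskError",
    "extract_contour",
    "sample_rays",
    "attach_edge_crossings",
    "filter_resolvable_rays",
    "bin_and_normalize",
    "condition_profile",
    "nucleolus_edge_profile",
    "profile_nucleus",
]

N_BINS = 20
BIN_WIDTH = 5.0


class MaskError(ValueError):
    """Mask is empty, multi-component or otherwise unusable."""


@dataclass
class RadialRay:
    """One centre-to-contour ray of interpolated intensities."""

    index: int
    distances: np.ndarray            # voxels, strictly increasing from 0
    intensities: np.ndarray
    length: float                    # centre-to-contour distance, voxels
    origin: Tuple[float, float] = (0.0, 0.0)   # (y, x) of the centre
    end: Tuple[float, float] = (0.0, 0.0)      # (y, x) of the contour point
    edge_crossing: Optional[float] = None  # distance at which the ray exits the nucleolus

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("ray length must be > 0")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("ray distances must be strictly increasing")

    def positions(self, distances: Optional[np.ndarray] = None) -> np.ndarray:
        """(2, n) array of (y, x) sample positions at the given distances."""
        d = self.distances if distances is None else np.asarray(distances)
        t = d / self.length
        oy, ox = self.origin
        ey, ex = self.end
        return np.vstack([oy + t * (ey - oy), ox + t * (ex - ox)])


@dataclass
class BinnedProfile:
    """A 20-bin radial intensity profile of one nucleus (the SNCP)."""

    values: np.ndarray                       # length 20
    bin_centres: np.ndarray = field(default_factory=lambda: np.array(BIN_CENTRES))
    normalized: bool = True
    nucleus_id: str = ""
    condition: str = ""
    n_per_bin: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS, dtype=int))
    interpolated_bins: Tuple[int, ...] = ()
    mean_ray_length: float = float("nan")    # voxels; used for %->voxel conversion

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"profile must have exactly {N_BINS} bins")


@dataclass
class ConditionProfile:
    """Across-nuclei mean profile with a 95% confidence band."""

    mean: np.ndarray
    ci_halfwidth: np.ndarray
    n: int
    condition: str = ""
    bin_centres: np.ndarray = field(default_factory=lambda: np.array(BIN_CENTRES))


@dataclass
class EdgeProfile:
    """Mean intensity vs absolute distance (µm) beyond the nucleolar edge."""

    bin_centres_um: np.ndarray
    values: np.ndarray
    n_per_bin: np.ndarray
    n_rays_excluded: int = 0


# ---------------------------------------------------------------------------
# contour extraction

_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def extract_contour(mask2d: np.ndarray) -> np.ndarray:
    """Ordered closed pixel contour of a single connected 2D region.

    Returns an (N, 2) array of (y, x) perimeter-pixel coordinates obtained by
    Moore-neighbour boundary tracing, clockwise from the topmost-leftmost
    boundary pixel. Every boundary pixel of the mask lies within one pixel of
    the returned polygon.
    """
    mask = np.asarray(mask2d, dtype=bool)
    if not mask.any():
        raise MaskError("empty mask")
    if _sklabel(mask, connectivity=2).max() != 1:
        raise MaskError("mask must contain exactly one connected component")

    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    ys, xs = np.nonzero(padded)
    order = np.lexsort((xs, ys))
    start = (int(ys[order[0]]), int(xs[order[0]]))

    if padded.sum() == 1:
        return np.array([[start[0] - 1, start[1] - 1]])

    contour = [start]
    prev = (start[0], start[1] - 1)   # background pixel west of start
    cur = start
    first_state = (cur, prev)
    max_steps = 4 * padded.size
    for _ in range(max_steps):
        i = _MOORE.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            dy, dx = _MOORE[(i + k) % 8]
            cand = (cur[0] + dy, cur[1] + dx)
            if padded[cand]:
                nxt = cand
                pdy, pdx = _MOORE[(i + k - 1) % 8]
                prev = (cur[0] + pdy, cur[1] + pdx)
                break
        if nxt is None:  # isolated pixel (handled above); defensive
            break
        if (nxt, prev) == first_state and len(contour) > 1:
            break
        cur = nxt
        if cur == start and (cur, prev) == first_state:
            break
        contour.append(cur)
        if (cur, prev) == first_state:
            contour.pop()
            break
    # de-duplicate the closing vertex if tracing re-appended the start
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    pts = np.array(contour, dtype=float) - 1.0  # undo padding offset
    return pts.astype(int) if np.allclose(pts, np.round(pts)) else pts


# ---------------------------------------------------------------------------
# ray sampling


def sample_rays(
    plane: np.ndarray,
    centre: Tuple[float, float],
    contour: np.ndarray,
    step: float = 0.5,
) -> List[RadialRay]:
    """Cast one ray from the centre to every contour point.

    Intensities are sampled by bilinear interpolation every ``step`` voxels
    along each centre-to-contour segment, with the final sample exactly at
    the contour point. The centre must lie strictly inside the contour
    polygon.
    """
    contour = np.asarray(contour, dtype=float)
    cy, cx = float(centre[0]), float(centre[1])
    poly = Polygon([(x, y) for y, x in contour])
    if not poly.buffer(0).contains(Point(cx, cy)):
        raise ValueError("centre must lie strictly inside the contour")

    all_coords = []
    dist_lists = []
    for (py, px) in contour:
        length = math.hypot(py - cy, px - cx)
        if length == 0:
            dist_lists.append(np.array([0.0]))
            all_coords.append(np.array([[cy], [cx]]))
            continue
        n_steps = int(math.floor(length / step))
        d = np.arange(n_steps + 1) * step
        if d[-1] < length - 1e-12:
            d = np.append(d, length)
        else:
            d[-1] = length
        t = d / length
        coords = np.vstack([cy + t * (py - cy), cx + t * (px - cx)])
        dist_lists.append(d)
        all_coords.append(coords)

    flat = np.concatenate(all_coords, axis=1)
    vals = map_coordinates(np.asarray(plane, dtype=float), flat, order=1, mode="nearest")
    rays: List[RadialRay] = []
    pos = 0
    for i, d in enumerate(dist_lists):
        n = len(d)
        py, px = contour[i]
        rays.append(
            RadialRay(
                index=i,
                distances=d,
                intensities=vals[pos : pos + n],
                length=float(d[-1]),
                origin=(cy, cx),
                end=(float(py), float(px)),
            )
        )
        pos += n
    return rays


def attach_edge_crossings(
    rays: Sequence[RadialRay],
    nucleolus_mask2d: np.ndarray,
    centre: Optional[Tuple[float, float]] = None,
) -> List[RadialRay]:
    """Record where each ray exits the nucleolus mask.

    The crossing distance is the midpoint between the last in-nucleolus and
    first out-of-nucleolus sample along the ray; rays starting outside the
    mask get a crossing of 0; rays that never exit keep
    ``edge_crossing=None``. Rays are modified in place and returned.
    """
    mask = np.asarray(nucleolus_mask2d, dtype=bool)
    for ray in rays:
        inside = _mask_along(mask, ray.positions())
        if not inside[0]:
            ray.edge_crossing = 0.0
            continue
        outside = np.nonzero(~inside)[0]
        if outside.size == 0:
            ray.edge_crossing = None
            continue
        k = int(outside[0])
        ray.edge_crossing = float(0.5 * (ray.distances[k - 1] + ray.distances[k]))
    return list(rays)


def _mask_along(mask: np.ndarray, coords: np.ndarray) -> np.ndarray:
    iy = np.clip(np.round(coords[0]).astype(int), 0, mask.shape[0] - 1)
    ix = np.clip(np.round(coords[1]).astype(int), 0, mask.shape[1] - 1)
    return mask[iy, ix]


def filter_resolvable_rays(
    rays: Sequence[RadialRay], min_length: float = 9.0
) -> Tuple[List[RadialRay], int]:
    """Drop rays whose nucleolar-edge-to-contour span is below ``min_length``.

    Mirrors the resolution-limit filter used for muscle nuclei, where only
    radial profiles with at least 9 px between the nucleolar edge and the
    nuclear periphery are resolvable. Returns (kept rays, number discarded).
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    if any(r.edge_crossing is None for r in rays):
        raise ValueError("rays lack nucleolus-edge crossing information")
    kept = [r for r in rays if (r.length - r.edge_crossing) >= min_length]
    discarded = len(rays) - len(kept)
    if not kept:
        warnings.warn("all rays fall below the resolvable length", stacklevel=2)
    return kept, discarded


# ---------------------------------------------------------------------------
# binning


def bin_and_normalize(
    rays: Sequence[RadialRay],
    method: str = "pooled",
    nucleus_id: str = "",
    condition: str = "",
) -> BinnedProfile:
    """Pool ray samples into 20 radial bins and max-normalize.

    Each ray's sample distances are divided by that ray's length (0% centre,
    100% contour). Samples are assigned to half-open 5% bins ([0,5)% -> bin
    centre 2.5%, ...), the last bin closed at 100%. With ``method="pooled"``
    (default) all samples are pooled before the per-bin mean; with
    ``method="per_ray"`` each ray is binned first and the per-ray bin means
    are averaged. The binned profile is divided by its maximum; an all-zero
    profile is left unnormalized and flagged.
    """
    if len(rays) == 0:
        raise ValueError("need at least one ray")
    if any(r.length <= 0 for r in rays):
        raise ValueError("ray of zero length")
    if method not in ("pooled", "per_ray"):
        raise ValueError(f"unknown binning method {method!r}")

    if method == "pooled":
        rel = np.concatenate([r.distances / r.length for r in rays]) * 100.0
        vals = np.concatenate([r.intensities for r in rays])
        sums = np.zeros(N_BINS)
        counts = np.zeros(N_BINS, dtype=int)
        idx = np.minimum((rel // BIN_WIDTH).astype(int), N_BINS - 1)
        np.add.at(sums, idx, vals)
        np.add.at(counts, idx, 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    else:
        per_ray = []
        counts = np.zeros(N_BINS, dtype=int)
        for r in rays:
            rel = r.distances / r.length * 100.0
            idx = np.minimum((rel // BIN_WIDTH).astype(int), N_BINS - 1)
            s = np.zeros(N_BINS)
            c = np.zeros(N_BINS, dtype=int)
            np.add.at(s, idx, r.intensities)
            np.add.at(c, idx, 1)
            per_ray.append(np.where(c > 0, s / np.maximum(c, 1), np.nan))
            counts += c
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(np.vstack(per_ray), axis=0)

    interpolated: Tuple[int, ...] = ()
    if np.isnan(means).any():
        bad = np.nonzero(np.isnan(means))[0]
        good = np.nonzero(~np.isnan(means))[0]
        if good.size == 0:
            raise ValueError("no samples in any bin")
        centres = np.asarray(BIN_CENTRES)
        means[bad] = np.interp(centres[bad], centres[good], means[good])
        interpolated = tuple(int(b) for b in bad)

    normalized = False
    peak = means.max()
    if peak > 0:
        means = means / peak
        normalized = True
    else:
        warnings.warn("all-zero profile; max-normalization skipped", stacklevel=2)

    return BinnedProfile(
        values=means,
        normalized=normalized,
        nucleus_id=nucleus_id,
        condition=condition,
        n_per_bin=counts,
        interpolated_bins=interpolated,
        mean_ray_length=float(np.mean([r.length for r in rays])),
    )


def condition_profile(profiles: Sequence[BinnedProfile],
                      condition: str = "") -> ConditionProfile:
    """Across-nuclei mean profile with a normal-approximation 95% band.

    The half-width is 1.96 * SD / sqrt(n); with a single profile the band is
    zero by convention.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    states = {p.normalized for p in profiles}
    if len(states) > 1:
        raise ValueError("profiles mix normalized and unnormalized states")
    mat = np.vstack([p.values for p in profiles])
    mean = mat.mean(axis=0)
    n = mat.shape[0]
    if n == 1:
        warnings.warn("single profile: confidence band is zero", stacklevel=2)
        half = np.zeros(N_BINS)
    else:
        half = 1.96 * mat.std(axis=0, ddof=1) / math.sqrt(n)
    if not condition:
        labels = {p.condition for p in profiles if p.condition}
        condition = labels.pop() if len(labels) == 1 else ""
    return ConditionProfile(mean=mean, ci_halfwidth=half, n=n, condition=condition)


def nucleolus_edge_profile(
    rays: Sequence[RadialRay],
    voxel_xy: float,
    bin_width_um: float = 0.25,
) -> EdgeProfile:
    """Mean intensity binned by absolute µm distance beyond the nucleolar edge.

    Uses each ray's recorded nucleolus-edge crossing; samples inside the
    nucleolus are discarded and rays that never exit the nucleolus are
    excluded with a warning.
    """
    usable = [r for r in rays if r.edge_crossing is not None]
    excluded = len(rays) - len(usable)
    if excluded:
        warnings.warn(f"{excluded} rays never exit the nucleolus; excluded",
                      stacklevel=2)
    if not usable:
        raise ValueError("no rays with a nucleolus-edge crossing")
    dists = []
    vals = []
    for r in usable:
        beyond = r.distances > r.edge_crossing
        dists.append((r.distances[beyond] - r.edge_crossing) * voxel_xy)
        vals.append(r.intensities[beyond])
    d = np.concatenate(dists)
    v = np.concatenate(vals)
    n_bins = int(math.ceil(d.max() / bin_width_um)) if d.size else 1
    idx = np.minimum((d // bin_width_um).astype(int), n_bins - 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    np.add.at(sums, idx, v)
    np.add.at(counts, idx, 1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = (np.arange(n_bins) + 0.5) * bin_width_um
    return EdgeProfile(bin_centres_um=centres, values=means, n_per_bin=counts,
                       n_rays_excluded=excluded)


# ---------------------------------------------------------------------------
# high-level per-nucleus driver


def profile_nucleus(
    plane: np.ndarray,
    mask2d: np.ndarray,
    centre: Tuple[float, float],
    step: float = 0.5,
    nucleolus_mask2d: Optional[np.ndarray] = None,
    min_ray_length: Optional[float] = None,
    method: str = "pooled",
    nucleus_id: str = "",
    condition: str = "",
) -> BinnedProfile:
    """Full single-nucleus pipeline: contour, rays, (filter,) bin, normalize."""
    contour = extract_contour(mask2d)
    rays = sample_rays(plane, centre, contour, step=step)
    if nucleolus_mask2d is not None:
        rays = attach_edge_crossings(rays, nucleolus_mask2d, centre)
    if min_ray_length is not None:
        rays, _ = filter_resolvable_rays(rays, min_ray_length)
        if not rays:
            raise ValueError("no resolvable rays for this nucleus")
    return bin_and_normalize(rays, method=method, nucleus_id=nucleus_id,
                             condition=condition)
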