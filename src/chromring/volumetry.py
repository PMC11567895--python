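"""Nucleolar 3D detection, Gaussian volumetry and FISH quantification.

Nucleoli (or FISH foci) are detected in 3D by smoothing the marker channel
with a small Gaussian (0.75 voxel), thresholding with an automatic algorithm
(Yen or Li) inside a search mask, and labelling connected components with
full 26-neighbourhood connectivity. The selected object is then quantified
by fitting a separable 3D Gaussian

    g(x, y, z) = A exp(-(x-x_c)^2/2σ_x^2) exp(-(y-y_c)^2/2σ_y^2) exp(-(z-z_c)^2/2σ_z^2) + B

to the *raw* voxel intensities inside its mask; the nucleolar volume is the
ellipsoid V = (4/3) π σ_z σ_y σ_x, reported in voxel^3 and µm^3.

FISH signal is quantified as the background-corrected sum of the voxel
values in the segmented objects, the background being the median intensity
of in-nucleus, non-spot pixels at the central z slice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import curve_fit
from skimage.filters import threshold_li, threshold_yen

__all__ = [
    "GaussianSpotFit",
    "SpotSegmentation",
    "FishQuant",
    "RelativeVolumeResult",
    "stack_cylinder",
    "extend_mask_z",
    "detect_spots",
    "select_nucleolus",
    "fit_gaussian3d",
    "relative_volume",
    "integrated_fish_signal",
    "nucleolar_nuclear_area",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class SpotNotFoundError(RuntimeError):
    """No segmented object matches the annotation or nucleus mask."""


@dataclass
class SpotSegmentation:
    """Labelled candidate spots from threshold-based 3D detection."""

    labels: np.ndarray              # int array, 0 = background
    method: str                     # thresholding algorithm actually used
    threshold: float
    n_labels: int
    voxel_counts: dict              # label -> voxel count

    @property
    def empty(self) -> bool:
        return self.n_labels == 0


@dataclass
class GaussianSpotFit:
    """Separable 3D Gaussian fit of one spot and its ellipsoid volume."""

    A: float
    B: float
    centre: Tuple[float, float, float]     # (z, y, x), voxels
    sigma: Tuple[float, float, float]      # (σ_z, σ_y, σ_x), voxels
    volume_vox3: float
    volume_um3: Optional[float]
    rss: float
    converged: bool
    n_voxels: int

    @staticmethod
    def ellipsoid_volume(sz: float, sy: float, sx: float) -> float:
        return 4.0 / 3.0 * math.pi * sz * sy * sx


@dataclass
class FishQuant:
    """Background-corrected integrated FISH intensity for one nucleus."""

    corrected_sum: float
    background_median: float
    spot_voxels: int


@dataclass
class RelativeVolumeResult:
    """Per-cell volume ratios vs a control cohort, with a rank-sum test."""

    ratios: np.ndarray          # treated volumes / control median
    median_ratio: float
    statistic: float
    pvalue: float


def stack_cylinder(mask2d: np.ndarray, z_range: Tuple[int, int]) -> np.ndarray:
    """Replicate a 2D mask across a half-open z range into a 'cylinder'."""
    mask = np.asarray(mask2d, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    z0, z1 = z_range
    if z1 <= z0:
        raise ValueError("z_range must be non-empty")
    return np.broadcast_to(mask, (z1 - z0,) + mask.shape).copy()


def extend_mask_z(
    mask2d: np.ndarray,
    central_z: int,
    n_z: int,
    n_slices: int = 10,
) -> Tuple[np.ndarray, bool]:
    """Extend a central-plane mask ``n_slices`` planes above and below.

    With the default ten 200-nm planes each way the mask spans up to 21
    slices; at the stack boundary the extension is clipped and the returned
    flag reports it.
    """
    mask = np.asarray(mask2d, dtype=bool)
    if not 0 <= central_z < n_z:
        raise ValueError("central_z outside the stack")
    lo = central_z - n_slices
    hi = central_z + n_slices
    clipped = lo < 0 or hi > n_z - 1
    lo = max(lo, 0)
    hi = min(hi, n_z - 1)
    out = np.zeros((n_z,) + mask.shape, dtype=bool)
    out[lo : hi + 1] = mask
    return out, clipped


def detect_spots(
    stack: np.ndarray,
    search_mask: np.ndarray,
    smoothing_sigma: float = 0.75,
    method: str = "auto",
) -> SpotSegmentation:
    """Smooth, threshold and label bright 3D objects inside a search mask.

    The stack is Gaussian-smoothed (``smoothing_sigma`` voxels, isotropic),
    thresholded by Yen or Li computed on the in-mask intensities, and the
    foreground labelled with 26-connectivity; components outside the search
    mask are discarded. ``method="auto"`` tries Yen first and falls back to
    Li when Yen returns no component or more than five. An empty result is a
    warning, not an error.
    """
    search = np.asarray(search_mask, dtype=bool)
    if not search.any():
        raise ValueError("search mask is empty")
    smoothed = ndimage.gaussian_filter(np.asarray(stack, dtype=float), smoothing_sigma)
    inside = smoothed[search]

    def _segment(thr_func, name):
        if np.ptp(inside) == 0:
            return None
        thr = float(thr_func(inside))
        fg = (smoothed > thr) & search
        labels, n = ndimage.label(fg, structure=_CONN26)
        return SpotSegmentation(
            labels=labels,
            method=name,
            threshold=thr,
            n_labels=int(n),
            voxel_counts={
                int(l): int(c)
                for l, c in zip(*np.unique(labels[labels > 0], return_counts=True))
            },
        )

    if method == "yen":
        seg = _segment(threshold_yen, "yen")
    elif method == "li":
        seg = _segment(threshold_li, "li")
    elif method == "auto":
        seg = _segment(threshold_yen, "yen")
        if seg is None or seg.empty or seg.n_labels > 5:
            seg = _segment(threshold_li, "li") or seg
    else:
        raise ValueError(f"unknown thresholding method {method!r}")

    if seg is None or seg.empty:
        warnings.warn("thresholding found no foreground voxels", stacklevel=2)
        return SpotSegmentation(
            labels=np.zeros_like(search, dtype=np.int32),
            method=method,
            threshold=float("nan"),
            n_labels=0,
            voxel_counts={},
        )
    return seg


def select_nucleolus(
    seg: SpotSegmentation,
    annotation: Optional[Tuple[int, int, int]] = None,
    nucleus_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pick the nucleolus label: by annotation, else largest in-nucleus label.

    Mirrors the manual removal of objects from other tissues: the label
    containing the annotated centre wins; otherwise the label with the
    largest overlap with the nucleus mask is taken.
    """
    if seg.empty:
        raise SpotNotFoundError("segmentation is empty")
    if annotation is not None:
        lab = int(seg.labels[tuple(int(c) for c in annotation)])
        if lab > 0:
            return seg.labels == lab
    if nucleus_mask is not None:
        nucleus = np.asarray(nucleus_mask, dtype=bool)
        best, best_overlap = 0, 0
        for lab in seg.voxel_counts:
            overlap = int(np.count_nonzero((seg.labels == lab) & nucleus))
            if overlap > best_overlap:
                best, best_overlap = lab, overlap
        if best:
            return seg.labels == best
    raise SpotNotFoundError("no label contains the annotation or overlaps the nucleus")


def _gauss3d(coords, A, B, zc, yc, xc, sz, sy, sx):
    z, y, x = coords
    return B + A * np.exp(
        -((z - zc) ** 2) / (2 * sz**2)
        - ((y - yc) ** 2) / (2 * sy**2)
        - ((x - xc) ** 2) / (2 * sx**2)
    )


def fit_gaussian3d(
    stack: np.ndarray,
    spot_mask: np.ndarray,
    voxel_size: Optional[Tuple[float, float, float]] = None,
) -> GaussianSpotFit:
    """Fit a separable 3D Gaussian to the raw intensities inside a mask.

    The fit is performed on unsmoothed voxel values (smoothing is for
    detection only, and would inflate the widths). Initialisation uses the
    intensity-weighted centroid and second moments of the mask. The derived
    ellipsoid volume is reported in voxel^3 and, when ``voxel_size``
    (z, y, x pitches in µm) is given, in µm^3.
    """
    mask = np.asarray(spot_mask, dtype=bool)
    n_vox = int(np.count_nonzero(mask))
    if n_vox < 10:
        raise ValueError(f"spot mask has {n_vox} voxels; need at least 10")
    coords = np.array(np.nonzero(mask), dtype=float)
    vals = np.asarray(stack, dtype=float)[mask]

    vmin, vmax = float(vals.min()), float(vals.max())
    w = np.clip(vals - vmin, 1e-12, None)
    w = w / w.sum()
    centroid = coords @ w
    second = np.sqrt(np.clip(((coords - centroid[:, None]) ** 2) @ w, 0.25, None))
    p0 = (vmax - vmin if vmax > vmin else 1.0, vmin,
          *centroid, *second)
    span = [max(c.max() - c.min(), 1.0) for c in coords]
    lo = [0.0, vmin - abs(vmin) - 1.0,
          *(c.min() - 2 for c in coords), 0.05, 0.05, 0.05]
    hi = [2 * (vmax - vmin) + 1.0, vmax,
          *(c.max() + 2 for c in coords), *(4 * s for s in span)]
    p0 = tuple(np.clip(p0, lo, hi))

    converged = True
    try:
        popt, _ = curve_fit(_gauss3d, coords, vals, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
    except RuntimeError:
        converged = False
        popt = np.asarray(p0)
    A, B, zc, yc, xc, sz, sy, sx = (float(v) for v in popt)
    resid = vals - _gauss3d(coords, *popt)
    vol_vox = GaussianSpotFit.ellipsoid_volume(sz, sy, sx)
    vol_um = None
    if voxel_size is not None:
        vz, vy, vx = voxel_size
        vol_um = vol_vox * vz * vy * vx
    return GaussianSpotFit(
        A=A, B=B, centre=(zc, yc, xc), sigma=(sz, sy, sx),
        volume_vox3=vol_vox, volume_um3=vol_um,
        rss=float(np.sum(resid**2)), converged=converged, n_voxels=n_vox,
    )


def relative_volume(
    treated: Sequence[float], control: Sequence[float]
) -> RelativeVolumeResult:
    """Per-cell volumes relative to the control median, with a rank-sum test.

    Each treated volume is divided by the median control volume; the two
    cohorts are compared with a standard two-sided Wilcoxon rank-sum test.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both volume sets must be non-empty")
    med = float(np.median(c))
    if med == 0:
        raise ValueError("control median volume is zero")
    res = stats.ranksums(t, c)
    ratios = t / med
    return RelativeVolumeResult(
        ratios=ratios,
        median_ratio=float(np.median(ratios)),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )


def integrated_fish_signal(
    stack: np.ndarray,
    spots: SpotSegmentation,
    nucleus_mask3d: np.ndarray,
    central_z: int,
) -> FishQuant:
    """Background-corrected sum of voxel values in the segmented spots.

    Background is the median intensity of pixels outside the spots and
    inside the nucleus at the central z slice; the corrected sum is
    raw sum − (spot voxel count × background median).
    """
    img = np.asarray(stack, dtype=float)
    spot_mask = spots.labels > 0
    nucleus = np.asarray(nucleus_mask3d, dtype=bool)
    bg_pixels = img[central_z][nucleus[central_z] & ~spot_mask[central_z]]
    if bg_pixels.size == 0:
        raise ValueError("no in-nucleus background pixels at the central slice")
    med = float(np.median(bg_pixels))
    n = int(np.count_nonzero(spot_mask))
    raw = float(img[spot_mask].sum()) if n else 0.0
    return FishQuant(corrected_sum=raw - n * med, background_median=med,
                     spot_voxels=n)


def nucleolar_nuclear_area(
    nucleolus_mask3d: np.ndarray,
    nucleus_mask2d: np.ndarray,
    voxel_xy: float,
) -> Tuple[float, float, float]:
    """(nucleolus area, nucleus area, ratio) in µm² from mask projections.

    The nucleolus 3D mask is max-projected along z; the nucleus area comes
    from its central-plane 2D mask.
    """
    proj = np.asarray(nucleolus_mask3d, dtype=bool).any(axis=0)
    nucleus = np.asarray(nucleus_mask2d, dtype=bool)
    if not proj.any() or not nucleus.any():
        raise ValueError("empty mask projection")
    px_area = voxel_xy * voxel_xy
    a_nucleolus = float(np.count_nonzero(proj)) * px_area
    a_nucleus = float(np.count_nonzero(nucleus)) * px_area
    return a_nucleolus, a_nucleus, a_nucleolus / a_nucleus
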