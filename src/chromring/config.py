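"""Configuration objects for scene simulation and analysis.

All physical lengths are in micrometres (µm) unless a name says otherwise.
Voxel coordinates follow the (z, y, x) axis order, 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import yaml

#: Default z spacing of the simulated stacks (µm); 200 nm between planes.
DEFAULT_VOXEL_Z = 0.2

#: Muscle nuclei are roughly a quarter of the *volume* of intestinal nuclei,
#: so the default radius scale is 0.25 ** (1/3).
TISSUE_SIZE_SCALES = {
    "intestine": 1.0,
    "hypoderm": 0.8,
    "muscle": 0.25 ** (1.0 / 3.0),
}

VALID_TISSUES = tuple(TISSUE_SIZE_SCALES)
VALID_MODES = ("fed", "fasted", "custom")


class InvalidParameterError(ValueError):
    """A configuration or model parameter violates its constraints."""


class ConfigurationError(ValueError):
    """A scene configuration is internally inconsistent (e.g. geometry)."""


@dataclass(frozen=True)
class RingParams:
    """Parameters of the radial chromatin density model.

    The density at normalized radius ``r`` (0 = nucleolus centre, 1 = nuclear
    surface) is ``B + A_i exp(-(r-x_i)^2 / 2 s_i^2) + A_o exp(-(r-x_o)^2 / 2 s_o^2)``:
    a background plus an inner (perinucleolar) and an outer (peripheral)
    Gaussian ring. Positions and widths are in normalized-radius units.
    """

    A_i: float = 1.0
    x_i: float = 0.55
    sigma_i: float = 0.15
    A_o: float = 0.0
    x_o: float = 0.90
    sigma_o: float = 0.06
    B: float = 0.1

    def validate(self) -> None:
        if self.A_i < 0 or self.A_o < 0 or self.B < 0:
            raise InvalidParameterError("ring amplitudes and background must be >= 0")
        if self.sigma_i <= 0 or self.sigma_o <= 0:
            raise InvalidParameterError("ring widths (sigma) must be > 0")
        if self.A_i > 0 and self.A_o > 0 and not self.x_i < self.x_o:
            raise InvalidParameterError(
                "inner ring centre x_i must lie inside outer ring centre x_o"
            )


#: Single mid-radius chromatin peak, as seen in well-fed intestinal nuclei.
FED_RING_PARAMS = RingParams(A_i=1.0, x_i=0.55, sigma_i=0.15, A_o=0.0, B=0.1)

#: Two concentric rings: perinucleolar and peripheral chromatin enrichment.
FASTED_RING_PARAMS = RingParams(
    A_i=1.0, x_i=0.25, sigma_i=0.10, A_o=0.6, x_o=0.90, sigma_o=0.06, B=0.1
)


@dataclass(frozen=True)
class SceneConfig:
    """Everything needed to render one synthetic single-nucleus scene.

    Parameters
    ----------
    nucleus_radius
        Reference (intestinal) nuclear radius in µm. The rendered radius is
        ``nucleus_radius * tissue_size_scale``.
    tissue, tissue_size_scale
        Tissue label and the radius scale applied for it. ``tissue_size_scale``
        of ``None`` looks the factor up in :data:`TISSUE_SIZE_SCALES`.
    nucleolus_sigmas
        (σ_z, σ_y, σ_x) of the nucleolar 3D Gaussian, in µm, z first to
        match the (z, y, x) axis order of the stacks.
    chromatin_mode, ring_params
        ``"fed"``/``"fasted"`` select the corresponding preset; ``"custom"``
        uses ``ring_params`` as given.
    psf_sigma_xy, psf_sigma_z
        Gaussian point-spread-function widths (µm).
    photon_scale
        Photons per intensity unit for the Poisson noise model; ``inf``
        disables shot noise.
    read_noise_sd
        Standard deviation of the additive Gaussian read noise (intensity units).
    voxel_xy, voxel_z
        Physical voxel pitches (µm); z defaults to 0.2 µm (200 nm planes).
    """

    nucleus_radius: float = 4.0
    tissue: str = "intestine"
    tissue_size_scale: Optional[float] = None
    nucleolus_sigmas: Tuple[float, float, float] = (0.8, 0.8, 0.8)
    nucleolus_amplitude: float = 1.0
    chromatin_mode: str = "fed"
    ring_params: Optional[RingParams] = None
    psf_sigma_xy: float = 0.08
    psf_sigma_z: float = 0.25
    photon_scale: float = 200.0
    read_noise_sd: float = 0.02
    voxel_xy: float = 0.1
    voxel_z: float = DEFAULT_VOXEL_Z
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise InvalidParameterError(f"unknown tissue {self.tissue!r}")
        if self.chromatin_mode not in VALID_MODES:
            raise InvalidParameterError(f"unknown chromatin_mode {self.chromatin_mode!r}")
        for name in ("nucleus_radius", "psf_sigma_xy", "psf_sigma_z",
                     "voxel_xy", "voxel_z"):
            if getattr(self, name) < 0 or (name.startswith("voxel") and getattr(self, name) <= 0):
                raise InvalidParameterError(f"{name} must be positive")
        if self.nucleus_radius <= 0:
            raise InvalidParameterError("nucleus_radius must be > 0")
        if any(s <= 0 for s in self.nucleolus_sigmas):
            raise InvalidParameterError("nucleolus sigmas must be > 0")
        scale = self.size_scale
        if not 0.0 < scale <= 1.0:
            raise InvalidParameterError("tissue_size_scale must lie in (0, 1]")
        if self.read_noise_sd < 0 or self.photon_scale <= 0:
            raise InvalidParameterError("noise parameters out of range")
        if self.chromatin_mode == "custom" and self.ring_params is None:
            raise InvalidParameterError("custom chromatin_mode requires ring_params")
        self.rings.validate()

    @property
    def size_scale(self) -> float:
        if self.tissue_size_scale is not None:
            return self.tissue_size_scale
        return TISSUE_SIZE_SCALES[self.tissue]

    @property
    def effective_radius(self) -> float:
        """Rendered nuclear radius in µm after the tissue scale."""
        return self.nucleus_radius * self.size_scale

    @property
    def rings(self) -> RingParams:
        if self.chromatin_mode == "fed":
            return self.ring_params or FED_RING_PARAMS
        if self.chromatin_mode == "fasted":
            return self.ring_params or FASTED_RING_PARAMS
        assert self.ring_params is not None
        return self.ring_params

    def with_(self, **kwargs) -> "SceneConfig":
        return replace(self, **kwargs)


def preset_config(mode: str = "fed", tissue: str = "intestine", **overrides) -> SceneConfig:
    """A ready-to-render config for a chromatin mode and tissue.

    The nucleolar sigmas are scaled with the tissue size so that the
    nucleolus keeps the same relative footprint in smaller nuclei.
    """
    scale = TISSUE_SIZE_SCALES[tissue]
    base = SceneConfig(chromatin_mode=mode, tissue=tissue)
    overrides.setdefault(
        "nucleolus_sigmas", tuple(s * scale for s in base.nucleolus_sigmas)
    )
    return base.with_(**overrides)


# --- analysis-side configuration -------------------------------------------

#: Centres (%) of the 20 five-percent-wide radial bins: 2.5, 7.5, ..., 97.5.
BIN_CENTRES = tuple(2.5 + 5.0 * i for i in range(20))

#: Regions (% of centre-to-contour distance) over which adjusted per-bin
#: p-values are combined. The 32.5% and 67.5% bins fall in the gaps and are
#: deliberately not covered.
DEFAULT_REGIONS = {
    "0-30": (0.0, 30.0),
    "35-65": (35.0, 65.0),
    "70-100": (70.0, 100.0),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the profiling/statistics pipeline."""

    bin_width_pct: float = 5.0
    ray_step: float = 0.5              # sampling step along rays, voxels
    min_ray_length: Optional[float] = None  # voxels, nucleolar edge to contour
    n_perm: int = 10_000
    alpha: float = 0.05
    bonferroni_m: int = 20
    combine_method: str = "fisher"     # or "pearson"
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    amp_fraction: float = 0.25         # organization-call amplitude threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(100.0 % self.bin_width_pct, 0.0, abs_tol=1e-9):
            raise InvalidParameterError("bin width must divide 100%")
        lo_hi = sorted(self.regions.values())
        for (a0, a1), (b0, b1) in zip(lo_hi, lo_hi[1:]):
            if b0 < a1:
                raise InvalidParameterError("regions must be disjoint")
        if self.n_perm < 99:
            raise InvalidParameterError("n_perm must be >= 99")

    @property
    def n_bins(self) -> int:
        return int(round(100.0 / self.bin_width_pct))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "regions" in data:
            data["regions"] = {k: tuple(v) for k, v in data["regions"].items()}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "bin_width_pct": self.bin_width_pct,
            "ray_step": self.ray_step,
            "min_ray_length": self.min_ray_length,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "bonferroni_m": self.bonferroni_m,
            "combine_method": self.combine_method,
            "regions": {k: list(v) for k, v in self.regions.items()},
            "amp_fraction": self.amp_fraction,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)
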