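"""Synthetic groups of smooth random-field image series with known ground truth.

The generator emulates the structure of a planar-array EIT study of evoked
cortical activity: per recording, a series of time-binned 3D conductivity-change
volumes whose noise is a stationary smooth Gaussian random field, with an
optional additive ellipsoidal activation whose amplitude follows a unimodal
time course (zero at the stimulation bin) and may decay exponentially with
cortical depth, mimicking the point-spread/sensitivity fall-off of a planar
electrode array.

Field synthesis convolves unit-variance white noise with a separable Gaussian
kernel of the requested FWHM and divides by the kernel's L2 norm, so the
marginal voxel variance stays exactly at the requested value while the field
smoothness equals the kernel FWHM. Convolution is periodic (wrap), which keeps
the marginal variance stationary up to the volume boundary.

Random streams are keyed hierarchically by ``(seed, recording_index,
bin_index)`` so every recording and bin is reproducible independently of
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid
from .series import RecordingSeries

__all__ = [
    "SyntheticConfig",
    "default_time_course",
    "generate_null_recording",
    "generate_active_recording",
    "generate_group",
    "activation_indicator",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian = sigma * 2 sqrt(2 ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    return float(fwhm) / _FWHM_PER_SIGMA


def default_time_course(n_bins: int, peak_bin: int, width_bins: float) -> np.ndarray:
    """Unimodal per-bin amplitude multipliers in [0, 1].

    A Gaussian bump centred on ``peak_bin`` of the given width (in bins),
    shifted and rescaled so the value at bin 0 (the stimulation time, at which
    no response is expected) is exactly 0 and the peak is exactly 1; values
    past the point where the bump falls below its bin-0 level are clipped to 0.

    Parameters
    ----------
    n_bins : int
        Number of time bins.
    peak_bin : int
        Index of the peak, 1 <= peak_bin < n_bins.
    width_bins : float
        Gaussian width (sigma) of the bump, in bins. Must be positive.
    """
    if width_bins <= 0:
        raise ValueError(f"width_bins must be positive, got {width_bins}")
    if not 0 <= peak_bin < n_bins:
        raise ValueError(f"peak_bin must lie in [0, {n_bins}), got {peak_bin}")
    if peak_bin == 0:
        raise ValueError(
            "peak_bin 0 conflicts with the zero-amplitude stimulation bin; use peak_bin >= 1"
        )
    k = np.arange(n_bins, dtype=float)
    bump = np.exp(-0.5 * ((k - peak_bin) / width_bins) ** 2)
    base = bump[0]
    tc = (bump - base) / (1.0 - base)
    return np.clip(tc, 0.0, 1.0)


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for one synthetic group of recordings.

    Defaults reproduce the study conditions at a reduced grid: 22 recordings,
    21 bins spanning 0-40 ms every 2 ms, 150 µm field FWHM on a 25 µm lattice,
    unit noise SD and an ellipsoidal activation peaking at 14 ms.
    ``effect_size`` is the peak mean shift in units of the noise SD.
    """

    n_recordings: int = 22
    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid((48, 48, 24)))
    noise_fwhm_um: float = 150.0
    noise_sd: float = 1.0
    activation_center_um: tuple[float, float, float] | None = None
    activation_radii_um: tuple[float, float, float] = (300.0, 300.0, 150.0)
    effect_size: float = 5.0
    n_time_bins: int = 21
    bin_spacing_ms: float = 2.0
    time_course: Sequence[float] | None = None
    depth_attenuation_scale_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recordings < 2:
            raise ValueError("n_recordings must be >= 2")
        if any(r <= 0 for r in self.activation_radii_um):
            raise ValueError("all activation radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_time_bins < 1:
            raise ValueError("n_time_bins must be >= 1")
        if self.bin_spacing_ms <= 0:
            raise ValueError("bin_spacing_ms must be positive")
        min_fwhm = 2.0 * max(self.grid.spacing_um)
        if self.noise_fwhm_um < min_fwhm:
            raise ValueError(
                f"noise_fwhm_um={self.noise_fwhm_um} violates the smooth-field requirement of "
                f"at least twice the voxel spacing ({min_fwhm} µm); random-field inference "
                "assumes the lattice approximates a continuous smooth field"
            )
        if self.activation_center_um is None:
            coords = self.grid.coordinate_arrays()
            self.activation_center_um = tuple(float(0.5 * (c[0] + c[-1])) for c in coords)
        if self.time_course is None:
            if self.n_time_bins == 1:
                self.time_course = np.ones(1)
            else:
                peak = min(7, self.n_time_bins - 1)
                self.time_course = default_time_course(self.n_time_bins, peak, 3.0)
        self.time_course = np.asarray(self.time_course, dtype=float)
        if self.time_course.shape != (self.n_time_bins,):
            raise ValueError("time_course length must equal n_time_bins")
        if np.any(self.time_course < 0) or np.any(self.time_course > 1):
            raise ValueError("time_course values must lie in [0, 1]")
        if self.depth_attenuation_scale_um is not None and self.depth_attenuation_scale_um <= 0:
            raise ValueError("depth_attenuation_scale_um must be positive or None")

    @property
    def bin_times_ms(self) -> np.ndarray:
        return np.arange(self.n_time_bins) * self.bin_spacing_ms

    @property
    def fwhm_voxels(self) -> tuple[float, float, float]:
        return tuple(self.noise_fwhm_um / s for s in self.grid.spacing_um)

    def to_dict(self) -> dict:
        """JSON-serialisable view of the configuration (for sidecars and logs)."""
        return {
            "n_recordings": self.n_recordings,
            "grid": {
                "dims": list(self.grid.dims),
                "spacing_um": list(self.grid.spacing_um),
                "origin_um": list(self.grid.origin_um),
            },
            "noise_fwhm_um": self.noise_fwhm_um,
            "noise_sd": self.noise_sd,
            "activation_center_um": list(self.activation_center_um),
            "activation_radii_um": list(self.activation_radii_um),
            "effect_size": self.effect_size,
            "n_time_bins": self.n_time_bins,
            "bin_spacing_ms": self.bin_spacing_ms,
            "time_course": self.time_course.tolist(),
            "depth_attenuation_scale_um": self.depth_attenuation_scale_um,
            "seed": self.seed,
        }


def _gaussian_kernel_l2(sigma_vox: float, truncate: float = 4.0) -> float:
    """L2 norm of the normalised discrete Gaussian kernel scipy applies."""
    if sigma_vox <= 0:
        return 1.0
    radius = int(truncate * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma_vox) ** 2)
    w /= w.sum()
    return float(np.sqrt(np.sum(w * w)))


def smooth_unit_field(rng: np.random.Generator, grid: VoxelGrid, fwhm_um: float) -> np.ndarray:
    """One unit-marginal-variance smooth Gaussian field on the grid."""
    white = rng.standard_normal(grid.dims)
    sigmas = [fwhm_to_sigma(fwhm_um / s) for s in grid.spacing_um]
    fld = ndimage.gaussian_filter(white, sigma=sigmas, mode="wrap", truncate=4.0)
    norm = np.prod([_gaussian_kernel_l2(s) for s in sigmas])
    return fld / norm


def _bin_rng(config: SyntheticConfig, recording_index: int, bin_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.seed), int(recording_index), int(bin_index)))
    )


def generate_null_recording(config: SyntheticConfig, recording_index: int) -> RecordingSeries:
    """One recording of pure smooth noise (no activation).

    Each bin is an independent smooth Gaussian field with marginal SD
    ``config.noise_sd`` and smoothness ``config.noise_fwhm_um``, emulating a
    post-mortem control recording.
    """
    bins = np.empty((config.n_time_bins,) + config.grid.dims)
    for k in range(config.n_time_bins):
        rng = _bin_rng(config, recording_index, k)
        bins[k] = config.noise_sd * smooth_unit_field(rng, config.grid, config.noise_fwhm_um)
    return RecordingSeries(config.grid, bins, config.bin_times_ms)


def depth_um(grid: VoxelGrid) -> np.ndarray:
    """Depth below the array-facing surface for every voxel.

    The planar array sits above the +z face of the volume (the rotation step
    of the geometric preprocessing puts the cortical surface normal along +z),
    so depth = max(z) - z, increasing away from the surface.
    """
    z = grid.coordinate_arrays()[2]
    d = z.max() - z
    return np.broadcast_to(d[None, None, :], grid.dims)


def activation_indicator(config: SyntheticConfig) -> np.ndarray:
    """Boolean ground-truth mask: voxels inside the activation ellipsoid."""
    cx, cy, cz = config.activation_center_um
    rx, ry, rz = config.activation_radii_um
    x, y, z = config.grid.coordinate_arrays()
    q = (
        ((x[:, None, None] - cx) / rx) ** 2
        + ((y[None, :, None] - cy) / ry) ** 2
        + ((z[None, None, :] - cz) / rz) ** 2
    )
    return q <= 1.0


def activation_field(config: SyntheticConfig) -> np.ndarray:
    """Peak-amplitude mean-shift field: effect * sd * indicator * depth taper."""
    ind = activation_indicator(config)
    if not ind.any():
        raise ValueError(
            "activation ellipsoid lies entirely outside the voxel grid; "
            "check activation_center_um and activation_radii_um against the grid extent"
        )
    fld = (config.effect_size * config.noise_sd) * ind.astype(float)
    if config.depth_attenuation_scale_um is not None:
        fld = fld * np.exp(-depth_um(config.grid) / config.depth_attenuation_scale_um)
    return fld


def generate_active_recording(config: SyntheticConfig, recording_index: int) -> RecordingSeries:
    """Null recording plus the time-modulated activation mean field.

    Bin ``k`` receives an additive shift ``effect_size * noise_sd *
    time_course[k]`` inside the activation ellipsoid (tapered with depth when
    ``depth_attenuation_scale_um`` is set). With ``effect_size=0`` the output
    is bit-identical to :func:`generate_null_recording` at the same seed.
    """
    series = generate_null_recording(config, recording_index)
    if config.effect_size == 0 or not np.any(config.time_course):
        # still validate the geometry so misconfiguration is caught early
        if config.effect_size != 0:
            activation_field(config)
        return series
    fld = activation_field(config)
    series.bins += config.time_course[:, None, None, None] * fld[None]
    return series


def generate_group(config: SyntheticConfig, active: bool = True) -> list[RecordingSeries]:
    """All ``n_recordings`` recordings of a group, active or null."""
    gen = generate_active_recording if active else generate_null_recording
    return [gen(config, r) for r in range(config.n_recordings)]
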