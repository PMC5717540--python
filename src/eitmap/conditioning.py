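"""Zero-phase Gaussian smoothing and proportional peak scaling.

Smoothing uses a separable symmetric Gaussian FIR kernel per axis (a symmetric
convolution is inherently zero-phase: filtering forwards and backwards with a
symmetric kernel introduces no shift). Proportional scaling normalises each
recording's whole image series by the mean of the above-half-maximum positive
values at the recording's peak time bin, compensating for per-recording
amplitude differences introduced upstream (e.g. by regularised reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid
from .series import RecordingSeries
from .synthetic import fwhm_to_sigma

__all__ = ["SmoothingSpec", "gaussian_smooth", "smooth_series", "proportional_scale"]

_BOUNDARY_MODES = {"reflect": "reflect", "nearest": "nearest", "zero": "constant"}


@dataclass(frozen=True)
class SmoothingSpec:
    """Per-axis Gaussian smoothing parameters.

    fwhm_um may be a scalar (isotropic) or a 3-tuple; each FWHM must be at
    least twice the corresponding voxel spacing, the lattice-approximation
    requirement for random-field inference on the smoothed images.
    """

    fwhm_um: tuple[float, float, float] = (150.0, 150.0, 150.0)
    boundary_mode: str = "reflect"
    truncation_sigmas: float = 4.0

    def __post_init__(self) -> None:
        fw = self.fwhm_um
        if np.isscalar(fw):
            fw = (float(fw),) * 3
        object.__setattr__(self, "fwhm_um", tuple(float(f) for f in fw))
        if len(self.fwhm_um) != 3 or any(f <= 0 for f in self.fwhm_um):
            raise ValueError("fwhm_um must be 3 positive lengths")
        if self.boundary_mode not in _BOUNDARY_MODES:
            raise ValueError(f"boundary_mode must be one of {sorted(_BOUNDARY_MODES)}")
        if self.truncation_sigmas <= 0:
            raise ValueError("truncation_sigmas must be positive")

    def validate_against(self, grid: VoxelGrid) -> None:
        for axis, (f, s) in enumerate(zip(self.fwhm_um, grid.spacing_um)):
            if f < 2.0 * s:
                raise ValueError(
                    f"smoothing FWHM {f} µm on axis {axis} is below twice the voxel "
                    f"spacing ({2 * s} µm); the kernel must be at least twice the voxel size"
                )


def gaussian_smooth(volume: np.ndarray, grid: VoxelGrid, spec: SmoothingSpec) -> np.ndarray:
    """Separable zero-phase Gaussian smoothing of one volume."""
    vol = grid.check_volume(np.asarray(volume, dtype=float))
    spec.validate_against(grid)
    sigmas = [fwhm_to_sigma(f / s) for f, s in zip(spec.fwhm_um, grid.spacing_um)]
    return ndimage.gaussian_filter(
        vol,
        sigma=sigmas,
        mode=_BOUNDARY_MODES[spec.boundary_mode],
        truncate=spec.truncation_sigmas,
    )


def smooth_series(series: RecordingSeries, spec: SmoothingSpec) -> RecordingSeries:
    """Smooth every time bin of a recording with the same kernel."""
    bins = np.stack([gaussian_smooth(b, series.grid, spec) for b in series.bins])
    return RecordingSeries(series.grid, bins, series.bin_times_ms.copy())


def proportional_scale(series: RecordingSeries) -> tuple[RecordingSeries, float, int]:
    """Scale a recording's whole image series by its peak-bin above-half-max mean.

    The peak bin is the bin holding the series' global maximum voxel value.
    The scale factor is 1/m where m is the mean of the positive voxel values
    strictly greater than half that global maximum at the peak bin, so after
    scaling the above-half-maximum mean at the peak bin equals 1. One factor
    is applied uniformly to every bin.

    Returns
    -------
    (scaled_series, factor, peak_bin)
    """
    peak_per_bin = series.bins.reshape(series.n_bins, -1).max(axis=1)
    peak_bin = int(np.argmax(peak_per_bin))
    global_max = float(peak_per_bin[peak_bin])
    if global_max <= 0:
        raise ValueError("proportional scaling undefined: no strictly positive voxel in any bin")
    vals = series.bins[peak_bin]
    above = vals[(vals > 0) & (vals > global_max / 2.0)]
    m = float(above.mean())
    factor = 1.0 / m
    scaled = RecordingSeries(series.grid, series.bins * factor, series.bin_times_ms.copy())
    return scaled, factor, peak_bin
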