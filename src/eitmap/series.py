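"""Time-binned image series: one recording's ordered set of 3D volumes.

The study design this package targets reconstructs one conductivity-change
volume per time bin (21 bins spanning 0-40 ms at 2 ms spacing) per recording;
each bin is analysed as an independent statistical map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid

__all__ = ["RecordingSeries"]


@dataclass
class RecordingSeries:
    """Ordered time-binned scalar volumes for one recording.

    Attributes
    ----------
    grid : VoxelGrid
        Shared lattice of all bins.
    bins : ndarray, shape (n_bins, *grid.dims)
        One scalar volume per time bin.
    bin_times_ms : ndarray, shape (n_bins,)
        Strictly increasing time stamps in milliseconds.
    """

    grid: VoxelGrid
    bins: np.ndarray
    bin_times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        self.bin_times_ms = np.asarray(self.bin_times_ms, dtype=float)
        if self.bins.ndim != 4:
            raise ValueError("bins must be a 4D array (n_bins, nx, ny, nz)")
        if self.bins.shape[1:] != self.grid.dims:
            raise ValueError(
                f"bin volumes of shape {self.bins.shape[1:]} do not match grid dims {self.grid.dims}"
            )
        if self.bin_times_ms.shape != (self.bins.shape[0],):
            raise ValueError("bin_times_ms length must equal the number of bins")
        if self.n_bins > 1 and not np.all(np.diff(self.bin_times_ms) > 0):
            raise ValueError("bin_times_ms must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.bins.shape[0]

    def copy(self) -> "RecordingSeries":
        return RecordingSeries(self.grid, self.bins.copy(), self.bin_times_ms.copy())
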