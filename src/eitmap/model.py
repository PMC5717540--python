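"""Second-level mass-univariate one-sample t model.

The model is the simplest second-level design: at each voxel the observed
conductivity changes across recordings are modelled as a common mean plus
i.i.d. error, and the null hypothesis is that the mean is zero (one-sided, in
favour of positive changes). Fitting yields a voxelwise t-map with n - 1
degrees of freedom, the implicit analysis mask, and standardised residual
fields used for random-field smoothness estimation.

The surface follows the model/results idiom::

    model = OneSampleTMap(volumes, grid)
    res = model.fit()
    fwe = res.rft(alpha=0.01)       # or res.bonferroni(...), res.permutation(...)
    print(res.summary(alpha=0.01, seed=0))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fwe as _fwe
from .grid import VoxelGrid

__all__ = ["GroupSample", "TStatMap", "implicit_mask", "one_sample_t", "OneSampleTMap", "OneSampleTMapResults"]


def implicit_mask(volumes: np.ndarray) -> np.ndarray:
    """Analysis mask: voxels finite and nonzero in every input volume.

    Exact zeros are treated as missing data (the implicit-masking convention
    for images whose background is zero).
    """
    x = np.asarray(volumes)
    if x.ndim != 4 or x.shape[0] < 1:
        raise ValueError("volumes must be (n_recordings, nx, ny, nz) with n >= 1")
    return np.all(np.isfinite(x) & (x != 0), axis=0)


@dataclass
class GroupSample:
    """One time bin's group data: one volume per recording plus the mask."""

    grid: VoxelGrid
    volumes: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4 or self.volumes.shape[0] < 2:
            raise ValueError("volumes must be (n_recordings >= 2, nx, ny, nz)")
        if self.volumes.shape[1:] != self.grid.dims:
            raise ValueError("volume shape does not match grid dims")
        auto = implicit_mask(self.volumes)
        if self.mask is None:
            self.mask = auto
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & auto

    @property
    def n_recordings(self) -> int:
        return self.volumes.shape[0]


@dataclass
class TStatMap:
    """Voxelwise t-statistics with df, mask and standardised residuals.

    Residuals are stored standardised to unit sum of squares per voxel
    (r_i / sqrt(sum_j r_j^2)); they sum to zero at every masked voxel and feed
    the random-field smoothness estimator directly.
    """

    t: np.ndarray
    df: int
    mask: np.ndarray
    residuals: np.ndarray


def one_sample_t(sample: GroupSample) -> TStatMap:
    """Voxelwise one-sample t = mean / (sd / sqrt(n)) on the masked volumes.

    Voxels whose sample variance is exactly zero cannot support a t value and
    are removed from the mask.
    """
    x = sample.volumes
    n = sample.n_recordings
    mask = sample.mask.copy()
    if not mask.any():
        raise ValueError("analysis mask is empty")

    mean = x.mean(axis=0)
    resid = x - mean[None]
    ssq = (resid**2).sum(axis=0)
    mask &= ssq > 0
    if not mask.any():
        raise ValueError("analysis mask is empty after removing zero-variance voxels")

    sd = np.sqrt(ssq / (n - 1))
    t = np.zeros(x.shape[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = mean / (sd / np.sqrt(n))
    t[mask] = t_all[mask]

    std_resid = np.zeros_like(resid)
    std_resid[:, mask] = resid[:, mask] / np.sqrt(ssq[mask])[None]
    return TStatMap(t=t, df=n - 1, mask=mask, residuals=std_resid)


class OneSampleTMap:
    """Model object for the voxelwise one-sample t-test of a group of volumes.

    Parameters
    ----------
    volumes : ndarray, shape (n_recordings, nx, ny, nz)
        One preprocessed volume per recording (a single time bin).
    grid : VoxelGrid, optional
        Lattice geometry; defaults to 25 µm isotropic spacing.
    mask : boolean ndarray, optional
        Extra analysis mask, intersected with the implicit mask.
    """

    def __init__(
        self,
        volumes: np.ndarray,
        grid: VoxelGrid | None = None,
        mask: np.ndarray | None = None,
    ) -> None:
        volumes = np.asarray(volumes, dtype=float)
        if grid is None:
            grid = VoxelGrid(volumes.shape[1:])
        self.sample = GroupSample(grid, volumes, mask)
        self.grid = grid

    @classmethod
    def from_series_group(cls, series_list, bin_index: int, mask=None) -> "OneSampleTMap":
        """Build the model for one time bin from a group of recording series."""
        grids = {s.grid for s in series_list}
        if len(grids) != 1:
            raise ValueError("recordings do not share a common grid")
        volumes = np.stack([s.bins[bin_index] for s in series_list])
        return cls(volumes, series_list[0].grid, mask)

    def fit(self) -> "OneSampleTMapResults":
        return OneSampleTMapResults(self, one_sample_t(self.sample))


class OneSampleTMapResults:
    """Fitted one-sample t-map with FWE-corrected thresholding methods."""

    def __init__(self, model: OneSampleTMap, tmap: TStatMap) -> None:
        self.model = model
        self.grid = model.grid
        self.tmap = tmap
        self._smoothness: _fwe.SmoothnessEstimate | None = None

    # -- plain accessors ----------------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self.tmap.t

    @property
    def df(self) -> int:
        return self.tmap.df

    @property
    def mask(self) -> np.ndarray:
        return self.tmap.mask

    @property
    def residuals(self) -> np.ndarray:
        return self.tmap.residuals

    @property
    def max_t(self) -> float:
        return float(self.t[self.mask].max())

    # -- inference ----------------------------------------------------------
    def smoothness(self) -> _fwe.SmoothnessEstimate:
        """Effective FWHM / resel counts of the residual fields (cached)."""
        if self._smoothness is None:
            self._smoothness = _fwe.estimate_smoothness(
                self.tmap.residuals, self.tmap.mask, self.grid
            )
        return self._smoothness

    def _result(self, method: str, alpha: float, threshold: float, **details) -> _fwe.FWEResult:
        sig = (self.t > threshold) & self.mask
        return _fwe.FWEResult(
            method=method,
            alpha_bin=alpha,
            t_threshold=threshold,
            sig_mask=sig,
            sig_volume_mm3=_fwe.significant_volume(sig, self.grid),
            details=details,
        )

    def bonferroni(self, alpha: float) -> _fwe.FWEResult:
        """Bonferroni FWE threshold over the masked voxels."""
        n = int(self.mask.sum())
        thr = _fwe.bonferroni_threshold(_fwe.bonferroni_alpha(alpha, n), self.df)
        return self._result("bonferroni", alpha, thr, n_tests=n)

    def rft(self, alpha: float) -> _fwe.FWEResult:
        """Random-field-theory FWE threshold (capped at Bonferroni)."""
        sm = self.smoothness()
        thr = _fwe.rft_threshold(sm, self.df, alpha)
        return self._result(
            "rft", alpha, thr, fwhm_voxels=sm.fwhm_voxels, resels=sm.resels
        )

    def permutation(
        self, alpha: float, n_perms: int = 1000, seed: int | None = None, rule: str = "ceil"
    ) -> _fwe.FWEResult:
        """Sign-flip max-statistic permutation FWE threshold."""
        _, result = _fwe.sign_flip_permutation(
            self.t, self.model.sample.volumes, self.mask, n_perms, alpha, seed, self.grid, rule
        )
        return result

    def permutation_null(self, n_perms: int = 1000, seed: int | None = None) -> _fwe.MaxStatNull:
        return _fwe.max_t_distribution(self.model.sample.volumes, self.mask, n_perms, seed)

    def threshold(self, method: str, alpha: float, **kwargs) -> _fwe.FWEResult:
        """Dispatch to one of the three FWE procedures by name."""
        dispatch = {
            "bonferroni": self.bonferroni,
            "rft": self.rft,
            "permutation": self.permutation,
            "perm": self.permutation,
        }
        if method not in dispatch:
            raise ValueError(f"unknown FWE method {method!r}")
        return dispatch[method](alpha, **kwargs)

    def summary(
        self,
        alpha: float = 0.05,
        methods: tuple[str, ...] = ("bonferroni", "rft", "permutation"),
        n_perms: int = 1000,
        seed: int | None = None,
    ) -> pd.DataFrame:
        """Comparison table of the FWE procedures at one level.

        Columns: method, alpha, t_threshold, n_sig_voxels, sig_volume_mm3,
        max_t, df, n_masked_voxels.
        """
        rows = []
        for m in methods:
            kw = {"n_perms": n_perms, "seed": seed} if m in ("permutation", "perm") else {}
            r = self.threshold(m, alpha, **kw)
            rows.append(
                {
                    "method": r.method,
                    "alpha": alpha,
                    "t_threshold": r.t_threshold,
                    "n_sig_voxels": r.n_sig_voxels,
                    "sig_volume_mm3": r.sig_volume_mm3,
                    "max_t": self.max_t,
                    "df": self.df,
                    "n_masked_voxels": int(self.mask.sum()),
                }
            )
        return pd.DataFrame(rows)
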