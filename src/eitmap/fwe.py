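"""Family-wise error control for voxelwise t-maps.

Three procedures are implemented and meant to be compared on the same t-map:

* **Bonferroni** — divide the family-wise level by the number of voxels and
  threshold at the corresponding one-sided Student-t quantile. Ignores spatial
  correlation, hence very conservative on smooth images.
* **Random field theory (RFT)** — treat the t-map as a lattice sampling of a
  smooth t-field and choose the threshold at which the expected Euler
  characteristic of the excursion set equals the family-wise level. The
  field's effective smoothness (FWHM per axis) is estimated from spatial
  derivatives of the normalised model residuals; the search region is counted
  in resels (volume in FWHM units). Euler-characteristic densities are the
  unified t-field expressions of Worsley et al. (1996).
* **Sign-flip max-statistic permutation** — under the null the group mean is
  zero and each recording's image is symmetric about zero, so multiplying
  recordings by independent ±1 relabels the data without changing its
  distribution. The null distribution of the image-wide maximum t across
  relabelings yields an exact FWE-corrected threshold; a random Monte Carlo
  subset of the 2^n relabelings is used when exhaustive enumeration is too
  costly.

A fourth, temporal, Bonferroni correction spreads a family-wise level over the
effectively independent time bins of a series.

One-sided inference on positive changes is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .grid import VoxelGrid

__all__ = [
    "SmoothnessEstimate",
    "MaxStatNull",
    "FWEResult",
    "temporal_correction",
    "bonferroni_alpha",
    "bonferroni_threshold",
    "estimate_smoothness",
    "box_resels",
    "ec_density_t",
    "expected_euler_characteristic",
    "rft_threshold",
    "sign_flip_permutation",
    "mc_error",
    "significant_volume",
]

_4LN2 = 4.0 * np.log(2.0)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SmoothnessEstimate:
    """Effective field smoothness and resel counts of the search region.

    fwhm_voxels is the per-axis effective FWHM in voxel units; resels are the
    0- to 3-dimensional resel counts (R0..R3) of the mask's bounding box with
    sides measured in FWHM units.
    """

    fwhm_voxels: tuple[float, float, float]
    resels: tuple[float, float, float, float]
    n_masked_voxels: int


@dataclass
class MaxStatNull:
    """Permutation null distribution of the image-wide maximum t."""

    max_values: np.ndarray  # sorted ascending; includes the identity relabeling
    n_perms: int
    exhaustive: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        self.max_values = np.sort(np.asarray(self.max_values, dtype=float))
        if len(self.max_values) != self.n_perms:
            raise ValueError("max_values length must equal n_perms")


@dataclass
class FWEResult:
    """Outcome of one FWE procedure at one time bin."""

    method: str
    alpha_bin: float
    t_threshold: float
    sig_mask: np.ndarray
    sig_volume_mm3: float
    corrected_p: np.ndarray | None = None
    details: dict = field(default_factory=dict)

    @property
    def n_sig_voxels(self) -> int:
        return int(self.sig_mask.sum())


# ---------------------------------------------------------------------------
# Bonferroni and temporal corrections


def bonferroni_alpha(p_fwe: float, n_tests: int) -> float:
    """Per-test level alpha = p_fwe / n for n independent tests."""
    if not 0.0 < p_fwe < 1.0:
        raise ValueError(f"p_fwe must lie in (0, 1), got {p_fwe}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return p_fwe / n_tests


def bonferroni_threshold(alpha_per_test: float, df: int) -> float:
    """One-sided upper Student-t quantile at the per-test level."""
    if not 0.0 < alpha_per_test < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha_per_test}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.t.isf(alpha_per_test, df))


def temporal_correction(
    alpha_fwe: float,
    n_bins: int,
    bin_spacing_ms: float,
    effective_resolution_ms: float,
) -> tuple[float, int]:
    """Bonferroni correction over the effectively independent time bins.

    Adjacent bins closer than the data's effective temporal resolution are not
    independent tests; the number of independent tests is the spanned window
    divided by that resolution: ``round((n_bins - 1) * spacing / resolution)``,
    floored at 1. E.g. 21 bins every 2 ms with 8 ms resolution give 5
    independent tests, so a 0.05 family level becomes 0.01 per bin.

    Returns
    -------
    (alpha_per_bin, n_independent)
    """
    if not 0.0 < alpha_fwe < 1.0:
        raise ValueError(f"alpha_fwe must lie in (0, 1), got {alpha_fwe}")
    if bin_spacing_ms <= 0 or effective_resolution_ms <= 0:
        raise ValueError("bin spacing and effective resolution must be positive")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n_independent = max(1, round((n_bins - 1) * bin_spacing_ms / effective_resolution_ms))
    return alpha_fwe / n_independent, n_independent


def mc_error(p: float, n_perms: int) -> float:
    """Monte Carlo half-width 2 sqrt(p (1 - p) / N') of a permutation p-value."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    return 2.0 * math.sqrt(p * (1.0 - p) / n_perms)


def significant_volume(sig_mask: np.ndarray, grid: VoxelGrid) -> float:
    """Volume of the significant voxels in mm³."""
    grid.check_volume(sig_mask)
    return float(np.count_nonzero(sig_mask)) * grid.voxel_volume_mm3


# ---------------------------------------------------------------------------
# random field theory


def estimate_smoothness(
    residuals: np.ndarray, mask: np.ndarray, grid: VoxelGrid | None = None
) -> SmoothnessEstimate:
    """Effective FWHM and resel counts from normalised residual derivatives.

    Parameters
    ----------
    residuals : ndarray, shape (n_recordings, nx, ny, nz)
        Standardised residual fields (unit sum of squares across recordings at
        each masked voxel), as produced by the one-sample t fit.
    mask : boolean ndarray
        Analysis mask.

    Notes
    -----
    Per axis, the derivative variance of the (unit-variance) error field is
    estimated as the average over masked voxel pairs of the sum across
    recordings of squared forward differences of the standardised residuals;
    the effective FWHM follows from the Gaussian autocorrelation model as
    ``FWHM = sqrt(4 ln 2 / lambda)`` (voxel units). Resels use the box
    approximation on the mask's bounding box: with sides ``s = extent / FWHM``
    per axis, R0 = 1, R1 = sum(s), R2 = sum of pairwise products,
    R3 = product.
    """
    res = np.asarray(residuals, dtype=float)
    if res.ndim != 4 or res.shape[0] < 2:
        raise ValueError("residuals must be (n_recordings >= 2, nx, ny, nz)")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")

    fwhm = []
    for axis in range(3):
        diffs = np.diff(res, axis=axis + 1)
        pair_ok = np.logical_and(
            np.take(mask, range(mask.shape[axis] - 1), axis=axis),
            np.take(mask, range(1, mask.shape[axis]), axis=axis),
        )
        if not pair_ok.any():
            raise ValueError(f"mask has no interior voxel pairs along axis {axis}")
        lam = float((diffs**2).sum(axis=0)[pair_ok].mean())
        if lam == 0.0:
            raise ValueError(
                f"residuals are flat along axis {axis}: infinite smoothness, FWHM undefined"
            )
        fwhm.append(math.sqrt(_4LN2 / lam))

    idx = np.nonzero(mask)
    extents = tuple(int(i.max() - i.min() + 1) for i in idx)
    return SmoothnessEstimate(tuple(fwhm), box_resels(extents, tuple(fwhm)), int(mask.sum()))


def box_resels(
    extents_voxels: tuple[float, float, float], fwhm_voxels: tuple[float, float, float]
) -> tuple[float, float, float, float]:
    """Resel counts R0..R3 of a box with the given sides, in FWHM units."""
    if any(f <= 0 for f in fwhm_voxels):
        raise ValueError("all FWHM must be positive")
    s = [e / f for e, f in zip(extents_voxels, fwhm_voxels)]
    return (
        1.0,
        s[0] + s[1] + s[2],
        s[0] * s[1] + s[0] * s[2] + s[1] * s[2],
        s[0] * s[1] * s[2],
    )


def ec_density_t(d: int, t: float, df: int) -> float:
    """Euler-characteristic density of a t-field in dimension d (0..3)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if d not in (0, 1, 2, 3):
        raise ValueError(f"dimension must be 0..3, got {d}")
    t = float(t)
    nu = float(df)
    shape = (1.0 + t * t / nu) ** (-(nu - 1.0) / 2.0)
    if d == 0:
        return float(stats.t.sf(t, df))
    if d == 1:
        return float(math.sqrt(_4LN2) / (2.0 * math.pi) * shape)
    if d == 2:
        lg = special.gammaln((nu + 1.0) / 2.0) - special.gammaln(nu / 2.0)
        c = math.exp(lg) / math.sqrt(nu / 2.0)
        return float(_4LN2 / (2.0 * math.pi) ** 1.5 * c * t * shape)
    return float(
        _4LN2**1.5 / (2.0 * math.pi) ** 2 * ((nu - 1.0) / nu * t * t - 1.0) * shape
    )


def expected_euler_characteristic(t: float, resels: tuple, df: int) -> float:
    """Expected EC of the excursion set above t: sum_d R_d rho_d(t)."""
    return float(sum(r * ec_density_t(d, t, df) for d, r in enumerate(resels)))


def rft_threshold(
    smoothness: SmoothnessEstimate,
    df: int,
    alpha: float,
    t_max: float = 50.0,
) -> float:
    """Voxel-level FWE threshold from the expected Euler characteristic.

    Solves ``E[EC](t*) = alpha`` on the upper, decreasing branch of the
    expected-EC curve, then caps the result at the Bonferroni threshold over
    the masked voxels (the parametric threshold never exceeds Bonferroni).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")

    def f(t: float) -> float:
        return expected_euler_characteristic(t, smoothness.resels, df) - alpha

    # E[EC] can be non-monotone (negative rho3 at low t); bracket from its peak.
    ts = np.linspace(0.0, t_max, 501)
    vals = np.array([f(t) for t in ts])
    lo = float(ts[int(np.argmax(vals))])
    if f(lo) < 0:
        raise ValueError("no RFT threshold in bracket; alpha unattainable for these resels")
    # low df gives polynomially heavy EC tails: extend the bracket as needed
    hi = t_max
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("no RFT threshold found; expected EC never drops to alpha")
    t_star = float(optimize.brentq(f, lo, hi, xtol=1e-6))
    t_bonf = bonferroni_threshold(
        bonferroni_alpha(alpha, smoothness.n_masked_voxels), df
    )
    return min(t_star, t_bonf)


# ---------------------------------------------------------------------------
# sign-flip permutation


def _signs_from_codes(codes: np.ndarray, n: int) -> np.ndarray:
    """Map integer relabeling codes in [0, 2^n) to ±1 sign matrices."""
    bits = (codes[:, None] >> np.arange(n)[None, :]) & 1
    return 1.0 - 2.0 * bits  # bit 0 -> +1, bit 1 -> -1


def _sample_sign_codes(n: int, n_perms: int, seed: int) -> tuple[np.ndarray, bool]:
    total = 2**n
    if total <= n_perms:
        return np.arange(total, dtype=np.int64), True
    rng = np.random.default_rng(seed)
    chosen: set[int] = set()
    while len(chosen) < n_perms - 1:
        need = n_perms - 1 - len(chosen)
        draws = rng.integers(1, total, size=2 * need)
        for d in draws:
            if len(chosen) >= n_perms - 1:
                break
            chosen.add(int(d))
    codes = np.concatenate([[0], np.fromiter(chosen, dtype=np.int64, count=len(chosen))])
    return codes, False


def max_t_distribution(
    volumes: np.ndarray,
    mask: np.ndarray,
    n_perms: int,
    seed: int | None = None,
    chunk: int = 128,
) -> MaxStatNull:
    """Null distribution of the masked maximum one-sample t under sign flips.

    All 2^n sign patterns are enumerated when 2^n <= n_perms (exhaustive);
    otherwise the identity pattern plus ``n_perms - 1`` distinct random
    patterns are used (Monte Carlo, sampling without replacement).

    The per-pattern t-map is computed in closed form: flipping signs leaves
    each voxel's sum of squares unchanged, so only the flipped mean is needed.
    """
    x = np.asarray(volumes, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 recordings")
    if n_perms < 2:
        raise ValueError("n_perms must be >= 2")
    data = x.reshape(n, -1)[:, np.asarray(mask, dtype=bool).ravel()]
    if data.shape[1] == 0:
        raise ValueError("mask is empty")
    if seed is None and 2**n > n_perms:
        raise ValueError("a seed is required for Monte Carlo permutation sampling")
    codes, exhaustive = _sample_sign_codes(n, n_perms, 0 if seed is None else int(seed))
    n_used = len(codes)

    sumsq = (data**2).sum(axis=0)  # invariant under sign flips
    maxima = np.empty(n_used)
    for start in range(0, n_used, chunk):
        signs = _signs_from_codes(codes[start : start + chunk], n)
        mean = (signs @ data) / n
        var = np.maximum(sumsq[None, :] - n * mean**2, 0.0) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        t[~np.isfinite(t)] = 0.0
        maxima[start : start + chunk] = t.max(axis=1)
    return MaxStatNull(maxima, n_used, exhaustive, seed)


def permutation_threshold(null: MaxStatNull, alpha: float, rule: str = "ceil") -> float:
    """FWE threshold from the sorted max-t null.

    ``rule='ceil'`` (default) takes the ``ceil((1 - alpha) * n_perms)``-th
    smallest max value; ``rule='ceil_plus_one'`` the next order statistic
    (the more conservative convention). Significance requires strictly
    exceeding the threshold, which resolves ties conservatively.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if alpha * null.n_perms < 1.0:
        raise ValueError(
            f"alpha={alpha} is unattainable with {null.n_perms} permutations "
            f"(alpha * n_perms must be >= 1)"
        )
    k = math.ceil((1.0 - alpha) * null.n_perms)
    if rule == "ceil_plus_one":
        k = min(k + 1, null.n_perms)
    elif rule != "ceil":
        raise ValueError(f"unknown threshold rule {rule!r}")
    return float(null.max_values[k - 1])


def sign_flip_permutation(
    t_map: np.ndarray,
    volumes: np.ndarray,
    mask: np.ndarray,
    n_perms: int,
    alpha: float,
    seed: int | None,
    grid: VoxelGrid,
    rule: str = "ceil",
) -> tuple[MaxStatNull, FWEResult]:
    """Max-statistic sign-flip permutation test of a one-sample t-map.

    Returns the max-t null and the FWE result: threshold, significance mask
    (t strictly above threshold within the analysis mask), significant volume,
    and the voxelwise FWE-corrected p-value
    ``p(v) = #{max values >= t(v)} / n_perms`` (NaN outside the mask).
    """
    null = max_t_distribution(volumes, mask, n_perms, seed)
    threshold = permutation_threshold(null, alpha, rule)
    mask = np.asarray(mask, dtype=bool)
    sig = (t_map > threshold) & mask
    corrected = np.full(t_map.shape, np.nan)
    # p = fraction of null maxima >= observed t; searchsorted on ascending nulls
    below = np.searchsorted(null.max_values, t_map[mask], side="left")
    corrected[mask] = (null.n_perms - below) / null.n_perms
    return null, FWEResult(
        method="permutation",
        alpha_bin=alpha,
        t_threshold=threshold,
        sig_mask=sig,
        sig_volume_mm3=significant_volume(sig, grid),
        corrected_p=corrected,
        details={"n_perms": null.n_perms, "exhaustive": null.exhaustive, "seed": seed},
    )
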