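"""NIfTI I/O, per-bin run orchestration and comparison tables.

Volumes are exchanged as one NIfTI-1 file per time bin named
``rec{r}_bin{k}.nii.gz`` with a µm-scaled diagonal affine, optionally
accompanied by a ``group.json`` sidecar holding the generating configuration
and ground truth. Analysis output is a :class:`RunReport`: one record per
(time bin, method) with the critical t-threshold, significant voxel count and
significant volume, plus provenance (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from . import fwe as _fwe
from .grid import VoxelGrid
from .model import GroupSample, OneSampleTMap
from .series import RecordingSeries

__all__ = [
    "RunReport",
    "write_series",
    "read_series",
    "analyze_group",
    "threshold_stability",
    "volume_curve",
    "pvalue_sweep",
    "config_hash",
]

_FNAME_RE = re.compile(r"^rec(\d+)_bin(\d+)\.nii(\.gz)?$")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# NIfTI series I/O


def _grid_from_img(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelGrid(img.shape[:3], spacing, origin)


def write_series(
    series_list: list[RecordingSeries],
    directory: str | Path,
    config: dict | None = None,
    truth_mask: np.ndarray | None = None,
) -> None:
    """Write each recording as one NIfTI file per bin, plus an optional sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r, series in enumerate(series_list):
        aff = series.grid.affine()
        for k in range(series.n_bins):
            img = nib.Nifti1Image(series.bins[k].astype(np.float64), aff)
            nib.save(img, directory / f"rec{r}_bin{k}.nii.gz")
    sidecar: dict = {"n_recordings": len(series_list)}
    if series_list:
        sidecar["bin_times_ms"] = series_list[0].bin_times_ms.tolist()
    if config is not None:
        sidecar["config"] = config
        sidecar["config_hash"] = config_hash(config)
    (directory / "group.json").write_text(json.dumps(sidecar, indent=2))
    if truth_mask is not None and series_list:
        img = nib.Nifti1Image(truth_mask.astype(np.uint8), series_list[0].grid.affine())
        nib.save(img, directory / "truth_mask.nii.gz")


def read_series(directory: str | Path) -> list[RecordingSeries]:
    """Read a directory of ``rec{r}_bin{k}`` NIfTI files into ordered series.

    All files must share dims and affine; any missing bin of a recording is an
    error naming the expected bins.
    """
    directory = Path(directory)
    found: dict[int, dict[int, Path]] = {}
    for path in sorted(directory.iterdir()):
        m = _FNAME_RE.match(path.name)
        if m:
            found.setdefault(int(m.group(1)), {})[int(m.group(2))] = path
    if not found:
        raise FileNotFoundError(f"no rec*_bin*.nii[.gz] files found in {directory}")

    bin_times = None
    sidecar_path = directory / "group.json"
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if "bin_times_ms" in sidecar:
            bin_times = np.asarray(sidecar["bin_times_ms"], dtype=float)

    n_bins = max(max(bins) for bins in found.values()) + 1
    expected = set(range(n_bins))
    grid: VoxelGrid | None = None
    series_list = []
    for r in sorted(found):
        missing = expected - set(found[r])
        if missing:
            raise FileNotFoundError(
                f"recording {r} is missing bins {sorted(missing)} (expected bins 0..{n_bins - 1})"
            )
        vols = []
        for k in range(n_bins):
            img = nib.load(found[r][k])
            g = _grid_from_img(img)
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError(
                    f"grid mismatch in {found[r][k].name}: {g.dims}@{g.spacing_um} µm "
                    f"vs {grid.dims}@{grid.spacing_um} µm"
                )
            vols.append(np.asarray(img.dataobj, dtype=float))
        times = bin_times if bin_times is not None else np.arange(n_bins, dtype=float)
        series_list.append(RecordingSeries(grid, np.stack(vols), times))
    return series_list


# ---------------------------------------------------------------------------
# run orchestration and comparison outputs


@dataclass
class RunReport:
    """Per-(bin, method) threshold/volume records with provenance."""

    records: pd.DataFrame
    alpha_fwe: float
    alpha_bin: float
    n_independent: int
    seed: int | None = None
    config_hash: str | None = None
    version: str = __version__

    def __post_init__(self) -> None:
        dup = self.records.duplicated(subset=["bin_time_ms", "method"])
        if dup.any():
            raise ValueError("duplicate (bin, method) records in report")
        if not np.all(np.isfinite(self.records["t_threshold"])):
            raise ValueError("non-finite threshold in report")

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha_fwe": self.alpha_fwe,
                "alpha_bin": self.alpha_bin,
                "n_independent": self.n_independent,
                "seed": self.seed,
                "config_hash": self.config_hash,
                "version": self.version,
                "records": self.records.to_dict(orient="records"),
            },
            indent=2,
        )


def analyze_group(
    series_list: list[RecordingSeries],
    alpha_fwe: float = 0.05,
    effective_resolution_ms: float = 8.0,
    methods: tuple[str, ...] = ("bonferroni", "rft", "permutation"),
    n_perms: int = 1000,
    seed: int | None = None,
    config: dict | None = None,
) -> RunReport:
    """Full per-bin group analysis: temporal correction then each FWE method.

    Each time bin is tested independently with a one-sample t-map at the
    temporally corrected level; permutation seeds are derived per bin from
    ``seed`` so the whole run is reproducible.
    """
    if not series_list:
        raise ValueError("empty group")
    n_bins = series_list[0].n_bins
    spacing = float(np.median(np.diff(series_list[0].bin_times_ms))) if n_bins > 1 else 1.0
    alpha_bin, n_indep = _fwe.temporal_correction(
        alpha_fwe, n_bins, spacing, effective_resolution_ms
    )
    rows = []
    for k in range(n_bins):
        res = OneSampleTMap.from_series_group(series_list, k).fit()
        for m in methods:
            kw = {}
            if m in ("permutation", "perm"):
                kw = {"n_perms": n_perms, "seed": None if seed is None else seed + k}
            r = res.threshold(m, alpha_bin, **kw)
            rows.append(
                {
                    "bin": k,
                    "bin_time_ms": float(series_list[0].bin_times_ms[k]),
                    "method": r.method,
                    "t_threshold": r.t_threshold,
                    "n_sig_voxels": r.n_sig_voxels,
                    "sig_volume_mm3": r.sig_volume_mm3,
                    "alpha_bin": alpha_bin,
                }
            )
    return RunReport(
        records=pd.DataFrame(rows),
        alpha_fwe=alpha_fwe,
        alpha_bin=alpha_bin,
        n_independent=n_indep,
        seed=seed,
        config_hash=config_hash(config) if config is not None else None,
    )


def threshold_stability(report: RunReport, method: str) -> tuple[float, float]:
    """Mean and unbiased SD of a method's critical t-threshold across bins."""
    thr = report.records.loc[report.records["method"] == method, "t_threshold"]
    if thr.empty:
        raise ValueError(f"no records for method {method!r}")
    if len(thr) < 2:
        raise ValueError("threshold stability needs at least 2 bins")
    return float(thr.mean()), float(thr.std(ddof=1))


def volume_curve(
    report: RunReport,
    csv_path: str | Path | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Significant volume (mm³) vs time bin per method; optional CSV and plot."""
    table = report.records.pivot(index="bin_time_ms", columns="method", values="sig_volume_mm3")
    if csv_path is not None:
        table.to_csv(csv_path)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for m in table.columns:
            ax.plot(table.index, table[m], marker="o", label=m)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("significant volume (mm³)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return table


def pvalue_sweep(
    sample: GroupSample,
    alphas: list[float],
    methods: tuple[str, ...] = ("rft", "permutation"),
    n_perms: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Significant-voxel counts for a grid of family-wise levels per method.

    The permutation max-t null is computed once and re-thresholded per level.
    Counts are monotone non-decreasing in alpha for every method.
    """
    alphas = sorted(float(a) for a in alphas)
    if any(not 0 < a < 1 for a in alphas):
        raise ValueError("all alphas must lie in (0, 1)")
    res = OneSampleTMap(sample.volumes, sample.grid, sample.mask).fit()
    null = None
    rows = []
    for m in methods:
        for a in alphas:
            if m in ("permutation", "perm"):
                if null is None:
                    null = res.permutation_null(n_perms=n_perms, seed=seed)
                thr = _fwe.permutation_threshold(null, a)
                count = int(((res.t > thr) & res.mask).sum())
            else:
                r = res.threshold(m, a)
                thr, count = r.t_threshold, r.n_sig_voxels
            rows.append({"method": m, "alpha": a, "t_threshold": thr, "n_sig_voxels": count})
    return pd.DataFrame(rows)
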