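"""Voxel-wise parameter maps, fixed-area ROI measurement, and signal ratios.

Fitters from :mod:`ivimr2.fitting` are applied independently to every masked
voxel of a 4-D volume (x, y, z, b-value or echo) to produce per-parameter
maps with per-voxel diagnostics.  ROIs are fixed-area discs (default 3 mm^2,
a typical homogeneous-liver region size in rodent imaging) rasterized on the
map grid; relative T1/T2 values are liver-to-muscle signal-intensity ratios.

Maps round-trip through NIfTI-1 via nibabel; pseudo-colour renderings use a
blue-to-red (low-to-high) colour scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .fitting import FitConfig, FitError, fit_ivim_segmented, fit_r2star
from .models import AcquisitionProtocol, SignalCurve

__all__ = [
    "ParameterMap",
    "RoiSpec",
    "RoiStats",
    "fit_volume",
    "extract_roi_mean",
    "relative_signal_ratio",
]

IVIM_MAP_NAMES = ("D", "D_star", "f")


@dataclass
class ParameterMap:
    """A spatial grid of one fitted parameter with fit diagnostics.

    ``values`` is a 3-D array; ``mask`` marks voxels that were fitted.
    ``voxel_size_mm`` orders (x, y, z).
    """

    name: str
    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    mask: np.ndarray
    rss: Optional[np.ndarray] = None
    converged: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3 or self.mask.shape != self.values.shape:
            raise ValueError("values must be 3-D and mask must match its shape")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive in all dimensions")

    @property
    def in_plane_voxel_area_mm2(self) -> float:
        return self.voxel_size_mm[0] * self.voxel_size_mm[1]

    def to_nifti(self, path: Union[str, Path]) -> None:
        import nibabel as nib

        affine = np.diag([*self.voxel_size_mm, 1.0])
        img = nib.Nifti1Image(np.where(self.mask, self.values, np.nan), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: Union[str, Path], name: str = "") -> "ParameterMap":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        zooms = img.header.get_zooms()[:3]
        mask = np.isfinite(data)
        return cls(name or Path(path).stem, np.nan_to_num(data), tuple(float(z) for z in zooms), mask)

    def to_png(self, path: Union[str, Path], slice_index: int = 0) -> None:
        """Render one axial slice as a pseudo-colour (blue = low, red = high) PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        sl = np.where(self.mask, self.values, np.nan)[:, :, slice_index]
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(sl.T, origin="lower", cmap="jet", interpolation="nearest")
        fig.colorbar(im, ax=ax, label=self.name)
        ax.set_axis_off()
        fig.savefig(str(path), dpi=120, bbox_inches="tight")
        plt.close(fig)


@dataclass(frozen=True)
class RoiSpec:
    """A fixed-area disc ROI centred on a voxel of one axial slice."""

    center: tuple[int, int, int]
    area_mm2: float = 3.0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("ROI area must be positive")


@dataclass(frozen=True)
class RoiStats:
    mean: float
    sd: float
    n_voxels: int


def _disc_indices(pmap: ParameterMap, roi: RoiSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """In-plane voxel indices of the disc whose rasterized area is nearest the target.

    A voxel belongs to the ROI if its centre lies within the disc radius; the
    radius is chosen so the realized area (n * voxel area) is nearest the
    requested area, i.e. within one voxel-area of it.
    """
    cx, cy, cz = roi.center
    nx, ny, nz = pmap.values.shape
    if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
        raise ValueError("ROI centre outside the map grid")
    dx, dy, _ = pmap.voxel_size_mm
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dist = np.hypot((xs - cx) * dx, (ys - cy) * dy).ravel()
    order = np.argsort(dist, kind="stable")
    va = pmap.in_plane_voxel_area_mm2
    n_target = max(1, int(round(roi.area_mm2 / va)))
    n_target = min(n_target, dist.size)
    chosen = order[:n_target]
    return xs.ravel()[chosen], ys.ravel()[chosen], cz


def extract_roi_mean(pmap: ParameterMap, roi: RoiSpec) -> RoiStats:
    """Arithmetic mean and SD of the map over a fixed-area disc ROI.

    Mirrors the vessel-exclusion rule of manual ROI placement: an ROI that
    touches any unmasked voxel is rejected rather than silently averaged.
    """
    ix, iy, iz = _disc_indices(pmap, roi)
    if not np.all(pmap.mask[ix, iy, iz]):
        raise ValueError("ROI touches voxels outside the fitted mask")
    vals = pmap.values[ix, iy, iz]
    return RoiStats(float(np.mean(vals)), float(np.std(vals, ddof=0)), int(vals.size))


def relative_signal_ratio(liver_mean: float, muscle_mean: float) -> float:
    """Relative T1/T2 value: liver over muscle signal intensity at the same level."""
    if muscle_mean <= 0:
        raise ValueError("muscle signal must be positive")
    if liver_mean < 0:
        raise ValueError("liver signal must be non-negative")
    return liver_mean / muscle_mean


def fit_volume(
    volume: np.ndarray,
    protocol: AcquisitionProtocol,
    kind: str,
    config: FitConfig | None = None,
    mask: Optional[np.ndarray] = None,
    voxel_size_mm: tuple[float, float, float] = (0.625, 0.625, 3.0),
) -> dict[str, ParameterMap]:
    """Fit every masked voxel of a 4-D volume and return per-parameter maps.

    ``kind`` is "diffusion" (returns D, D_star and f maps via the segmented
    IVIM fit) or "relaxometry" (returns an R2_star map).  The 4th axis must
    match the protocol length.  Without an explicit mask, voxels whose first
    frame exceeds 5% of the volume maximum are fitted.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, curve)")
    abscissa = protocol.b_values if kind == "diffusion" else protocol.echo_times_ms
    if vol.shape[3] != len(abscissa):
        raise ValueError(
            f"4th dimension ({vol.shape[3]}) does not match protocol length ({len(abscissa)})"
        )
    if mask is None:
        mask = vol[..., 0] > 0.05 * vol.max() if vol.size else np.zeros(vol.shape[:3], bool)
    mask = np.asarray(mask, dtype=bool)

    names = IVIM_MAP_NAMES if kind == "diffusion" else ("R2_star",)
    shape = vol.shape[:3]
    out = {n: np.zeros(shape) for n in names}
    rss = np.zeros(shape)
    conv = np.zeros(shape, dtype=bool)
    fitted = np.zeros(shape, dtype=bool)

    for ix, iy, iz in zip(*np.nonzero(mask)):
        y = np.clip(vol[ix, iy, iz, :], 0.0, None)
        curve = SignalCurve(tuple(abscissa), tuple(y), kind)  # type: ignore[arg-type]
        try:
            if kind == "diffusion":
                res = fit_ivim_segmented(curve, config)
                out["D"][ix, iy, iz] = res.params.D
                out["D_star"][ix, iy, iz] = res.params.D_star
                out["f"][ix, iy, iz] = res.params.f
            else:
                res = fit_r2star(curve)
                out["R2_star"][ix, iy, iz] = res.params.R2_star
        except FitError:
            continue
        rss[ix, iy, iz] = res.rss
        conv[ix, iy, iz] = res.converged
        fitted[ix, iy, iz] = True

    return {
        n: ParameterMap(n, out[n], voxel_size_mm, fitted, rss=rss, converged=conv)
        for n in names
    }
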