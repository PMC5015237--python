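"""Volume container, NIfTI/DICOM I/O, isotropic resampling and SPECT background removal.

The whole pipeline works on a single in-memory volume model: a 3-D scalar grid
plus voxel spacing, world origin and a modality tag.  The shared coordinate
convention is

* voxel indices are 0-based, array axis 0 = x (patient left = increasing x),
  axis 1 = y (anterior-posterior), axis 2 = z (inferior-superior);
* world coordinate of voxel centre ``i`` = ``origin_mm + i * spacing_mm``.

SPECT and CT are assumed co-registered (hybrid scanner); no registration is
performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "Volume",
    "ResampleSpec",
    "BackgroundThreshold",
    "load_volume",
    "save_volume",
    "load_dicom_series",
    "resample",
    "suppress_background",
]


class Modality(str, Enum):
    SPECT = "SPECT"
    CT = "CT"


@dataclass
class Volume:
    """A 3-D scalar grid with voxel geometry and a modality tag.

    SPECT values are clamped to >= 0 on construction: negative values can only
    be reconstruction artefacts and would break the count-based segmentation
    contracts downstream.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: Modality
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.values.ndim}-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing_mm}")
        self.modality = Modality(self.modality)
        if self.modality is Modality.SPECT and (self.values < 0).any():
            n = int((self.values < 0).sum())
            log.info("clamping %d negative SPECT voxels to 0", n)
            self.values = np.clip(self.values, 0.0, None)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world(self, index) -> np.ndarray:
        """World coordinate (mm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(self.spacing_mm)

    def total_counts_mm3(self) -> float:
        """Sum of values times voxel volume (grid integral of the image)."""
        return float(self.values.sum() * self.voxel_volume_mm3)


@dataclass(frozen=True)
class ResampleSpec:
    """Target grid for resampling; defaults to the common 1 mm isotropic lattice."""

    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    interpolation_order: int = 3  # cubic b-spline

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")
        if self.interpolation_order not in (0, 1, 3):
            raise ValueError("interpolation order must be 0, 1 or 3")


@dataclass(frozen=True)
class BackgroundThreshold:
    """Semi-quantitative SPECT noise floor: zero everything below a fraction of a reference.

    The reference is either the global maximum voxel (default) or the total
    counts in the volume.  Reconstructed counts are not calibrated to injected
    MBq, so a fraction of the hottest voxel is the operational reading of
    "below 1 % of the injected activity".
    """

    fraction: float = 0.01
    reference: str = "global_max"  # or "total_counts"

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        if self.reference not in ("global_max", "total_counts"):
            raise ValueError(f"unknown reference {self.reference!r}")


def _check_grid(shape: tuple[int, ...]) -> None:
    if any(n < 3 for n in shape):
        raise ValueError(f"grid must be at least 3 voxels per axis, got shape {shape}")


def load_volume(path: str | Path, modality: Modality | str) -> Volume:
    """Load a NIfTI volume; spacing and origin come from the header.

    Raises ``FileNotFoundError`` for missing files, ``ValueError`` for non-3-D
    images or missing/degenerate spacing metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got {data.ndim}-D in {path}")
    _check_grid(data.shape)
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid spacing metadata (pixdim) in {path}: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    vol = Volume(values=data, spacing_mm=tuple(float(z) for z in zooms),
                 modality=modality, origin_mm=origin)
    log.info("loaded %s volume %s shape=%s spacing=%s", vol.modality.value, path,
             vol.shape, vol.spacing_mm)
    return vol


def save_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1 with a diagonal affine (spacing + origin)."""
    affine = np.diag(list(v.spacing_mm) + [1.0])
    affine[:3, 3] = v.origin_mm
    nib.save(nib.Nifti1Image(v.values.astype(np.float64), affine), str(path))


def load_dicom_series(directory: str | Path, modality: Modality | str) -> Volume:
    """Flatten a single-frame DICOM series into the Volume model.

    Slices are sorted by their position along the slice axis; in-plane spacing
    comes from PixelSpacing and the slice spacing from consecutive positions.
    This is a minimal reader for axially-stacked series, not a conformant
    DICOM implementation.
    """
    import pydicom

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such DICOM directory: {directory}")
    datasets = []
    for f in sorted(directory.iterdir()):
        if f.is_file():
            try:
                datasets.append(pydicom.dcmread(str(f)))
            except Exception:  # non-DICOM clutter is skipped
                continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")
    try:
        datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        zpos = [float(d.ImagePositionPatient[2]) for d in datasets]
    except AttributeError as e:
        raise ValueError("DICOM series lacks ImagePositionPatient metadata") from e
    try:
        row_mm, col_mm = (float(x) for x in datasets[0].PixelSpacing)
    except AttributeError as e:
        raise ValueError("DICOM series lacks PixelSpacing metadata") from e
    if len(datasets) < 2:
        raise ValueError("need at least two slices to derive slice spacing")
    dz = float(np.diff(zpos).mean())
    if dz <= 0:
        raise ValueError("non-increasing slice positions in DICOM series")
    slope = float(getattr(datasets[0], "RescaleSlope", 1.0))
    intercept = float(getattr(datasets[0], "RescaleIntercept", 0.0))
    # pixel_array is (row=y, col=x); transpose to our (x, y) in-plane order
    slices = [d.pixel_array.T.astype(np.float64) * slope + intercept for d in datasets]
    data = np.stack(slices, axis=-1)
    _check_grid(data.shape)
    origin = (float(datasets[0].ImagePositionPatient[0]),
              float(datasets[0].ImagePositionPatient[1]), zpos[0])
    return Volume(values=data, spacing_mm=(col_mm, row_mm, dz),
                  modality=modality, origin_mm=origin)


def resample(v: Volume, spec: ResampleSpec = ResampleSpec()) -> Volume:
    """Resample onto the target spacing with b-spline interpolation (cubic by default).

    The physical extent is preserved to within one output voxel; the origin is
    shifted so voxel centres of the two grids cover the same physical slab.
    SPECT output is clamped to >= 0 (cubic overshoot near sharp edges).
    """
    factors = tuple(s / t for s, t in zip(v.spacing_mm, spec.target_spacing_mm))
    out_shape = tuple(int(round(n * f)) for n, f in zip(v.shape, factors))
    if any(n < 3 for n in out_shape):
        raise ValueError(
            f"degenerate extent: target spacing {spec.target_spacing_mm} leaves "
            f"shape {out_shape}; need >= 3 voxels per axis")
    # prefilter=False expands the samples in the b-spline basis (a smoothing
    # spline, not an interpolating one): non-negative for non-negative input,
    # partition of unity, conserves the grid integral.  The interpolating
    # variant rings around isolated peaks; its negative lobes would be clamped
    # away and inflate SPECT counts.
    out = ndimage.zoom(v.values, zoom=factors, order=spec.interpolation_order,
                       mode="nearest", grid_mode=True, prefilter=False)
    if v.modality is Modality.SPECT:
        out = np.clip(out, 0.0, None)
    # grid_mode=True aligns grid edges, so the first output voxel centre moves
    # by (target - source)/2 along each axis.
    origin = tuple(o + (t - s) / 2.0
                   for o, s, t in zip(v.origin_mm, v.spacing_mm, spec.target_spacing_mm))
    log.info("resampled %s %s@%s -> %s@%s", v.modality.value, v.shape, v.spacing_mm,
             out.shape, spec.target_spacing_mm)
    return Volume(values=out, spacing_mm=spec.target_spacing_mm,
                  modality=v.modality, origin_mm=origin)


def suppress_background(v: Volume, t: BackgroundThreshold = BackgroundThreshold()) -> Volume:
    """Zero every SPECT voxel below ``fraction`` of the reference value.

    Idempotent; never zeroes the global maximum; an all-zero volume is
    returned unchanged with a warning.
    """
    if v.modality is not Modality.SPECT:
        raise ValueError("background suppression applies to SPECT volumes only")
    ref = float(v.values.max()) if t.reference == "global_max" else float(v.values.sum())
    if ref <= 0:
        log.warning("suppress_background: all-zero volume, nothing to do")
        return replace(v, values=v.values.copy())
    cutoff = t.fraction * ref
    out = np.where(v.values < cutoff, 0.0, v.values)
    log.info("background cutoff %.6g (%s x %.4g); zeroed %d of %d voxels",
             cutoff, t.reference, t.fraction,
             int((v.values < cutoff).sum() - (v.values == 0).sum()), v.values.size)
    return replace(v, values=out)
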