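"""CT volume and ROI handling: loading, bounding-box cropping, resampling,
and absolute discretization.

The preprocessing chain mirrors standard planning-CT radiomics practice: a
tight 3D bounding box is fitted around each ROI, voxels outside the ROI are
zero-marked (for export parity only — every statistic downstream uses the
validity mask, never the zeros), intensities are resampled to 1 x 1 x 5 mm,
and HU values are discretized into 400 absolute bins of 10 HU covering
-1000..3000 HU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, DegenerateROIError, DomainError, FormatError

# Absolute discretization constants: 400 bins of 10 HU over -1000..3000 HU.
HU_LO = -1000.0
HU_HI = 3000.0
N_BINS = 400
BIN_WIDTH = (HU_HI - HU_LO) / N_BINS  # = 10 HU exactly

#: Target grid used throughout: 1 mm in-plane, 5 mm slice direction.
DEFAULT_SPACING = (1.0, 1.0, 5.0)

#: Sentinel bin index for voxels outside the ROI.
INVALID_BIN = -1


@dataclass
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units with physical geometry.

    Axis order is (x, y, z) with ``spacing`` in mm per voxel along each axis
    and ``origin`` the physical position of voxel (0, 0, 0).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise DomainError("CT grid must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing):
            raise DomainError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.grid)):
            raise DomainError("CT grid contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class ROIMask:
    """A binary mask aligned voxel-for-voxel with a :class:`CTVolume`."""

    grid: np.ndarray
    label: str = "tumor"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        values = np.unique(grid)
        if not np.all(np.isin(values, (0, 1))):
            raise DomainError("ROI mask must be binary (0/1)")
        self.grid = grid.astype(bool)
        if self.grid.ndim != 3:
            raise DomainError("ROI mask must be 3D")
        if not self.grid.any():
            raise DomainError(f"ROI mask '{self.label}' has no foreground voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class MaskedSubvolume:
    """A bounding-box crop: HU grid plus an aligned ROI validity mask.

    Voxels with ``valid == False`` carry grid value 0 (the zero marker);
    ROI voxels retain the HU of the source volume.
    """

    grid: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.valid = np.asarray(self.valid).astype(bool)
        if self.grid.shape != self.valid.shape:
            raise AlignmentError("grid and validity mask shapes differ")
        # enforce the zero marker outside the ROI
        self.grid = np.where(self.valid, self.grid, 0.0)

    @property
    def hu_values(self) -> np.ndarray:
        """Raw HU of ROI voxels only."""
        return self.grid[self.valid]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class DiscretizedVolume:
    """Integer bin indices (0..399) for ROI voxels; -1 outside the ROI."""

    bins: np.ndarray
    valid: np.ndarray
    n_bins: int = N_BINS
    lo: float = HU_LO
    hi: float = HU_HI
    spacing: tuple[float, float, float] = field(default=DEFAULT_SPACING)

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int64)
        self.valid = np.asarray(self.valid).astype(bool)
        if self.bins.shape != self.valid.shape:
            raise AlignmentError("bins and validity mask shapes differ")
        inside = self.bins[self.valid]
        if inside.size and (inside.min() < 0 or inside.max() >= self.n_bins):
            raise DomainError("bin index outside [0, n_bins) for a valid voxel")

    @property
    def bin_width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def load_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    HU values are passed through unmodified; spacing and origin come from
    the header. DICOM directories are read with SimpleITK's series reader.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file or directory: {path}")
    if os.path.isdir(path):
        return _load_dicom_series(path)
    try:
        import nibabel as nib

        img = nib.load(path)
    except Exception as exc:  # nibabel raises a mix of its own error types
        raise FormatError(f"not a readable image: {path}: {exc}") from exc
    grid = np.asanyarray(img.dataobj, dtype=np.float64)
    if grid.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {grid.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(grid=grid, spacing=tuple(float(z) for z in zooms), origin=origin)


def _load_dicom_series(directory: str) -> CTVolume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(directory)
    if not names:
        raise FormatError(f"no DICOM series found under {directory}")
    reader.SetFileNames(names)
    image = reader.Execute()
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
    grid = sitk.GetArrayFromImage(image).transpose(2, 1, 0).astype(np.float64)
    return CTVolume(
        grid=grid,
        spacing=tuple(float(s) for s in image.GetSpacing()),
        origin=tuple(float(o) for o in image.GetOrigin()),
    )


def save_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with spacing/origin in the affine."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.grid.astype(np.float32), affine), os.fspath(path))


def load_mask(path: str | os.PathLike, label: str) -> ROIMask:
    """Read a 0/1 byte mask sharing the CT geometry."""
    vol = load_volume(path)
    return ROIMask(grid=vol.grid > 0.5, label=label)


def save_mask(mask: ROIMask, spacing: tuple[float, float, float], path: str | os.PathLike) -> None:
    save_volume(CTVolume(grid=mask.grid.astype(np.float64), spacing=spacing), path)


def exclude_tumor_from_lung(lung: ROIMask, tumor: ROIMask) -> ROIMask:
    """Subtract the tumor (GTV) from the lung mask.

    Lung delineations conventionally exclude the gross tumor volume; applying
    the subtraction at load time guarantees it regardless of how the masks
    were drawn.
    """
    if lung.grid.shape != tumor.grid.shape:
        raise AlignmentError("lung and tumor masks have different shapes")
    grid = lung.grid & ~tumor.grid
    if not grid.any():
        raise DomainError("lung mask is empty after tumor exclusion")
    return ROIMask(grid=grid, label="lung")


def bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    """Tight axis-aligned bounding box of a boolean array (inclusive voxels)."""
    if not mask.any():
        raise DomainError("cannot fit a bounding box around an empty mask")
    slices = []
    for axis in range(mask.ndim):
        profile = mask.any(axis=tuple(a for a in range(mask.ndim) if a != axis))
        idx = np.flatnonzero(profile)
        slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    return tuple(slices)


def crop_to_roi(volume: CTVolume, mask: ROIMask) -> MaskedSubvolume:
    """Fit the tight 3D bounding box of the ROI and zero-mark non-ROI voxels."""
    if volume.grid.shape != mask.grid.shape:
        raise AlignmentError(
            f"mask shape {mask.grid.shape} does not match volume {volume.grid.shape}"
        )
    box = bounding_box(mask.grid)
    valid = mask.grid[box]
    grid = np.where(valid, volume.grid[box], 0.0)
    return MaskedSubvolume(grid=grid, valid=valid, spacing=volume.spacing, provenance=mask.label)


def resample(
    sub: MaskedSubvolume,
    target_spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> MaskedSubvolume:
    """Resample to ``target_spacing`` (trilinear grid, nearest-neighbour mask).

    Grid-point alignment: output sample j along an axis sits at physical
    position j * target over the extent (n - 1) * spacing, so resampling at
    the native spacing is the identity and a constant field stays constant.
    The validity mask is resampled nearest-neighbour and re-binarized.
    """
    if any(t <= 0 for t in target_spacing):
        raise DomainError(f"target spacing must be positive, got {target_spacing}")
    if tuple(sub.spacing) == tuple(target_spacing):
        return MaskedSubvolume(
            grid=sub.grid.copy(), valid=sub.valid.copy(),
            spacing=tuple(target_spacing), provenance=sub.provenance,
        )
    in_shape = sub.grid.shape
    out_shape = []
    coords = []
    for n, s_in, s_out in zip(in_shape, sub.spacing, target_spacing):
        extent = (n - 1) * s_in
        m = max(1, int(np.floor(extent / s_out + 1e-9)) + 1)
        out_shape.append(m)
        coords.append(np.arange(m) * (s_out / s_in))
    mesh = np.meshgrid(*coords, indexing="ij")
    pts = np.stack([c.ravel() for c in mesh])
    grid = ndimage.map_coordinates(sub.grid, pts, order=1, mode="nearest").reshape(out_shape)
    valid = ndimage.map_coordinates(
        sub.valid.astype(np.uint8), pts, order=0, mode="nearest"
    ).reshape(out_shape).astype(bool)
    return MaskedSubvolume(
        grid=np.where(valid, grid, 0.0), valid=valid,
        spacing=tuple(target_spacing), provenance=sub.provenance,
    )


def discretize(sub: MaskedSubvolume) -> DiscretizedVolume:
    """Absolute discretization: bin = floor((HU + 1000) / 10), clamped to [0, 399].

    Out-of-range HU (metal artefacts above 3000 HU, sub-air values) is clamped
    to the edge bins. Invalid voxels carry the sentinel -1 and never enter any
    downstream feature computation.
    """
    if sub.n_valid == 0:
        raise DegenerateROIError("cannot discretize an empty ROI")
    bins = np.floor((sub.grid - HU_LO) / BIN_WIDTH).astype(np.int64)
    bins = np.clip(bins, 0, N_BINS - 1)
    bins[~sub.valid] = INVALID_BIN
    return DiscretizedVolume(bins=bins, valid=sub.valid, spacing=sub.spacing)


def preprocess_roi(
    volume: CTVolume,
    mask: ROIMask,
    target_spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> tuple[MaskedSubvolume, DiscretizedVolume]:
    """The full chain for one ROI: crop -> resample -> discretize."""
    sub = resample(crop_to_roi(volume, mask), target_spacing)
    return sub, discretize(sub)
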