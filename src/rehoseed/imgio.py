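"""NIfTI I/O, grid geometry, masking and temporal bandpass filtering.

Volumes are expected to arrive motion-corrected and spatially normalized;
this module only loads them onto a common grid, restricts them to a brain
mask and applies the 0.01-0.08 Hz bandpass that isolates the resting-state
BOLD band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import signal

from rehoseed.errors import FormatError, GeometryError, InputError, ParameterError

logger = logging.getLogger(__name__)

AFFINE_TOL_MM = 1e-4


@dataclass(frozen=True)
class GridGeom:
    """Voxel grid geometry: shape plus voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise GeometryError(f"shape must be 3 positive ints, got {self.shape}")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Edge lengths of a voxel in mm, from the affine columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "GridGeom", tol_mm: float = AFFINE_TOL_MM) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol_mm, rtol=0.0
        )


@dataclass(frozen=True)
class BrainMask:
    """Boolean in-brain indicator on a grid.

    In-mask voxels are enumerated in C order; that ordering defines the
    flat "mask vector" layout used by every per-voxel map downstream.
    """

    geom: GridGeom
    inside: np.ndarray

    def __post_init__(self) -> None:
        inside = np.asarray(self.inside, dtype=bool)
        if inside.shape != self.geom.shape:
            raise GeometryError(
                f"mask shape {inside.shape} != grid shape {self.geom.shape}"
            )
        if not inside.any():
            raise InputError("mask has no in-brain voxels")
        object.__setattr__(self, "inside", inside)

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())

    @property
    def ijk(self) -> np.ndarray:
        """(n_voxels, 3) voxel indices of in-mask voxels, C order."""
        return np.argwhere(self.inside)

    def vector_to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a mask-vector of per-voxel values back onto the 3D grid."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise InputError(
                f"vector length {values.shape[0]} != mask size {self.n_voxels}"
            )
        out = np.full(self.geom.shape + values.shape[1:], fill, dtype=values.dtype)
        out[self.inside] = values
        return out

    def restrict(self, keep: np.ndarray) -> "BrainMask":
        """New mask keeping only in-mask voxels where ``keep`` is True."""
        inside = np.zeros(self.geom.shape, dtype=bool)
        inside[self.inside] = np.asarray(keep, dtype=bool)
        return BrainMask(self.geom, inside)


@dataclass
class Volume4D:
    """One subject's masked voxel x time array.

    ``data`` has shape (n_voxels, n_timepoints) with rows in the mask's
    C-order voxel enumeration.
    """

    geom: GridGeom
    mask: BrainMask
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("Volume4D data must be 2D (voxels, timepoints)")
        if self.data.shape[0] != self.mask.n_voxels:
            raise GeometryError(
                f"data has {self.data.shape[0]} voxels, mask has {self.mask.n_voxels}"
            )
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        if not np.isfinite(self.data).all():
            raise InputError("Volume4D contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def load_mask(path: str | Path) -> BrainMask:
    """Read a 3D NIfTI mask; nonzero voxels are in-brain."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise FormatError(f"mask must be 3D, got {arr.ndim}D")
    geom = GridGeom(arr.shape, img.affine)
    return BrainMask(geom, arr != 0)


def load_subject(path: str | Path, mask: BrainMask, tr_seconds: float = 2.0) -> Volume4D:
    """Load a 4D NIfTI time series restricted to ``mask``.

    Voxels whose series is non-finite or has zero temporal variance are
    dropped from the effective mask (correlations and ranks are undefined
    there); the returned volume carries the reduced mask.
    """
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise FormatError(f"expected a 4D NIfTI, got {arr.ndim} dimensions")
    geom = GridGeom(arr.shape[:3], img.affine)
    if not geom.matches(mask.geom):
        raise GeometryError(
            f"volume grid {geom.shape} / affine does not match mask grid"
        )
    data = arr[mask.inside].astype(float)  # (n_voxels, n_timepoints)
    good = np.isfinite(data).all(axis=1) & (data.std(axis=1) > 0)
    if not good.all():
        n_bad = int((~good).sum())
        logger.info("dropping %d constant or non-finite voxels from mask", n_bad)
        mask = mask.restrict(good)
        data = data[good]
    return Volume4D(geom=mask.geom, mask=mask, data=data, tr_seconds=tr_seconds)


def save_volume(vol: Volume4D, path: str | Path) -> None:
    """Write a Volume4D back to NIfTI (out-of-mask voxels zero)."""
    full = np.zeros(vol.geom.shape + (vol.n_timepoints,), dtype=np.float64)
    full[vol.mask.inside] = vol.data
    nib.save(nib.Nifti1Image(full, vol.geom.affine), str(path))


def save_map(values: np.ndarray, mask: BrainMask, path: str | Path) -> None:
    """Write a per-voxel mask-vector as a 3D NIfTI scalar map."""
    vol = mask.vector_to_volume(np.asarray(values, dtype=np.float64))
    nib.save(nib.Nifti1Image(vol, mask.geom.affine), str(path))


def bandpass(
    vol: Volume4D,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 2,
) -> Volume4D:
    """Zero-phase Butterworth bandpass of every voxel time course.

    The filter is applied forward-backward (``sosfiltfilt``), so the
    effective attenuation is the squared magnitude response of a
    Butterworth of the given order. Each series is demeaned before and
    after filtering; the passband excludes DC by construction.
    """
    nyquist = 1.0 / (2.0 * vol.tr_seconds)
    if not (0.0 < low_hz < high_hz):
        raise ParameterError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyquist:
        raise ParameterError(
            f"high_hz={high_hz} must be below Nyquist {nyquist:.4f} Hz (TR={vol.tr_seconds}s)"
        )
    if vol.n_timepoints < 8:
        raise ParameterError("need at least 8 timepoints to bandpass")
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / vol.tr_seconds, output="sos"
    )
    x = vol.data - vol.data.mean(axis=1, keepdims=True)
    y = signal.sosfiltfilt(sos, x, axis=1)
    y = y - y.mean(axis=1, keepdims=True)
    return Volume4D(geom=vol.geom, mask=vol.mask, data=y, tr_seconds=vol.tr_seconds)
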