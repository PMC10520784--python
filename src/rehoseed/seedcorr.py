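"""Seed regions and whole-brain Fisher-z seed correlation maps.

A seed is either a literature sphere around an MNI-mm coordinate or a
data-driven cluster of voxels. Its unweighted mean time course r is
correlated (Pearson) with every in-mask voxel series F, and the
correlation is Fisher z-transformed (arctanh) for group statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from rehoseed.errors import InputError, SeedError
from rehoseed.imgio import BrainMask, GridGeom, Volume4D

# correlations are clipped to +-(1 - CLIP_EPS) before arctanh so maps stay finite
CLIP_EPS = 1e-7


@dataclass
class SeedRegion:
    """A named set of in-mask voxels used to extract a reference time course.

    ``voxels`` are indices into the mask's C-order voxel enumeration.
    """

    name: str
    voxels: np.ndarray
    origin: str  # "literature_sphere" | "reho_cluster"
    mask: BrainMask
    center_mm: np.ndarray | None = None
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.unique(np.asarray(self.voxels, dtype=np.int64))
        if self.voxels.size == 0:
            raise SeedError(f"seed {self.name!r} is empty")
        if self.voxels.min() < 0 or self.voxels.max() >= self.mask.n_voxels:
            raise SeedError(f"seed {self.name!r} has voxels outside the mask")

    @property
    def size(self) -> int:
        return int(self.voxels.size)

    @property
    def ijk(self) -> np.ndarray:
        return self.mask.ijk[self.voxels]

    def centroid_mm(self) -> np.ndarray:
        return self.mask.geom.voxel_to_world(self.ijk).mean(axis=0)

    def save(self, path: str | Path) -> None:
        """Write as a NIfTI label volume plus a JSON sidecar."""
        lab = np.zeros(self.mask.n_voxels, dtype=np.int16)
        lab[self.voxels] = 1
        vol = self.mask.vector_to_volume(lab)
        nib.save(nib.Nifti1Image(vol.astype(np.int16), self.mask.geom.affine), str(path))
        meta = {
            "name": self.name,
            "origin": self.origin,
            "n_voxels": self.size,
            "center_mm": None if self.center_mm is None else list(map(float, self.center_mm)),
            "radius_mm": self.radius_mm,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


@dataclass
class FCMap:
    """Per-voxel Fisher z of the seed-to-voxel Pearson correlation."""

    geom: GridGeom
    mask: BrainMask
    z: np.ndarray
    seed_name: str = ""
    flagged: np.ndarray | None = None  # zero-variance voxels, z forced to 0


def sphere_seed(
    center_mm: np.ndarray,
    radius_mm: float,
    mask: BrainMask,
    name: str = "sphere",
) -> SeedRegion:
    """All in-mask voxels whose center lies within ``radius_mm`` of ``center_mm``.

    Distance is voxel-center to sphere-center in world mm via the affine.
    """
    center_mm = np.asarray(center_mm, dtype=float)
    world = mask.geom.voxel_to_world(mask.ijk)
    dist = np.linalg.norm(world - center_mm, axis=1)
    voxels = np.flatnonzero(dist <= radius_mm)
    if voxels.size == 0:
        raise SeedError(
            f"sphere at {center_mm.tolist()} r={radius_mm}mm contains no in-mask voxel"
        )
    return SeedRegion(
        name=name,
        voxels=voxels,
        origin="literature_sphere",
        mask=mask,
        center_mm=center_mm,
        radius_mm=float(radius_mm),
    )


# literature DMN seeds commonly used in childhood-ADHD resting-state work,
# MNI mm, built with a 6 mm radius
LITERATURE_SEEDS_MM = {
    "dACC": (8.0, 7.0, 38.0),
    "vmPFC": (2.0, 56.0, 0.0),
    "PCC": (-2.0, -54.0, 27.0),
}
LITERATURE_SEED_RADIUS_MM = 6.0


def literature_seeds(mask: BrainMask, radius_mm: float = LITERATURE_SEED_RADIUS_MM) -> list[SeedRegion]:
    """The three standard DMN spheres (dACC, vmPFC, PCC) on this grid."""
    return [
        sphere_seed(np.array(c), radius_mm, mask, name=name)
        for name, c in LITERATURE_SEEDS_MM.items()
    ]


def seed_timecourse(vol: Volume4D, seed: SeedRegion) -> np.ndarray:
    """Unweighted mean of the seed voxels' series at each timepoint."""
    if seed.voxels.max() >= vol.data.shape[0]:
        raise SeedError("seed voxels outside the volume's mask")
    return vol.data[seed.voxels].mean(axis=0)


def fc_map(vol: Volume4D, seed: SeedRegion) -> FCMap:
    """Whole-brain Fisher-z map of the seed's mean time course.

    Pearson correlation of the reference course against every in-mask
    voxel, clipped to +-(1 - 1e-7) and arctanh-transformed. Voxels with
    zero temporal variance get z = 0 and are flagged.
    """
    if vol.n_timepoints < 3:
        raise InputError("need at least 3 timepoints for a correlation map")
    r = seed_timecourse(vol, seed)
    r = r - r.mean()
    r_norm = np.linalg.norm(r)
    x = vol.data - vol.data.mean(axis=1, keepdims=True)
    x_norm = np.linalg.norm(x, axis=1)
    ok = (x_norm > 0) & (r_norm > 0)
    cc = np.zeros(vol.data.shape[0])
    if r_norm > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = np.where(ok, (x @ r) / (x_norm * r_norm + ~ok), 0.0)
    cc = np.clip(cc, -(1.0 - CLIP_EPS), 1.0 - CLIP_EPS)
    z = np.arctanh(cc)
    z[~ok] = 0.0
    return FCMap(geom=vol.geom, mask=vol.mask, z=z, seed_name=seed.name, flagged=~ok)
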