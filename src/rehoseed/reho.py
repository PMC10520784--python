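"""Regional homogeneity: Kendall's coefficient of concordance per voxel.

ReHo at a voxel measures how concordantly the voxel and its immediate
neighbors fluctuate over time. Each of the K series in a 3x3x3 (27-voxel)
neighborhood is ranked over the n timepoints; with R_i the rank sum at
timepoint i and Rbar = (n+1)K/2 their mean, Kendall's W is

    W = (sum_i R_i^2 - n Rbar^2) / (K^2 (n^3 - n) / 12)

ranging from 0 (no agreement) to 1 (perfect concordance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from rehoseed.errors import InputError, ParameterError
from rehoseed.imgio import BrainMask, GridGeom, Volume4D

# neighbor offsets by neighborhood size: 7 = faces, 19 = faces+edges,
# 27 = full cube (the voxel itself is always included)
_CUBE = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
]
NEIGHBORHOOD_OFFSETS = {
    7: [o for o in _CUBE if sum(v * v for v in o) <= 1],
    19: [o for o in _CUBE if sum(v * v for v in o) <= 2],
    27: _CUBE,
}


@dataclass
class ReHoMap:
    """Per-voxel Kendall's W on a masked grid.

    ``w`` is a mask-vector in [0, 1]; ``flagged`` marks voxels whose
    effective neighborhood had fewer than 2 usable series (W forced to 0).
    """

    geom: GridGeom
    mask: BrainMask
    w: np.ndarray
    flagged: np.ndarray
    neighborhood: int = 27

    def normalized(self) -> "ReHoMap":
        """Divide by the in-mask mean W (per-subject standardization)."""
        mean_w = float(self.w.mean())
        if mean_w <= 0:
            raise InputError("cannot normalize a ReHo map with mean W <= 0")
        return ReHoMap(self.geom, self.mask, self.w / mean_w, self.flagged, self.neighborhood)

    def qc_summary(self) -> dict:
        return {
            "mean_w": float(self.w.mean()),
            "max_w": float(self.w.max()),
            "n_flagged": int(self.flagged.sum()),
        }


def _concordance(rank_sums: np.ndarray, n: int, k: np.ndarray | int) -> np.ndarray:
    """Kendall's W from per-timepoint rank sums (no tie correction)."""
    k = np.asarray(k, dtype=float)
    rbar = (n + 1) * k / 2.0
    s = (rank_sums**2).sum(axis=-1) - n * rbar**2
    denom = k**2 * (n**3 - n) / 12.0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, s / denom, 0.0)
    return np.clip(w, 0.0, 1.0)


def kendalls_w(series_set: np.ndarray) -> float:
    """Kendall's W of K time series of length n.

    Ties get average (mid-)ranks with no tie correction in the
    denominator. Raises for constant series, whose ranks are undefined.
    """
    series = np.asarray(series_set, dtype=float)
    if series.ndim != 2:
        raise InputError("series_set must be 2D (K, n)")
    k, n = series.shape
    if k < 2 or n < 2:
        raise ParameterError(f"need K >= 2 and n >= 2, got K={k}, n={n}")
    if (series.std(axis=1) == 0).any():
        raise InputError("constant series have undefined ranks")
    ranks = rankdata(series, axis=1)
    rank_sums = ranks.sum(axis=0)
    return float(_concordance(rank_sums, n, k))


def reho_map(
    vol: Volume4D,
    mask: BrainMask | None = None,
    neighborhood: int = 27,
) -> ReHoMap:
    """Kendall's W over each in-mask voxel's 3D neighborhood.

    At mask edges only in-mask neighbors participate, with the effective
    K substituted into the formula (no padding). Constant-series voxels
    are excluded from every neighborhood; voxels left with fewer than 2
    usable series get W = 0 and are flagged.
    """
    if neighborhood not in NEIGHBORHOOD_OFFSETS:
        raise ParameterError(f"neighborhood must be one of {{7,19,27}}, got {neighborhood}")
    mask = mask or vol.mask
    if mask.n_voxels != vol.data.shape[0]:
        raise InputError("mask does not match the volume's voxel layout")
    n = vol.n_timepoints
    usable = vol.data.std(axis=1) > 0

    ranks = np.zeros_like(vol.data)
    if usable.any():
        ranks[usable] = rankdata(vol.data[usable], axis=1)

    # index volume: vector index of each usable in-mask voxel, -1 elsewhere
    shape = mask.geom.shape
    idx_vol = np.full(shape, -1, dtype=np.int64)
    idx_vol[mask.inside] = np.where(usable, np.arange(mask.n_voxels), -1)
    padded = np.full(tuple(s + 2 for s in shape), -1, dtype=np.int64)
    padded[1:-1, 1:-1, 1:-1] = idx_vol

    rank_sums = np.zeros((mask.n_voxels, n))
    k_eff = np.zeros(mask.n_voxels, dtype=np.int64)
    sx, sy, sz = shape
    for dx, dy, dz in NEIGHBORHOOD_OFFSETS[neighborhood]:
        shifted = padded[1 + dx : 1 + dx + sx, 1 + dy : 1 + dy + sy, 1 + dz : 1 + dz + sz]
        nbr = shifted[mask.inside]  # vector index of this neighbor per voxel
        valid = nbr >= 0
        rank_sums[valid] += ranks[nbr[valid]]
        k_eff += valid

    w = _concordance(rank_sums, n, k_eff)
    flagged = (k_eff < 2) | ~usable
    w[flagged] = 0.0
    return ReHoMap(geom=mask.geom, mask=mask, w=w, flagged=flagged, neighborhood=neighborhood)
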