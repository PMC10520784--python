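"""Voxel-wise group statistics, leave-one-out voting and cluster selection.

The group-difference map is a per-voxel linear model
``value = b0 + bg * group + bs * sex``; the reported t is the one on the
group coefficient (a two-sample t-test with sex as covariate). Candidate
voxels must survive p < alpha AND belong to a connected component of at
least ``min_extent`` voxels, in more than 33% of leave-one-subject-out
refits of that test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from rehoseed.errors import DesignError, InputError, ParameterError
from rehoseed.imgio import BrainMask, GridGeom
from rehoseed.seedcorr import SeedRegion

logger = logging.getLogger(__name__)

VOTE_THRESHOLD = 0.33  # strict >: a voxel needs more than 33% of the votes

GROUP_LEVELS = ("control", "ADHD")  # group coded 0/1 in this order
SEX_LEVELS = ("M", "F")


@dataclass
class SubjectTable:
    """Subject ids with group (ADHD/control) and sex (F/M) labels."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = {"subject_id", "group", "sex"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"subject table missing columns {sorted(missing)}")
        if df["subject_id"].duplicated().any():
            raise InputError("duplicate subject ids")
        bad_group = set(df["group"]) - set(GROUP_LEVELS)
        if bad_group:
            raise InputError(f"unknown group labels {sorted(bad_group)}")
        bad_sex = set(df["sex"]) - set(SEX_LEVELS)
        if bad_sex:
            raise InputError(f"unknown sex labels {sorted(bad_sex)}")
        for g in GROUP_LEVELS:
            if (df["group"] == g).sum() == 0:
                raise InputError(f"group {g!r} is empty")
        self.frame = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list:
        return list(self.frame["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def group_indicator(self) -> np.ndarray:
        """1 for ADHD, 0 for control."""
        return (self.frame["group"] == "ADHD").to_numpy(dtype=float)

    def sex_indicator(self) -> np.ndarray:
        """1 for F, 0 for M."""
        return (self.frame["sex"] == "F").to_numpy(dtype=float)

    def subset(self, rows: np.ndarray) -> "SubjectTable":
        return SubjectTable(self.frame.iloc[np.asarray(rows)].reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "SubjectTable":
        return cls(pd.read_csv(path))


@dataclass
class TMap:
    geom: GridGeom
    mask: BrainMask
    t: np.ndarray
    p: np.ndarray
    dof: int


@dataclass
class VoteMap:
    geom: GridGeom
    mask: BrainMask
    vote_fraction: np.ndarray
    n_maps: int

    def candidates(self, threshold: float = VOTE_THRESHOLD) -> np.ndarray:
        """Mask-vector indices of voxels with strictly more votes than the cut."""
        return np.flatnonzero(self.vote_fraction > threshold)


@dataclass
class Cluster:
    voxels: np.ndarray  # mask-vector indices
    size: int
    peak_voxel: int  # mask-vector index of max |t| (or first voxel if no t given)
    sign: int  # sign of the mean t over the cluster (0 if no t given)


@dataclass
class ClusterSet:
    mask: BrainMask
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def to_frame(self) -> pd.DataFrame:
        """Cluster table: peak world-mm coordinates and sizes, largest first."""
        rows = []
        for c in self.clusters:
            ijk = self.mask.ijk[c.peak_voxel]
            x, y, z = self.mask.geom.voxel_to_world(ijk)[0]
            rows.append({"x": x, "y": y, "z": z, "cluster_size": c.size, "sign": c.sign})
        return pd.DataFrame(rows, columns=["x", "y", "z", "cluster_size", "sign"])


def glm_ttest(
    maps: np.ndarray,
    table: SubjectTable,
    mask: BrainMask | None = None,
    covariates: tuple[str, ...] = ("sex",),
) -> TMap:
    """Per-voxel t-test on the group effect, adjusted for sex.

    ``maps`` is (n_subjects, n_voxels) of per-subject scalar values
    (ReHo W or Fisher z). Fits an OLS model with intercept, group and the
    requested covariates at every voxel and returns the t and two-sided p
    of the group coefficient; dof = n_subjects - n_regressors.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] != table.n_subjects:
        raise InputError(f"maps must be (n_subjects, n_voxels); got {maps.shape}")
    for g in GROUP_LEVELS:
        if (table.frame["group"] == g).sum() < 2:
            raise InputError(f"need at least 2 subjects in group {g!r}")
    cols = [np.ones(table.n_subjects), table.group_indicator()]
    if "sex" in covariates:
        cols.append(table.sex_indicator())
    X = np.column_stack(cols)
    n, p_reg = X.shape
    if np.linalg.matrix_rank(X) < p_reg:
        raise DesignError("design matrix is rank deficient (covariate confounded with group?)")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ maps  # (p_reg, n_voxels)
    resid = maps - X @ beta
    dof = n - p_reg
    sigma2 = (resid**2).sum(axis=0) / dof
    # a residual variance at rounding-error scale means the model fits the
    # voxel exactly (e.g. identical maps): report t = 0 there, not 0/0 noise
    scale = np.maximum((maps**2).mean(axis=0), np.finfo(float).tiny)
    degenerate = sigma2 <= 1e-24 * scale
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    ok = (se > 0) & ~degenerate
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(ok, beta[1] / np.where(ok, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return TMap(geom=mask.geom if mask else None, mask=mask, t=t, p=p, dof=dof)


def cluster_components(
    binary: np.ndarray,
    mask: BrainMask,
    connectivity: int = 6,
    min_extent: int = 10,
    t_values: np.ndarray | None = None,
) -> ClusterSet:
    """Connected components of a suprathreshold set, extent-filtered.

    ``binary`` is a mask-vector of booleans. Components are joined under
    face (6), face+edge (18) or face+edge+corner (26) adjacency;
    components smaller than ``min_extent`` are dropped and the rest are
    returned sorted by size descending (ties by first voxel index).
    """
    if connectivity not in (6, 18, 26):
        raise ParameterError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    binary = np.asarray(binary, dtype=bool)
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    vol = mask.vector_to_volume(binary)
    labels, n_labels = ndimage.label(vol, structure=structure)
    lab_vec = labels[mask.inside]

    clusters = []
    for lab in range(1, n_labels + 1):
        voxels = np.flatnonzero(lab_vec == lab)
        if voxels.size < min_extent:
            continue
        if t_values is not None:
            tv = np.asarray(t_values)[voxels]
            peak = int(voxels[np.argmax(np.abs(tv))])
            sign = int(np.sign(tv.mean()))
        else:
            peak, sign = int(voxels[0]), 0
        clusters.append(Cluster(voxels=voxels, size=int(voxels.size), peak_voxel=peak, sign=sign))
    clusters.sort(key=lambda c: (-c.size, c.voxels[0]))
    return ClusterSet(mask=mask, clusters=clusters)


def loo_vote(
    maps: np.ndarray,
    table: SubjectTable,
    mask: BrainMask,
    alpha: float = 0.01,
    min_extent: int = 10,
    connectivity: int = 6,
    cluster_filter: bool = True,
    covariates: tuple[str, ...] = ("sex",),
) -> VoteMap:
    """Leave-one-subject-out voting over thresholded t-maps.

    For each left-out subject the group t-test is refit on the remaining
    subjects, thresholded at two-sided p < alpha and (by default) cluster
    extent-filtered; surviving voxels receive one vote. A fold whose
    training half would empty a group is skipped with a warning.
    """
    maps = np.asarray(maps, dtype=float)
    n = table.n_subjects
    if n < 3:
        raise InputError("leave-one-out voting needs at least 3 subjects")
    votes = np.zeros(maps.shape[1], dtype=np.int64)
    n_maps = 0
    group = table.group_indicator()
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if len(np.unique(group[keep])) < 2 or min(
            (group[keep] == 0).sum(), (group[keep] == 1).sum()
        ) < 2:
            logger.warning("LOO fold %d skipped: a group would be empty or singleton", i)
            continue
        tmap = glm_ttest(maps[keep], table.subset(keep), covariates=covariates)
        surviving = tmap.p < alpha
        if cluster_filter:
            comp = cluster_components(
                surviving, mask, connectivity=connectivity, min_extent=min_extent
            )
            surviving = np.zeros_like(surviving)
            for c in comp.clusters:
                surviving[c.voxels] = True
        votes += surviving
        n_maps += 1
    if n_maps == 0:
        raise InputError("no valid LOO folds")
    return VoteMap(geom=mask.geom, mask=mask, vote_fraction=votes / n_maps, n_maps=n_maps)


def select_reho_seeds(
    clusters: ClusterSet,
    k: int = 4,
    dedup_radius_mm: float = 20.0,
) -> list[SeedRegion]:
    """Greedy largest-first pick of up to ``k`` clusters as seeds.

    A cluster is skipped when its centroid lies within ``dedup_radius_mm``
    of an already-picked centroid, either directly or after mirroring the
    picked centroid across the x = 0 midline — so contralateral homologs
    of an already-selected region are not picked twice.
    """
    if len(clusters) == 0:
        raise InputError("no clusters to select seeds from")
    mask = clusters.mask
    picked: list[SeedRegion] = []
    picked_centroids: list[np.ndarray] = []
    for idx, c in enumerate(clusters.clusters):
        if len(picked) >= k:
            break
        centroid = mask.geom.voxel_to_world(mask.ijk[c.voxels]).mean(axis=0)
        mirror = centroid * np.array([-1.0, 1.0, 1.0])
        too_close = any(
            np.linalg.norm(centroid - pc) <= dedup_radius_mm
            or np.linalg.norm(mirror - pc) <= dedup_radius_mm
            for pc in picked_centroids
        )
        if too_close:
            logger.info("cluster of size %d skipped as same-area duplicate", c.size)
            continue
        picked.append(
            SeedRegion(
                name=f"reho_seed_{len(picked) + 1}",
                voxels=c.voxels,
                origin="reho_cluster",
                mask=mask,
            )
        )
        picked_centroids.append(centroid)
    if len(picked) < k:
        logger.warning("only %d of %d requested seeds available", len(picked), k)
    return picked


def mask_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Percentage of reference set ``b`` covered by ``a``: 100 |a&b| / |b|."""
    a = np.unique(np.asarray(a, dtype=np.int64))
    b = np.unique(np.asarray(b, dtype=np.int64))
    if b.size == 0:
        raise InputError("reference voxel set is empty")
    return 100.0 * np.intersect1d(a, b, assume_unique=True).size / b.size
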