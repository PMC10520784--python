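"""Synthetic two-group rs-fMRI cohorts with planted group differences.

Each subject's voxel series is AR(1) Gaussian noise plus, inside planted
spherical clusters, a subject-specific band-limited latent signal scaled
by a group-specific weight (elevated local synchrony = a ReHo effect),
and, inside planted remote regions, the latent of a seed cluster scaled
by a group-specific coupling (long-range connectivity = an FC effect).
Latents are sums of random-phase sinusoids drawn inside 0.01-0.08 Hz so
planted effects live in the analysis passband by construction.

Defaults emulate the structure of a two-site childhood-ADHD cohort:
172 timepoints at TR 2 s on a coarse grid, near-balanced groups with a
sex imbalance (more boys among patients), one planted ReHo cluster
present only in the patient group and one long-range link from it whose
coupling exists only in the patient group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from rehoseed.errors import SpecError
from rehoseed.groupstats import SubjectTable
from rehoseed.imgio import BrainMask, GridGeom, Volume4D, save_volume

PASSBAND_HZ = (0.01, 0.08)


@dataclass(frozen=True)
class PlantedCluster:
    """Sphere (voxel-index units) carrying a shared latent per group."""

    center: tuple[float, float, float]
    radius: float
    weight: dict  # group label -> latent amplitude (>= 0)


@dataclass(frozen=True)
class PlantedLink:
    """Remote sphere coupled to a planted cluster's latent, per group."""

    seed_cluster: int  # index into planted_reho_clusters
    remote_center: tuple[float, float, float]
    remote_radius: float
    coupling: dict  # group label -> coupling strength


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    shape: tuple[int, int, int] = (16, 16, 16)
    n_timepoints: int = 172
    tr_seconds: float = 2.0
    n_per_group: dict = field(default_factory=lambda: {"ADHD": 20, "control": 20})
    # sex imbalance mirroring F/M = 16/57 (patients) vs 34/42 (controls)
    female_fraction: dict = field(
        default_factory=lambda: {"ADHD": 16 / 73, "control": 34 / 76}
    )
    ar_coef: float = 0.3
    noise_sd: float = 1.0
    n_latent_sinusoids: int = 6
    # planted sphere sized like the largest discriminative ReHo clusters
    # reported for real childhood-ADHD cohorts (~130 voxels at 4 mm)
    planted_reho_clusters: tuple = (
        PlantedCluster(center=(5.0, 5.0, 5.0), radius=3.0,
                       weight={"ADHD": 1.0, "control": 0.0}),
    )
    planted_fc_links: tuple = (
        PlantedLink(seed_cluster=0, remote_center=(11.0, 11.0, 10.0),
                    remote_radius=1.5, coupling={"ADHD": 0.8, "control": 0.0}),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group.values()) or len(self.n_per_group) < 2:
            raise SpecError("both groups must be nonempty")
        for pc in self.planted_reho_clusters:
            if any(w < 0 for w in pc.weight.values()):
                raise SpecError("cluster weights must be >= 0")
            if not _inside_grid(pc.center, self.shape):
                raise SpecError(f"cluster center {pc.center} outside grid {self.shape}")
        for link in self.planted_fc_links:
            if not (0 <= link.seed_cluster < len(self.planted_reho_clusters)):
                raise SpecError(f"link references unknown cluster {link.seed_cluster}")
            if not _inside_grid(link.remote_center, self.shape):
                raise SpecError(f"remote center {link.remote_center} outside grid")


def _inside_grid(center, shape) -> bool:
    return all(0 <= c <= s - 1 for c, s in zip(center, shape))


def _sphere_indices(center, radius, mask: BrainMask) -> np.ndarray:
    """Mask-vector indices of voxels within radius (voxel units) of center."""
    d = np.linalg.norm(mask.ijk - np.asarray(center, dtype=float), axis=1)
    return np.flatnonzero(d <= radius)


def null_spec(**overrides) -> CohortSpec:
    """Cohort with the same structure but no group differences.

    Planted clusters keep equal weights/couplings across groups, so any
    detected seed is a false positive; used for calibration checks.
    """
    base = CohortSpec()
    clusters = tuple(
        PlantedCluster(pc.center, pc.radius, {g: 0.7 for g in pc.weight})
        for pc in base.planted_reho_clusters
    )
    links = tuple(
        PlantedLink(l.seed_cluster, l.remote_center, l.remote_radius,
                    {g: 0.4 for g in l.coupling})
        for l in base.planted_fc_links
    )
    kwargs = dict(planted_reho_clusters=clusters, planted_fc_links=links)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


@dataclass
class Cohort:
    """Generated cohort: volumes, mask, subject table and ground truth."""

    spec: CohortSpec
    mask: BrainMask
    table: SubjectTable
    volumes: dict  # subject_id -> Volume4D
    ground_truth: dict  # name -> mask-vector voxel indices

    def write(self, outdir: str | Path) -> None:
        """Write standard NIfTI volumes, the mask and the subject CSV."""
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nib.save(
            nib.Nifti1Image(self.mask.inside.astype(np.uint8), self.mask.geom.affine),
            str(outdir / "mask.nii.gz"),
        )
        rows = []
        for _, row in self.table.frame.iterrows():
            sid = row["subject_id"]
            path = outdir / f"{sid}.nii.gz"
            save_volume(self.volumes[sid], path)
            rows.append({**row.to_dict(), "path": str(path)})
        pd.DataFrame(rows).to_csv(outdir / "subjects.csv", index=False)
        for name, voxels in self.ground_truth.items():
            lab = np.zeros(self.mask.n_voxels, dtype=np.int16)
            lab[voxels] = 1
            vol = self.mask.vector_to_volume(lab)
            nib.save(
                nib.Nifti1Image(vol.astype(np.int16), self.mask.geom.affine),
                str(outdir / f"truth_{name}.nii.gz"),
            )

    def maps_for(self, values_by_subject: dict) -> np.ndarray:
        """Stack per-subject mask-vectors in subject-table order."""
        return np.stack([values_by_subject[s] for s in self.table.subject_ids])


def _band_limited_latent(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Unit-variance sum of random-phase sinusoids inside the passband."""
    t = np.arange(spec.n_timepoints) * spec.tr_seconds
    freqs = rng.uniform(*PASSBAND_HZ, size=spec.n_latent_sinusoids)
    phases = rng.uniform(0.0, 2 * np.pi, size=spec.n_latent_sinusoids)
    x = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar1_noise(rng: np.random.Generator, n_voxels: int, spec: CohortSpec) -> np.ndarray:
    """AR(1) noise with stationary marginal sd = noise_sd."""
    innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar_coef**2)
    e = rng.normal(0.0, innov_sd, size=(n_voxels, spec.n_timepoints))
    return signal.lfilter([1.0], [1.0, -spec.ar_coef], e, axis=1)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a deterministic synthetic cohort from a spec.

    The same spec (including its master seed) always yields byte-identical
    volumes. Planted spheres must not overlap one another.
    """
    shape = tuple(spec.shape)
    affine = np.diag([4.0, 4.0, 4.0, 1.0])
    affine[:3, 3] = -4.0 * (np.asarray(shape) - 1) / 2.0
    geom = GridGeom(shape, affine)
    mask = BrainMask(geom, np.ones(shape, dtype=bool))

    cluster_vox = [
        _sphere_indices(pc.center, pc.radius, mask) for pc in spec.planted_reho_clusters
    ]
    link_vox = [
        _sphere_indices(l.remote_center, l.remote_radius, mask)
        for l in spec.planted_fc_links
    ]
    all_sets = cluster_vox + link_vox
    for i in range(len(all_sets)):
        for j in range(i + 1, len(all_sets)):
            if np.intersect1d(all_sets[i], all_sets[j]).size:
                raise SpecError("planted regions overlap")

    groups = sorted(spec.n_per_group)
    ss = np.random.SeedSequence(spec.seed)
    sex_rng = np.random.default_rng(ss.spawn(1)[0])
    rows, order = [], []
    for group in groups:
        n = spec.n_per_group[group]
        n_f = int(round(spec.female_fraction.get(group, 0.5) * n))
        sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
        sex_rng.shuffle(sexes)
        for i in range(n):
            sid = f"{group.lower()}_{i + 1:03d}"
            rows.append({"subject_id": sid, "group": group, "sex": sexes[i]})
            order.append((sid, group))
    table = SubjectTable(pd.DataFrame(rows))

    volumes = {}
    for (sid, group), child in zip(order, ss.spawn(len(order))):
        rng = np.random.default_rng(child)
        data = _ar1_noise(rng, mask.n_voxels, spec)
        latents = [_band_limited_latent(rng, spec) for _ in spec.planted_reho_clusters]
        for pc, vox, latent in zip(spec.planted_reho_clusters, cluster_vox, latents):
            data[vox] += pc.weight.get(group, 0.0) * latent
        for link, vox in zip(spec.planted_fc_links, link_vox):
            data[vox] += link.coupling.get(group, 0.0) * latents[link.seed_cluster]
        volumes[sid] = Volume4D(geom=geom, mask=mask, data=data, tr_seconds=spec.tr_seconds)

    truth = {f"reho_{i}": vox for i, vox in enumerate(cluster_vox)}
    # the regional-homogeneity effect extends one voxel beyond the planted
    # sphere: any voxel whose 3x3x3 neighborhood overlaps the cluster has
    # genuinely elevated concordance, so the ReHo-effect region is the
    # planted set dilated by the neighborhood cube
    structure = np.ones((3, 3, 3), dtype=bool)
    for i, vox in enumerate(cluster_vox):
        binary = np.zeros(mask.n_voxels, dtype=bool)
        binary[vox] = True
        dilated = ndimage.binary_dilation(mask.vector_to_volume(binary), structure)
        truth[f"reho_{i}_effect"] = np.flatnonzero(dilated[mask.inside])
    truth.update({f"link_{i}_remote": vox for i, vox in enumerate(link_vox)})
    return Cohort(spec=spec, mask=mask, table=table, volumes=volumes, ground_truth=truth)
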