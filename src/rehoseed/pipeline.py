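"""End-to-end orchestration of the two-level seed-correlation pipeline.

Level 1: per-subject ReHo maps are compared between groups with
leave-one-out voted, covariate-adjusted t-tests; surviving clusters
become data-driven seeds. Level 2: each seed's whole-brain Fisher-z
connectivity maps are compared the same way, and the voted candidate
voxels become classifier features.

The pipeline runs in two validation modes. In "paper" mode seeds and
candidate voxels are derived once from the full sample and the classifier
alone is validated by random sampling. In "nested" mode seed derivation
and candidate voting are re-run inside every training split, so no
information from held-out subjects touches feature selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from rehoseed.classify import PCSearchSpec, ValidationReport, random_sampling_validate
from rehoseed.errors import InputError
from rehoseed.features import FeatureMatrix, build_features
from rehoseed.groupstats import (
    VOTE_THRESHOLD,
    ClusterSet,
    SubjectTable,
    cluster_components,
    glm_ttest,
    loo_vote,
    select_reho_seeds,
)
from rehoseed.imgio import BrainMask, Volume4D, bandpass, load_mask, load_subject, save_map
from rehoseed.reho import reho_map
from rehoseed.seedcorr import SeedRegion, fc_map, literature_seeds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the pipeline in one place."""

    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.08
    filter_order: int = 2
    neighborhood: int = 27
    # dividing each subject's map by its mean W is common for real cohorts,
    # but on small grids it leaks any focal group effect into the whole
    # background (the normalizing mean itself differs by group) — off by default
    normalize_reho: bool = False
    alpha: float = 0.01
    min_extent: int = 10
    connectivity: int = 6
    vote_threshold: float = VOTE_THRESHOLD
    cluster_filter_per_fold: bool = True
    n_seeds: int = 4
    dedup_radius_mm: float = 20.0
    families: tuple[str, ...] = ("ReHoFC",)
    literature_radius_mm: float = 6.0
    test_fraction: float = 0.25
    repeats: int = 10
    classifier: str = "lda"
    variance_lo: float = 0.50
    variance_hi: float = 0.90

    def pc_spec(self) -> PCSearchSpec:
        return PCSearchSpec(variance_lo=self.variance_lo, variance_hi=self.variance_hi)


class SeedCorrPipeline:
    """Holds a cohort's filtered volumes and derived per-subject maps."""

    def __init__(
        self,
        volumes: dict[str, Volume4D],
        mask: BrainMask,
        table: SubjectTable,
        config: PipelineConfig = PipelineConfig(),
        prefiltered: bool = False,
    ) -> None:
        self.config = config
        self.mask = mask
        self.table = table
        if prefiltered:
            self.volumes = dict(volumes)
        else:
            self.volumes = {
                sid: bandpass(
                    vol,
                    low_hz=config.bandpass_low_hz,
                    high_hz=config.bandpass_high_hz,
                    order=config.filter_order,
                )
                for sid, vol in volumes.items()
            }
        missing = set(table.subject_ids) - set(self.volumes)
        if missing:
            raise InputError(f"no volume for subjects {sorted(missing)}")
        self._reho: dict[str, np.ndarray] | None = None
        self._fc_cache: dict[tuple, dict[str, np.ndarray]] = {}

    # ---------------- per-subject maps ----------------

    def reho_maps(self) -> dict[str, np.ndarray]:
        """Per-subject ReHo mask-vectors (normalized if configured)."""
        if self._reho is None:
            self._reho = {}
            for sid in self.table.subject_ids:
                rm = reho_map(self.volumes[sid], neighborhood=self.config.neighborhood)
                if self.config.normalize_reho:
                    rm = rm.normalized()
                self._reho[sid] = rm.w
        return self._reho

    def fc_maps(self, seed: SeedRegion) -> dict[str, np.ndarray]:
        """Per-subject Fisher-z maps for one seed (cached by voxel set)."""
        key = (seed.name, seed.voxels.tobytes())
        if key not in self._fc_cache:
            self._fc_cache[key] = {
                sid: fc_map(self.volumes[sid], seed).z for sid in self.table.subject_ids
            }
        return self._fc_cache[key]

    def _stack(self, maps: dict[str, np.ndarray], table: SubjectTable) -> np.ndarray:
        return np.stack([maps[s] for s in table.subject_ids])

    # ---------------- level 1: seeds from ReHo ----------------

    def reho_candidates(self, train: SubjectTable) -> np.ndarray:
        """Voted candidate voxels of the ReHo family on given subjects."""
        cfg = self.config
        vm = loo_vote(
            self._stack(self.reho_maps(), train), train, self.mask,
            alpha=cfg.alpha, min_extent=cfg.min_extent,
            connectivity=cfg.connectivity, cluster_filter=cfg.cluster_filter_per_fold,
        )
        return vm.candidates(cfg.vote_threshold)

    def derive_seeds(self, train: SubjectTable) -> tuple[list[SeedRegion], ClusterSet]:
        """ReHo-discriminative clusters of the training subjects as seeds."""
        cfg = self.config
        cand = self.reho_candidates(train)
        binary = np.zeros(self.mask.n_voxels, dtype=bool)
        binary[cand] = True
        tmap = glm_ttest(self._stack(self.reho_maps(), train), train, self.mask)
        clusters = cluster_components(
            binary, self.mask, connectivity=cfg.connectivity,
            min_extent=cfg.min_extent, t_values=tmap.t,
        )
        if len(clusters) == 0:
            return [], clusters
        seeds = select_reho_seeds(clusters, k=cfg.n_seeds, dedup_radius_mm=cfg.dedup_radius_mm)
        return seeds, clusters

    # ---------------- level 2: candidate FC voxels ----------------

    def fc_candidates(self, seed: SeedRegion, train: SubjectTable) -> np.ndarray:
        cfg = self.config
        vm = loo_vote(
            self._stack(self.fc_maps(seed), train), train, self.mask,
            alpha=cfg.alpha, min_extent=cfg.min_extent,
            connectivity=cfg.connectivity, cluster_filter=cfg.cluster_filter_per_fold,
        )
        return vm.candidates(cfg.vote_threshold)

    # ---------------- feature assembly ----------------

    def _collect(self, train: SubjectTable):
        """Derive seeds/candidates from ``train`` for all configured families."""
        cfg = self.config
        subject_maps: dict[tuple[str, str], dict] = {}
        candidates: dict[tuple[str, str], np.ndarray] = {}
        if "ReHo" in cfg.families:
            subject_maps[("ReHo", "")] = self.reho_maps()
            candidates[("ReHo", "")] = self.reho_candidates(train)
        if "ReHoFC" in cfg.families:
            seeds, _ = self.derive_seeds(train)
            if not seeds:
                raise InputError("no ReHo seeds found on the training subjects")
            for seed in seeds:
                subject_maps[("ReHoFC", seed.name)] = self.fc_maps(seed)
                candidates[("ReHoFC", seed.name)] = self.fc_candidates(seed, train)
        if "LFC" in cfg.families:
            for seed in literature_seeds(self.mask, cfg.literature_radius_mm):
                subject_maps[("LFC", seed.name)] = self.fc_maps(seed)
                candidates[("LFC", seed.name)] = self.fc_candidates(seed, train)
        return subject_maps, candidates

    def features(self, train: SubjectTable | None = None) -> FeatureMatrix:
        """Feature matrix for all subjects, candidates derived from ``train``.

        With ``train=None`` candidates come from the full sample
        (paper-mode upstream derivation).
        """
        train = train or self.table
        subject_maps, candidates = self._collect(train)
        return build_features(
            subject_maps, candidates, self.table.subject_ids, self.config.families
        )

    def nested_builder(self):
        """Feature builder for nested-mode validation.

        Returns a callable mapping a training SubjectTable to
        ``(X_train, transform)``: seeds and candidates are derived from the
        training subjects only, then any subject list can be projected onto
        those candidate voxels.
        """

        def builder(train: SubjectTable):
            subject_maps, candidates = self._collect(train)
            fm = build_features(
                subject_maps, candidates, self.table.subject_ids, self.config.families
            )
            X_train = fm.rows(train.subject_ids)
            return X_train, fm.rows

        return builder

    # ---------------- validation ----------------

    def validate(self, mode: str = "nested", seed: int = 0) -> ValidationReport:
        cfg = self.config
        if mode == "paper":
            source = self.features()
        else:
            source = self.nested_builder()
        return random_sampling_validate(
            source, self.table,
            test_fraction=cfg.test_fraction, repeats=cfg.repeats, seed=seed,
            mode=mode, classifier=cfg.classifier, pc_spec=cfg.pc_spec(),
        )


def pipeline_from_cohort(cohort, config: PipelineConfig = PipelineConfig()) -> SeedCorrPipeline:
    """Build a pipeline straight from a synthetic Cohort object."""
    return SeedCorrPipeline(cohort.volumes, cohort.mask, cohort.table, config)


def run_pipeline(
    subject_csv: str | Path,
    mask_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    tr_seconds: float = 2.0,
    mode: str = "nested",
    seed: int = 0,
) -> ValidationReport:
    """File-based entry point: load a cohort, run the pipeline, write reports.

    ``subject_csv`` needs columns subject_id, group (ADHD|control),
    sex (F|M) and path (4D NIfTI per subject); ``mask_path`` is a 3D
    NIfTI on the same grid.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(subject_csv)
    if "path" not in df.columns:
        raise InputError("subject table needs a 'path' column")
    mask = load_mask(mask_path)
    table = SubjectTable(df[["subject_id", "group", "sex"]])
    volumes = {
        row["subject_id"]: load_subject(row["path"], mask, tr_seconds=tr_seconds)
        for _, row in df.iterrows()
    }
    # subjects may drop different bad voxels; intersect so all share one layout
    common = np.logical_and.reduce([v.mask.inside for v in volumes.values()])
    if common.sum() < mask.n_voxels:
        mask = BrainMask(mask.geom, common)
        paths = df.set_index("subject_id")["path"]
        volumes = {sid: load_subject(paths[sid], mask, tr_seconds) for sid in volumes}
    pipe = SeedCorrPipeline(volumes, mask, table, config)
    report = pipe.validate(mode=mode, seed=seed)
    (outdir / "validation_report.json").write_text(report.to_json())
    report.to_frame().to_csv(outdir / "validation_repeats.csv", index=False)

    reho_maps = pipe.reho_maps()
    qc = pd.DataFrame(
        [
            {"subject_id": sid, "mean_w": reho_maps[sid].mean(), "max_w": reho_maps[sid].max()}
            for sid in table.subject_ids
        ]
    )
    qc.to_csv(outdir / "reho_qc.csv", index=False)
    tmap = glm_ttest(np.stack([reho_maps[s] for s in table.subject_ids]), table, pipe.mask)
    save_map(tmap.t, pipe.mask, outdir / "reho_tmap.nii.gz")
    vm = loo_vote(
        np.stack([reho_maps[s] for s in table.subject_ids]), table, pipe.mask,
        alpha=config.alpha, min_extent=config.min_extent,
        connectivity=config.connectivity, cluster_filter=config.cluster_filter_per_fold,
    )
    save_map(vm.vote_fraction, pipe.mask, outdir / "reho_votes.nii.gz")
    seeds, clusters = pipe.derive_seeds(table)
    clusters.to_frame().to_csv(outdir / "reho_clusters.csv", index=False)
    for s in seeds:
        s.save(outdir / f"{s.name}.nii.gz")
    logger.info(
        "mean accuracy %.3f (SE %.3f / SP %.3f) over %d repeats",
        report.mean_accuracy, report.mean_sensitivity,
        report.mean_specificity, len(report.repeats),
    )
    return report
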