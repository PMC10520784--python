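"""Per-subject feature vectors over candidate voxels.

Three feature families: ReHo (Kendall's W at candidate voxels), LFC
(Fisher z from literature spherical seeds) and ReHoFC (Fisher z from
data-driven ReHo-cluster seeds). Families can be combined by column
concatenation; columns follow a fixed lexicographic (family, seed,
voxel) order so dimensionality reduction is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rehoseed.errors import InputError

FAMILIES = ("LFC", "ReHo", "ReHoFC")


@dataclass
class FeatureMatrix:
    """Subjects x candidate-voxel values with a column manifest.

    ``columns`` holds (family, seed_name, voxel_index) per column; the
    ReHo family has no seed and uses the empty string.
    """

    values: np.ndarray
    subject_ids: list
    columns: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("feature values must be 2D (subjects, features)")
        if self.values.shape != (len(self.subject_ids), len(self.columns)):
            raise InputError(
                f"shape {self.values.shape} != ({len(self.subject_ids)}, {len(self.columns)})"
            )
        if not np.isfinite(self.values).all():
            raise InputError("feature matrix contains missing values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def rows(self, subject_ids: list) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.subject_ids)}
        return self.values[[index[s] for s in subject_ids]]

    def save(self, path: str | Path) -> None:
        """Persist as CSV plus a JSON column manifest."""
        names = [f"{fam}|{seed}|{vox}" for fam, seed, vox in self.columns]
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=names)
        df.index.name = "subject_id"
        df.to_csv(path)
        manifest = [{"family": f, "seed": s, "voxel": int(v)} for f, s, v in self.columns]
        Path(str(path) + ".manifest.json").write_text(json.dumps(manifest))


def build_features(
    subject_maps: dict[tuple[str, str], dict],
    candidates: dict[tuple[str, str], np.ndarray],
    subject_ids: list,
    families: tuple[str, ...],
) -> FeatureMatrix:
    """Assemble the feature matrix for the requested families.

    ``subject_maps[(family, seed_name)]`` maps subject_id -> mask-vector
    of per-voxel values (W or Fisher z); ``candidates`` holds the
    candidate voxel indices per (family, seed). Columns are ordered
    lexicographically by (family, seed_name, voxel index).
    """
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise InputError(f"unknown feature families {sorted(unknown)}")
    keys = sorted(k for k in candidates if k[0] in families)
    for fam in families:
        fam_keys = [k for k in keys if k[0] == fam]
        if not fam_keys or all(len(candidates[k]) == 0 for k in fam_keys):
            raise InputError(f"no candidate voxels for requested family {fam!r}")
    columns: list[tuple[str, str, int]] = []
    blocks: list[np.ndarray] = []
    for key in keys:
        fam, seed_name = key
        vox = np.sort(np.asarray(candidates[key], dtype=np.int64))
        if vox.size == 0:
            continue
        maps = subject_maps[key]
        block = np.stack([np.asarray(maps[s])[vox] for s in subject_ids])
        blocks.append(block)
        columns.extend((fam, seed_name, int(v)) for v in vox)
    return FeatureMatrix(
        values=np.hstack(blocks), subject_ids=list(subject_ids), columns=columns
    )
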