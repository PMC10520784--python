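"""Seed-based functional connectivity: Fisher-z correlation maps.

Builds a seed from the planted cluster's ground-truth voxels, extracts its
mean reference time course, and correlates it with every in-mask voxel
(Pearson r, then z = arctanh r). In patients the remote coupled region
shows clearly positive z; in controls it does not.
"""

import numpy as np

from rehoseed import CohortSpec, bandpass, fc_map, generate_cohort
from rehoseed.seedcorr import SeedRegion

cohort = generate_cohort(CohortSpec(seed=7))
seed = SeedRegion(
    name="planted_cluster",
    voxels=cohort.ground_truth["reho_0"],
    origin="reho_cluster",
    mask=cohort.mask,
)
remote = cohort.ground_truth["link_0_remote"]

for group in ("adhd", "control"):
    sids = [s for s in cohort.table.subject_ids if s.startswith(group)]
    z_remote = []
    z_background = []
    for sid in sids:
        fm = fc_map(bandpass(cohort.volumes[sid]), seed)
        z_remote.append(fm.z[remote].mean())
        z_background.append(np.delete(fm.z, np.concatenate([remote, seed.voxels])).mean())
    print(f"{group:8s}: mean z at remote region = {np.mean(z_remote):+.3f}, "
          f"background mean z = {np.mean(z_background):+.3f}")

# Expected: remote z ~ +0.5 for patients (coupling 0.8 against unit noise),
# ~0 for controls; background stays near 0 for both.
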