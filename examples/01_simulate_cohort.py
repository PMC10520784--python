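"""Simulate a two-group resting-state cohort with planted effects.

Generates 20 patients and 20 controls on a 16x16x16 grid (172 timepoints,
TR 2 s). One spherical cluster carries a shared band-limited latent signal
only in the patient group (a regional-homogeneity effect), and a remote
region is coupled to that cluster's latent only in patients (a long-range
connectivity effect). The volumes are written as ordinary NIfTI files plus
a subject CSV, i.e. the exact input contract of the analysis pipeline.
"""

from rehoseed import CohortSpec, generate_cohort

spec = CohortSpec(seed=7)
cohort = generate_cohort(spec)
cohort.write("scratch/example_cohort")

frame = cohort.table.frame
print(f"subjects: {cohort.table.n_subjects} "
      f"({(frame.group == 'ADHD').sum()} ADHD / {(frame.group == 'control').sum()} control)")
print(f"sex by group:\n{frame.groupby(['group', 'sex']).size()}")
print(f"grid: {cohort.mask.geom.shape}, {cohort.mask.n_voxels} in-mask voxels")
for name, vox in cohort.ground_truth.items():
    print(f"ground truth {name}: {vox.size} voxels")

# The planted ReHo cluster (123 voxels) is where local synchrony differs by
# group; the "effect" set adds the one-voxel halo whose neighborhoods
# overlap it; the remote set is where seed coupling differs.
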