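import numpy as np
import pandas as pd
import pytest

from rehoseed.errors import DesignError, InputError
from rehoseed.groupstats import (
    SubjectTable,
    VoteMap,
    cluster_components,
    glm_ttest,
    loo_vote,
    mask_overlap,
    select_reho_seeds,
)
from rehoseed.imgio import BrainMask, GridGeom

from _oracles import flood_fill_components, pooled_two_sample_t


def _table(groups, sexes=None):
    n = len(groups)
    sexes = sexes or ["M"] * n
    return SubjectTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": groups,
                "sex": sexes,
            }
        )
    )


def _mask(shape=(6, 6, 6), vox=4.0):
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = -vox * (np.asarray(shape) - 1) / 2.0
    return BrainMask(GridGeom(shape, affine), np.ones(shape, bool))


class TestGlmTtest:
    def test_identical_groups_give_zero_t(self, rng):
        vals = rng.normal(size=(1, 30))
        maps = np.vstack([vals] * 10)
        table = _table(["ADHD"] * 5 + ["control"] * 5, ["F", "M"] * 5)
        res = glm_ttest(maps, table)
        np.testing.assert_allclose(res.t, 0.0, atol=1e-10)
        np.testing.assert_allclose(res.p, 1.0, atol=1e-10)

    def test_no_covariate_matches_pooled_t_oracle(self, rng):
        maps = rng.normal(size=(20, 50))
        table = _table(["control"] * 10 + ["ADHD"] * 10)
        res = glm_ttest(maps, table, covariates=())
        assert res.dof == 18
        for v in range(50):
            expected = pooled_two_sample_t(maps[:10, v], maps[10:, v])
            assert res.t[v] == pytest.approx(expected, abs=1e-8)

    def test_inert_balanced_covariate_matches_pooled_t_up_to_dof(self, rng):
        """With sex balanced and carrying no effect, the adjusted t equals
        the pooled t rescaled by sqrt((n-3)/(n-2)) — the only difference
        left is the residual degrees of freedom."""
        n_pairs = 10
        pair_vals = rng.normal(size=(2 * n_pairs, 40))
        maps = np.repeat(pair_vals, 2, axis=0)  # F/M twin pairs, identical values
        groups = ["control"] * (2 * n_pairs) + ["ADHD"] * (2 * n_pairs)
        sexes = ["F", "M"] * (2 * n_pairs)
        table = _table(groups, sexes)
        res = glm_ttest(maps, table, covariates=("sex",))
        n = 4 * n_pairs
        assert res.dof == n - 3
        scale = np.sqrt((n - 3) / (n - 2))
        for v in range(40):
            expected = pooled_two_sample_t(maps[: 2 * n_pairs, v], maps[2 * n_pairs :, v])
            assert res.t[v] == pytest.approx(expected * scale, abs=1e-8)

    def test_shift_gives_positive_t(self, rng):
        maps = rng.normal(size=(16, 5))
        maps[8:, 2] += 5.0  # ADHD shifted up at voxel 2
        table = _table(["control"] * 8 + ["ADHD"] * 8, ["F", "M"] * 8)
        res = glm_ttest(maps, table)
        assert res.t[2] > 3.0
        assert res.p[2] < 0.01

    def test_confounded_design_rejected(self, rng):
        maps = rng.normal(size=(8, 3))
        table = _table(["control"] * 4 + ["ADHD"] * 4, ["M"] * 4 + ["F"] * 4)
        with pytest.raises(DesignError):
            glm_ttest(maps, table)  # sex perfectly confounded with group


class TestClusterComponents:
    def test_isolated_voxel_removed(self):
        mask = _mask((6, 6, 6))
        binary = np.zeros(216, bool)
        binary[0] = True
        assert len(cluster_components(binary, mask, min_extent=10)) == 0

    def test_ten_voxel_slab_survives(self):
        # "more than 10 voxels" is read as >= 10
        mask = _mask((6, 6, 6))
        vol = np.zeros((6, 6, 6), bool)
        vol[1:3, 0:5, 2] = True  # 2x5x1 face-connected slab
        binary = vol[mask.inside]
        cs = cluster_components(binary, mask, connectivity=6, min_extent=10)
        assert cs.sizes() == [10]

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        mask = _mask((12, 12, 12))
        vol = rng.random((12, 12, 12)) < 0.3
        binary = vol[mask.inside]
        cs = cluster_components(binary, mask, connectivity=connectivity, min_extent=1)
        got = {frozenset(map(tuple, mask.ijk[c.voxels])) for c in cs.clusters}
        expected = {frozenset(c) for c in flood_fill_components(vol, connectivity)}
        assert got == expected

    def test_partitions_suprathreshold_set(self, rng):
        mask = _mask((10, 10, 10))
        binary = rng.random(1000) < 0.25
        cs = cluster_components(binary, mask, min_extent=1)
        covered = np.concatenate([c.voxels for c in cs.clusters]) if len(cs) else []
        assert sorted(covered) == sorted(np.flatnonzero(binary))

    def test_sorted_by_size_and_peak_sign(self, rng):
        mask = _mask((8, 8, 8))
        vol = np.zeros((8, 8, 8), bool)
        vol[0:2, 0:3, 0] = True  # 6 voxels
        vol[5:8, 5:8, 5:7] = True  # 18 voxels
        binary = vol[mask.inside]
        t_values = -np.ones(512)
        cs = cluster_components(binary, mask, min_extent=1, t_values=t_values)
        assert cs.sizes() == [18, 6]
        assert all(c.sign == -1 for c in cs.clusters)


class TestLooVote:
    def test_strong_effect_voxels_get_full_votes(self, rng):
        mask = _mask((6, 6, 6))
        vol = np.zeros((6, 6, 6), bool)
        vol[1:3, 0:5, 2] = True
        effect = vol[mask.inside]
        maps = rng.normal(size=(14, 216))
        maps[7:, effect] += 6.0
        table = _table(["control"] * 7 + ["ADHD"] * 7, ["F", "M"] * 7)
        vm = loo_vote(maps, table, mask)
        assert vm.n_maps == 14
        assert (vm.vote_fraction[effect] == 1.0).all()
        assert set(np.flatnonzero(effect)) <= set(vm.candidates())

    def test_vote_counts_are_integers(self, rng):
        mask = _mask((5, 5, 5))
        maps = rng.normal(size=(9, 125))
        table = _table(["control"] * 5 + ["ADHD"] * 4, ["F", "M", "F", "M", "F"] + ["M"] * 4)
        vm = loo_vote(maps, table, mask, cluster_filter=False)
        counts = vm.vote_fraction * vm.n_maps
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_vote_fraction_permutation_invariant(self, rng):
        mask = _mask((5, 5, 5))
        maps = rng.normal(size=(10, 125))
        maps[5:, :20] += 2.0
        table = _table(["control"] * 5 + ["ADHD"] * 5, ["F", "M"] * 5)
        vm1 = loo_vote(maps, table, mask, cluster_filter=False)
        perm = rng.permutation(10)
        vm2 = loo_vote(maps[perm], table.subset(perm), mask, cluster_filter=False)
        np.testing.assert_array_equal(vm1.vote_fraction, vm2.vote_fraction)

    def test_folds_emptying_a_group_are_skipped(self, rng):
        mask = _mask((4, 4, 4))
        maps = rng.normal(size=(7, 64))
        table = _table(["ADHD"] * 2 + ["control"] * 5,
                       ["F", "M", "F", "M", "F", "M", "M"])
        vm = loo_vote(maps, table, mask, cluster_filter=False)
        # removing either ADHD subject leaves a singleton group -> skipped
        assert vm.n_maps == 5

    def test_candidate_threshold_is_strictly_above_33_percent(self):
        mask = _mask((5, 5, 5))
        frac = np.zeros(125)
        frac[0] = 33 / 100.0  # exactly 33% of votes: excluded
        frac[1] = 34 / 100.0  # 34%: included
        frac[2] = 1.0
        vm = VoteMap(geom=mask.geom, mask=mask, vote_fraction=frac, n_maps=100)
        cand = vm.candidates()
        assert 0 not in cand and 1 in cand and 2 in cand


class TestSelectRehoSeeds:
    @staticmethod
    def _cluster_set(mask, centers_mm, sizes):
        from rehoseed.groupstats import Cluster, ClusterSet

        world = mask.geom.voxel_to_world(mask.ijk)
        clusters, used = [], np.zeros(mask.n_voxels, bool)
        for c_mm, size in zip(centers_mm, sizes):
            d = np.linalg.norm(world - np.asarray(c_mm, float), axis=1)
            d[used] = np.inf
            vox = np.argsort(d)[:size]
            used[vox] = True
            clusters.append(Cluster(voxels=np.sort(vox), size=size, peak_voxel=int(vox[0]), sign=1))
        clusters.sort(key=lambda c: -c.size)
        return ClusterSet(mask=mask, clusters=clusters)

    def test_contralateral_homolog_not_repeated(self):
        # five clusters sorted by size; the 47-voxel one mirrors the
        # 89-voxel one across the midline and must be skipped
        mask = _mask((35, 35, 35))
        centers = [(32, 64, -10), (52, 0, -18), (24, 4, -2), (-4, -32, 66), (-32, -4, -2)]
        sizes = [130, 90, 89, 53, 47]
        cs = self._cluster_set(mask, centers, sizes)
        seeds = select_reho_seeds(cs, k=4, dedup_radius_mm=20.0)
        assert [s.size for s in seeds] == [130, 90, 89, 53]

    def test_single_cluster_returned(self):
        mask = _mask((10, 10, 10))
        cs = self._cluster_set(mask, [(0, 0, 0)], [12])
        seeds = select_reho_seeds(cs, k=4)
        assert len(seeds) == 1 and seeds[0].size == 12

    def test_fewer_than_k_distant_clusters_all_returned(self):
        mask = _mask((16, 16, 16))
        cs = self._cluster_set(mask, [(-20, -20, -20), (20, 20, 20)], [15, 11])
        seeds = select_reho_seeds(cs, k=4, dedup_radius_mm=20.0)
        assert [s.size for s in seeds] == [15, 11]

    def test_empty_cluster_set_rejected(self):
        from rehoseed.groupstats import ClusterSet

        with pytest.raises(InputError):
            select_reho_seeds(ClusterSet(mask=_mask((4, 4, 4)), clusters=[]))


class TestMaskOverlap:
    def test_identical_sets_full_overlap(self):
        a = np.arange(40)
        assert mask_overlap(a, a) == pytest.approx(100.0)

    def test_disjoint_sets_no_overlap(self):
        assert mask_overlap(np.arange(10), np.arange(10, 20)) == pytest.approx(0.0)

    def test_partial_coverage_fraction_of_reference(self):
        b = np.arange(40)
        a = np.arange(10)  # 10 of b's 40 voxels
        assert mask_overlap(a, b) == pytest.approx(25.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(InputError):
            mask_overlap(np.arange(3), np.array([]))
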