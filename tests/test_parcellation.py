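import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from twdfc import (
    Parcellation,
    TWdFCMap,
    VolumeGrid,
    WindowSpec,
    build_features,
    concatenate_maps,
    decompose,
    kmeans_parcellate,
    merge_bilateral,
    threshold_zmaps,
)
from twdfc.parcellation import ComponentSet, FeatureMatrix


def _map_from(data, grid):
    return TWdFCMap(data=data, grid=grid, spec=WindowSpec(width=2))


class TestConcatenate:
    def test_frames_stack_and_columns_centre(self, grid8, rng):
        d1 = rng.normal(size=(8, 8, 8, 6))
        d2 = rng.normal(size=(8, 8, 8, 6))
        d1[5:, :, :, :] = np.nan  # untraversed region
        d2[5:, :, :, :] = np.nan
        maps = [_map_from(d1, grid8), _map_from(d2, grid8)]
        data, vox, slices = concatenate_maps(maps)
        assert data.shape == (12, vox.shape[0])
        for sl in slices:
            np.testing.assert_allclose(data[sl].mean(axis=0), 0.0, atol=1e-10)

    def test_voxel_nan_everywhere_excluded_from_mask(self, grid8, rng):
        d = rng.normal(size=(8, 8, 8, 4))
        d[0, 0, 0, :] = np.nan
        data, vox, _ = concatenate_maps([_map_from(d, grid8)])
        assert [0, 0, 0] not in vox.tolist()

    def test_grid_mismatch_rejected(self, grid8, rng):
        other = VolumeGrid.isotropic((8, 8, 8), 3.0)
        m1 = _map_from(rng.normal(size=(8, 8, 8, 2)), grid8)
        m2 = _map_from(rng.normal(size=(8, 8, 8, 2)), other)
        with pytest.raises(ValueError, match="grid"):
            concatenate_maps([m1, m2])


class TestDecompose:
    def _mixture(self, rng, n_voxels=500, n_frames=60):
        """Exact noiseless mixture of 3 sparse zero-mean spatial patterns on
        disjoint supports (mutually uncorrelated, strongly non-Gaussian)."""
        patterns = np.zeros((3, n_voxels))
        for i in range(3):
            patterns[i, i::3] = rng.normal(0, 1, size=len(range(i, n_voxels, 3)))
        mixing = rng.normal(size=(n_frames, 3))
        return mixing @ patterns, patterns

    def test_recovers_planted_spatial_patterns(self, rng):
        data, patterns = self._mixture(rng)
        c = decompose(data, n_components=3, seed=0)
        # match greedily up to sign and permutation
        used = set()
        for p in patterns:
            cors = [
                abs(np.corrcoef(p, m)[0, 1]) if i not in used else -1
                for i, m in enumerate(c.spatial_maps)
            ]
            best = int(np.argmax(cors))
            assert cors[best] > 0.99
            used.add(best)

    def test_auto_mode_stops_at_data_rank(self, rng):
        data, _ = self._mixture(rng)
        c = decompose(data, n_components="auto", var_threshold=0.98, seed=0)
        assert c.n_components == 3
        assert c.variance_explained > 0.999

    def test_determinism_given_seed(self, rng):
        data, _ = self._mixture(rng)
        c1 = decompose(data, n_components=3, seed=5)
        c2 = decompose(data, n_components=3, seed=5)
        np.testing.assert_array_equal(c1.spatial_maps, c2.spatial_maps)

    def test_reconstruction_consistency(self, rng):
        # low-rank structure with sparse (non-Gaussian, hence identifiable)
        # sources plus weak noise: the mixing-matrix column space must
        # capture at least the variance fraction the PCA step reports
        patterns = np.zeros((8, 400))
        for i in range(8):
            patterns[i, i::8] = rng.normal(0, 1, size=50)
        data = rng.normal(size=(40, 8)) @ patterns
        data += 0.05 * rng.normal(size=data.shape)
        data -= data.mean(axis=0)
        c = decompose(data, n_components=8, seed=0)
        from numpy.linalg import lstsq

        coef, *_ = lstsq(c.mixing, data, rcond=None)
        resid = data - c.mixing @ coef
        captured = 1 - resid.var() / data.var()
        assert captured >= c.variance_explained - 1e-6


class TestThreshold:
    def _cs(self, maps):
        return ComponentSet(
            spatial_maps=np.atleast_2d(maps),
            mixing=np.zeros((2, len(np.atleast_2d(maps)))),
            variance_explained=1.0,
            analysis_voxels=np.empty((0, 3), int),
            grid=VolumeGrid.isotropic((1, 1, 1)),
        )

    def test_pure_noise_mostly_zeroed_by_mixture_mode(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=5000)
        out = threshold_zmaps(self._cs(z), mode="mixture")
        assert (out == 0).mean() >= 0.95

    def test_shifted_population_kept_by_mixture_mode(self):
        rng = np.random.default_rng(1)
        z = np.concatenate([rng.normal(0, 1, 4000), rng.normal(6, 1, 1000)])
        out = threshold_zmaps(self._cs(z), mode="mixture")[0]
        assert (out[4000:] != 0).mean() > 0.99

    def test_zabs_mode_keeps_values_above_cut(self):
        z = np.array([1.0, 2.0, -3.0])
        out = threshold_zmaps(self._cs(z), mode="zabs", z_cut=1.645)[0]
        np.testing.assert_array_equal(out, [0.0, 2.0, -3.0])


class TestFeatures:
    def test_rows_follow_seed_voxels_and_lookup(self, grid8, rng):
        vox = np.argwhere(np.ones((8, 8, 8), bool))
        thr = rng.normal(size=(3, len(vox)))
        seed = np.zeros((8, 8, 8), bool)
        seed[1:3, 1:3, 1] = True
        f = build_features(thr, vox, seed)
        assert f.features.shape == (4, 3)
        lut = {tuple(v): i for i, v in enumerate(vox)}
        for r, v in enumerate(f.voxels):
            np.testing.assert_array_equal(f.features[r], thr[:, lut[tuple(v)]])

    def test_seed_voxel_outside_analysis_gets_zero_row(self, grid8, rng):
        vox = np.argwhere(np.zeros((8, 8, 8), bool) | (np.arange(8)[:, None, None] < 4))
        thr = rng.normal(size=(2, len(vox)))
        seed = np.zeros((8, 8, 8), bool)
        seed[3:5, 0, 0] = True  # voxel (4,0,0) outside analysis half
        with pytest.warns(UserWarning, match="outside"):
            f = build_features(thr, vox, seed)
        assert f.n_outside_analysis == 1
        assert np.all(f.features[-1] == 0)


class TestKMeans:
    def test_separated_blobs_split_perfectly(self, grid8, rng):
        n = 40
        X = np.vstack([rng.normal(0, 0.1, (n, 3)), rng.normal(5, 0.1, (n, 3))])
        vox = np.argwhere(np.ones((8, 8, 8), bool))[: 2 * n]
        f = FeatureMatrix(features=X, voxels=vox)
        p = kmeans_parcellate(f, k=2, grid=grid8, seed=0)
        labels = [p.labels[tuple(v)] for v in vox]
        truth = [0] * n + [1] * n
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_rows_rejected(self, grid8):
        f = FeatureMatrix(features=np.ones((10, 2)), voxels=np.argwhere(np.ones((8, 8, 8), bool))[:10])
        with pytest.raises(ValueError, match="distinct"):
            kmeans_parcellate(f, k=2, grid=grid8)

    def test_same_seed_reproduces_labels(self, grid8, rng):
        X = rng.normal(size=(60, 4))
        vox = np.argwhere(np.ones((8, 8, 8), bool))[:60]
        f = FeatureMatrix(features=X, voxels=vox)
        p1 = kmeans_parcellate(f, k=3, grid=grid8, seed=9)
        p2 = kmeans_parcellate(f, k=3, grid=grid8, seed=9)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_labels_ordered_by_descending_size(self, grid8, rng):
        X = np.vstack([rng.normal(0, 0.1, (50, 2)), rng.normal(8, 0.1, (10, 2))])
        vox = np.argwhere(np.ones((8, 8, 8), bool))[:60]
        p = kmeans_parcellate(FeatureMatrix(features=X, voxels=vox), k=2, grid=grid8, seed=0)
        sizes = np.bincount(p.labels[p.labels > 0])
        assert sizes[1] >= sizes[2]


class TestMergeBilateral:
    def _parc(self, centroids, grid):
        k = len(centroids)
        return Parcellation(
            labels=np.zeros(grid.dims, dtype=np.int32),
            k=k,
            grid=grid,
            centroids=np.asarray(centroids, dtype=float),
        )

    def test_mirror_symmetric_clusters_pair_exactly(self, grid8):
        lefts = [(-10.0, y, 0.0) for y in (8.0, 0.0, -8.0)]
        rights = [(10.0, y, 0.0) for y in (0.0, -8.0, 8.0)]
        p = self._parc(lefts + rights, grid8)
        m = merge_bilateral(p, midline_x=0.0)
        assert sorted(set(m.bilateral_map.values())) == ["A", "B", "C"]
        # anterior-most pair (y=8): clusters 1 (left) and 6 (right) -> A
        assert m.bilateral_map[1] == m.bilateral_map[6] == "A"
        assert m.bilateral_map[2] == m.bilateral_map[4] == "B"
        assert m.bilateral_map[3] == m.bilateral_map[5] == "C"

    def test_override_mapping_applied_verbatim(self, grid8):
        p = self._parc([(0.0, 0.0, 0.0)] * 6, grid8)
        override = {1: "A", 4: "A", 2: "B", 6: "B", 3: "C", 5: "C"}
        m = merge_bilateral(p, override=override)
        assert m.bilateral_map == override
        assert len(m.merged_ids()) == 3

    def test_jittered_mirrors_keep_pairing(self, grid8, rng):
        lefts = [(-10.0, y, 2.0) for y in (8.0, 0.0, -8.0)]
        rights = [(10.0 + rng.normal(0, 1), y + rng.normal(0, 1), 2.0) for y in (8.0, 0.0, -8.0)]
        p = self._parc(lefts + rights, grid8)
        m = merge_bilateral(p)
        for i in range(3):
            assert m.bilateral_map[i + 1] == m.bilateral_map[i + 4]

    def test_unequal_sides_require_override(self, grid8):
        p = self._parc([(-10, 0, 0), (-10, 5, 0), (10, 0, 0)], grid8)
        with pytest.raises(ValueError, match="override"):
            merge_bilateral(p)
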