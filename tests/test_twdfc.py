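import numpy as np
import pytest

from twdfc import (
    BoldSeries,
    Tractogram,
    VolumeGrid,
    WindowSpec,
    compute_twdfc,
    endpoint_series,
    hamming_taper,
    project_twdfc,
    rasterize_streamline,
    windowed_corr,
)
from twdfc.grid import voxel_centers
from twdfc.seed import EndpointTable


class TestHammingTaper:
    def test_closed_form_small_windows(self):
        np.testing.assert_allclose(hamming_taper(3), [0.08, 1.0, 0.08], atol=1e-15)
        np.testing.assert_allclose(hamming_taper(2), [0.08, 0.08], atol=1e-15)

    def test_window_85_peaks_at_centre(self):
        w = hamming_taper(85)
        assert np.argmax(w) == 42
        assert abs(w[42] - 1.0) < 1e-6
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)  # symmetric

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hamming_taper(1)


class TestWindowedCorr:
    def test_identical_series_give_unity(self):
        x = np.sin(np.arange(40) * 0.3)
        r, ndeg = windowed_corr(x, x, WindowSpec(10, 5, "hamming"))
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        assert ndeg == 0

    def test_anticorrelated_series_give_minus_one(self):
        x = np.sin(np.arange(40) * 0.3)
        r, _ = windowed_corr(x, -x, WindowSpec(10, 5))
        np.testing.assert_allclose(r, -1.0, atol=1e-12)

    def test_constant_window_counts_as_degenerate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        x[:10] = 4.2  # first window flat
        y = rng.normal(size=30)
        r, ndeg = windowed_corr(x, y, WindowSpec(10, 10))
        assert r[0] == 0.0 and ndeg == 1

    def test_rectangular_taper_matches_plain_pearson_oracle(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=(2, 40))
        spec = WindowSpec(10, 5, "rectangular")
        r, _ = windowed_corr(x, y, spec)
        for k in range(spec.n_windows(40)):
            t0 = k * 5
            expected = np.corrcoef(x[t0 : t0 + 10], y[t0 : t0 + 10])[0, 1]
            assert abs(r[k] - expected) < 1e-12

    def test_window_count_formula(self):
        assert WindowSpec(85, 1).n_windows(300) == 216
        assert WindowSpec(10, 5).n_windows(40) == 7

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 2**20),
        a=st.floats(0.05, 20.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_invariant_to_positive_affine_rescaling(self, seed, a, b):
        """Pearson correlation (windowed, tapered) is invariant under
        y -> a*y + b for a > 0."""
        rng_ = np.random.default_rng(seed)
        x, y = rng_.normal(size=(2, 36))
        spec = WindowSpec(12, 6, "hamming")
        r1, _ = windowed_corr(x, y, spec)
        r2, _ = windowed_corr(x, a * y + b, spec)
        np.testing.assert_allclose(r1, r2, atol=1e-9)


class TestRasterize:
    def test_axis_aligned_segment_crosses_expected_voxels(self, grid8):
        # from centre of (1,2,2) to centre of (5,2,2): exactly voxels 1..5 in x
        a = voxel_centers([(1, 2, 2)], grid8)[0]
        b = voxel_centers([(5, 2, 2)], grid8)[0]
        vox = rasterize_streamline(np.array([a, b]), grid8)
        expected = {(i, 2, 2) for i in range(1, 6)}
        assert {tuple(v) for v in vox} == expected

    def test_streamline_inside_one_voxel(self, grid8):
        c = voxel_centers([(3, 3, 3)], grid8)[0]
        vox = rasterize_streamline(np.array([c - 0.3, c + 0.3]), grid8)
        assert [tuple(v) for v in vox] == [(3, 3, 3)]

    def test_halving_step_leaves_straight_segment_set_unchanged(self, grid8):
        # a gently sloped segment that does not graze voxel corners: the
        # default 1 mm sampling already catches every traversed voxel
        a = voxel_centers([(0, 1, 2)], grid8)[0] + np.array([0.3, 0.1, 0.0])
        b = voxel_centers([(7, 2, 3)], grid8)[0]
        s = np.array([a, b])
        v1 = {tuple(v) for v in rasterize_streamline(s, grid8, step_mm=1.0)}
        v2 = {tuple(v) for v in rasterize_streamline(s, grid8, step_mm=0.5)}
        assert v1 == v2

    def test_endpoint_voxels_always_included(self, grid8):
        a = voxel_centers([(0, 0, 0)], grid8)[0]
        b = voxel_centers([(7, 7, 7)], grid8)[0]
        vox = {tuple(v) for v in rasterize_streamline(np.array([a, b]), grid8, step_mm=50.0)}
        assert (0, 0, 0) in vox and (7, 7, 7) in vox


class TestProjection:
    def test_two_streamlines_average_in_shared_voxel(self, grid8):
        dyn = np.array([[0.8, 0.2], [0.4, -0.2]])
        shared = np.array([[3, 3, 3]])
        vsets = [shared, shared]
        m = project_twdfc(dyn, vsets, grid8)
        np.testing.assert_allclose(m.data[3, 3, 3], [0.6, 0.0], atol=1e-15)

    def test_single_streamline_voxels_copy_its_weighting(self, grid8):
        dyn = np.array([[0.5, -0.5, 0.1]])
        vset = [np.array([[0, 0, 0], [1, 1, 1]])]
        m = project_twdfc(dyn, vset, grid8)
        np.testing.assert_array_equal(m.data[0, 0, 0], dyn[0])
        np.testing.assert_array_equal(m.data[1, 1, 1], dyn[0])
        assert np.isnan(m.data[5, 5, 5]).all()

    def test_weighted_average_uses_streamline_weights(self, grid8):
        dyn = np.array([[1.0], [0.0]])
        shared = np.array([[2, 2, 2]])
        m = project_twdfc(
            dyn, [shared, shared], grid8,
            streamline_weights=np.array([3.0, 1.0]), use_weights=True,
        )
        np.testing.assert_allclose(m.data[2, 2, 2], [0.75])
        with pytest.raises(ValueError, match="weights"):
            project_twdfc(dyn, [shared, shared], grid8, use_weights=True)

    def test_random_projection_matches_accumulate_oracle(self, grid8, rng):
        n, N = 20, 4
        dyn = rng.uniform(-1, 1, (n, N))
        vsets = [
            np.unique(rng.integers(0, 8, (rng.integers(1, 10), 3)), axis=0)
            for _ in range(n)
        ]
        m = project_twdfc(dyn, vsets, grid8)
        acc = np.zeros((8, 8, 8, N))
        cnt = np.zeros((8, 8, 8))
        for s in range(n):
            for v in vsets[s]:
                acc[tuple(v)] += dyn[s]
                cnt[tuple(v)] += 1
        expected = np.where(cnt[..., None] > 0, acc / np.maximum(cnt, 1)[..., None], np.nan)
        np.testing.assert_allclose(m.data, expected, atol=1e-12)

    def test_permutation_of_streamlines_is_bit_identical(self, grid8, rng):
        n, N = 15, 3
        dyn = rng.uniform(-1, 1, (n, N))
        vsets = [rng.integers(0, 8, (5, 3)) for _ in range(n)]
        vsets = [np.unique(v, axis=0) for v in vsets]
        m1 = project_twdfc(dyn, vsets, grid8)
        perm = rng.permutation(n)
        m2 = project_twdfc(dyn[perm], [vsets[i] for i in perm], grid8)
        np.testing.assert_array_equal(m1.data, m2.data)


class TestComputeTwdfc:
    def _setup(self, rng, T=120, n_streamlines=6, dims=(8, 8, 8)):
        grid = VolumeGrid.isotropic(dims, 2.0)
        bold = BoldSeries(rng.normal(size=(*dims, T)), 0.72, grid)
        sls, seed_vox, distal_vox = [], [], []
        for s in range(n_streamlines):
            a = rng.integers(0, dims[0], 3)
            b = rng.integers(0, dims[0], 3)
            pa = voxel_centers([a], grid)[0]
            pb = voxel_centers([b], grid)[0]
            if np.all(a == b):
                b = (a + 1) % dims[0]
                pb = voxel_centers([b], grid)[0]
            sls.append(np.linspace(pa, pb, 8).astype(np.float32))
            seed_vox.append(a)
            distal_vox.append(b)
        t = Tractogram(streamlines=sls)
        tab = EndpointTable(
            streamline_id=np.arange(n_streamlines),
            seed_voxel=np.array(seed_vox),
            distal_voxel=np.array(distal_vox),
            weight=np.ones(n_streamlines),
        )
        return bold, t, tab

    def test_frame_count_is_T_minus_W_plus_one(self, rng):
        bold, t, tab = self._setup(rng, T=120)
        m = compute_twdfc(bold, t, tab, spec=WindowSpec(85, 1))
        assert m.n_windows == 120 - 85 + 1

    def test_endpoint_series_match_direct_indexing(self, rng):
        bold, t, tab = self._setup(rng)
        s, d, flagged = endpoint_series(bold, tab)
        for row in range(len(tab)):
            np.testing.assert_array_equal(s[row], bold.data[tuple(tab.seed_voxel[row])])
            np.testing.assert_array_equal(d[row], bold.data[tuple(tab.distal_voxel[row])])
        assert not flagged.any()

    def test_identical_endpoint_series_give_unit_map(self, rng):
        bold, t, tab = self._setup(rng, n_streamlines=2)
        for row in range(2):
            bold.data[tuple(tab.distal_voxel[row])] = bold.data[tuple(tab.seed_voxel[row])]
        m = compute_twdfc(bold, t, tab, spec=WindowSpec(40, 10))
        finite = np.isfinite(m.data)
        np.testing.assert_allclose(m.data[finite], 1.0, atol=1e-12)

    def test_full_map_equals_triple_loop_brute_force(self, rng):
        """Oracle equivalence: python-loop weighted-Pearson projection."""
        bold, t, tab = self._setup(rng, T=60, n_streamlines=12)
        spec = WindowSpec(20, 7, "hamming")
        m = compute_twdfc(bold, t, tab, spec=spec)

        from twdfc.twdfc_map import rasterize_streamline as rasterize

        w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(20) / 19)
        w = w / w.sum()
        N = spec.n_windows(60)
        vsets = [rasterize(s, bold.grid) for s in t.streamlines]
        acc = {}
        for s in range(12):
            xs = bold.data[tuple(tab.seed_voxel[s])]
            ys = bold.data[tuple(tab.distal_voxel[s])]
            fc = np.zeros(N)
            for k in range(N):
                a = xs[k * 7 : k * 7 + 20]
                b = ys[k * 7 : k * 7 + 20]
                ma = float(np.sum(w * a)); mb = float(np.sum(w * b))
                va = float(np.sum(w * (a - ma) ** 2)); vb = float(np.sum(w * (b - mb) ** 2))
                cov = float(np.sum(w * (a - ma) * (b - mb)))
                fc[k] = 0.0 if min(va, vb) < 1e-12 else cov / np.sqrt(va * vb)
            for v in vsets[s]:
                acc.setdefault(tuple(v), []).append(fc)
        for v, fcs in acc.items():
            expected = np.mean(fcs, axis=0)
            np.testing.assert_allclose(m.data[v], expected, atol=1e-12)
        n_traversed = int(np.any(np.isfinite(m.data), axis=3).sum())
        assert n_traversed == len(acc)
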