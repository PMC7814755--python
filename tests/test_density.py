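import numpy as np
import pytest

from paintract.bundles import Tractogram
from paintract.density import (ImageGrid, ProbabilityMap, Warp, density_map,
                               directional_density, group_probability, indicator,
                               retention_filter, tract_mask, warp_tensor_field)


@pytest.fixture(scope="module")
def grid():
    return ImageGrid.isotropic(shape=(40, 40, 40), voxel_size=1.5)


@pytest.fixture(scope="module")
def random_tract():
    rng = np.random.default_rng(11)
    lines = []
    for _ in range(50):
        n = rng.integers(2, 10)
        start = rng.uniform(10, 45, 3)
        pts = np.vstack([start, start + np.cumsum(rng.normal(0, 2.0, (n - 1, 3)), axis=0)])
        lines.append(np.clip(pts, 5, 52))
    return Tractogram(lines)


class TestScalarDensity:
    def test_straight_10mm_mass(self, grid):
        t = Tractogram([np.array([[20.0, 20, 20], [30.0, 20, 20]])])
        d = density_map(t, grid)
        assert d.values.sum() == pytest.approx(10.0, abs=1e-6)

    def test_mass_conservation_random(self, grid, random_tract):
        d = density_map(random_tract, grid)
        total = random_tract.total_length()
        assert abs(d.values.sum() - total) / total < 1e-6

    def test_voxel_center_line_confined(self, grid):
        # a streamline exactly on a line of voxel centers deposits only there
        t = Tractogram([np.array([[15.0, 30.0, 30.0], [45.0, 30.0, 30.0]])])
        d = density_map(t, grid)
        support = np.argwhere(d.values > 1e-12)
        assert set(support[:, 1]) == {20} and set(support[:, 2]) == {20}

    def test_outside_grid_clipped_with_warning(self, grid):
        t = Tractogram([np.array([[-30.0, 0, 0], [-20.0, 0, 0]])])
        with pytest.warns(UserWarning, match="clipped"):
            d = density_map(t, grid)
        assert d.values.sum() == 0.0


class TestIndicator:
    def test_closed_threshold_boundary(self, grid):
        d = density_map(Tractogram([np.array([[20.0, 20, 20], [30.0, 20, 20]])]), grid)
        d.values[:] = 0.0
        d.values[5, 5, 5] = 1.0
        ind = indicator(d, cutoff=1.0)
        assert ind[5, 5, 5] == 1 and ind.sum() == 1

    def test_zero_map_and_zero_cutoff(self, grid):
        d = density_map(Tractogram([]), grid)
        assert indicator(d).sum() == 0
        d.values[1, 2, 3] = 0.25
        assert indicator(d, cutoff=0.0).sum() == 1


class TestGroupProbability:
    def test_counting(self, grid):
        maps = [np.zeros((4, 4, 4), dtype=np.uint8) for _ in range(4)]
        for m in maps[:3]:
            m[1, 1, 1] = 1
        maps[0][2, 2, 2] = 1
        p = group_probability(maps, ImageGrid.isotropic(shape=(4, 4, 4)))
        assert p.values[1, 1, 1] == pytest.approx(0.75)
        assert p.values[2, 2, 2] == pytest.approx(0.25)

    def test_matches_stacked_mean_oracle(self):
        rng = np.random.default_rng(0)
        maps = [(rng.random((6, 6, 6)) > 0.5).astype(np.uint8) for _ in range(9)]
        p = group_probability(maps, ImageGrid.isotropic(shape=(6, 6, 6)))
        np.testing.assert_array_equal(p.values, np.stack(maps).mean(axis=0))
        # values are multiples of 1/n
        np.testing.assert_allclose((p.values * 9) % 1.0, 0.0, atol=1e-12)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            group_probability([np.zeros((4, 4, 4)), np.zeros((5, 5, 5))])


class TestDirectionalDensity:
    def test_straight_bundle_principal_axis(self, grid):
        t = Tractogram([np.array([[15.0, 30.0 + dy, 30.0], [45.0, 30.0 + dy, 30.0]])
                        for dy in (-1.0, 0.0, 1.0)])
        f = directional_density(t, grid)
        tr = f.trace()
        vox = np.unravel_index(np.argmax(tr), tr.shape)
        w, v = np.linalg.eigh(f.tensors[vox])
        assert abs(v[:, -1] @ np.array([1.0, 0, 0])) >= 0.999

    def test_trace_equals_scalar_density(self, grid, random_tract):
        f = directional_density(random_tract, grid)
        d = density_map(random_tract, grid)
        np.testing.assert_allclose(f.trace(), d.values, atol=1e-6)

    def test_orthogonal_crossing_equal_eigenvalues(self, grid):
        t = Tractogram([np.array([[15.0, 30.0, 30.0], [45.0, 30.0, 30.0]]),
                        np.array([[30.0, 15.0, 30.0], [30.0, 45.0, 30.0]])])
        f = directional_density(t, grid)
        vox = (20, 20, 20)  # world (30, 30, 30), the crossing voxel
        w = np.linalg.eigvalsh(f.tensors[vox])
        assert w[-1] > 0 and abs(w[-1] - w[-2]) / w[-1] < 0.05


class TestWarp:
    def test_identity_noop_bitexact(self, grid, random_tract):
        f = directional_density(random_tract, grid)
        out = warp_tensor_field(f, Warp.identity(grid))
        assert np.array_equal(out.tensors, f.tensors)

    def test_rotation_90deg_reorients(self, grid):
        t = Tractogram([np.array([[15.0, 30.0, 30.0], [45.0, 30.0, 30.0]])])
        f = directional_density(t, grid)
        R = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        c = np.array([29.25, 29.25, 29.25])  # grid center, keeps the map inside
        w = Warp.from_linear(grid, R.T, offset=c - R.T @ c)  # pull-back uses inverse
        out = warp_tensor_field(f, w, mode="rotation")
        tr = out.trace()
        assert tr.max() > 0
        vox = np.unravel_index(np.argmax(tr), tr.shape)
        _, v = np.linalg.eigh(out.tensors[vox])
        assert abs(v[:, -1] @ np.array([0.0, 1.0, 0.0])) >= 0.999

    def test_anisotropic_scaling_preserves_ratios_in_rotation_mode(self, grid,
                                                                   random_tract):
        f = directional_density(random_tract, grid)
        S = np.diag([1.25, 1.0, 0.9])
        c = np.array([29.25] * 3)
        w = Warp.from_linear(grid, S, offset=c - S @ c)
        out = warp_tensor_field(f, w, mode="rotation")
        tr_out = out.trace()
        vox = np.unravel_index(np.argmax(tr_out), tr_out.shape)
        # polar rotation factor of a pure scaling is the identity: sampled
        # tensors keep their eigenvalue ratios
        y = (np.array(vox) * 1.5) @ S.T + (c - S @ c)
        from paintract.density import _trilinear_gather_tensors
        ref = _trilinear_gather_tensors(f, y[None, :])[0]
        np.testing.assert_allclose(out.tensors[vox], ref, atol=1e-10)

    def test_full_mode_scales_eigenvalues(self, grid, random_tract):
        f = directional_density(random_tract, grid)
        S = np.diag([2.0, 1.0, 1.0])
        c = np.array([29.25] * 3)
        w = Warp.from_linear(grid, S, offset=c - S @ c)
        rot = warp_tensor_field(f, w, mode="rotation")
        full = warp_tensor_field(f, w, mode="full")
        assert not np.allclose(rot.tensors, full.tensors)


class TestMaskAndRetention:
    def make_prob(self, values):
        g = ImageGrid.isotropic(shape=values.shape)
        return ProbabilityMap(grid=g, values=values)

    def test_lower_limit_and_upper_limit(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0] = 0.9
        vals[1, 1, 1] = 0.8
        vals[2, 2, 2] = 0.5
        m = tract_mask(self.make_prob(vals), 0.8)
        assert m.values.sum() == 2 and m.upper_limit == pytest.approx(0.9)

    def test_zero_limit_gives_support(self):
        vals = np.zeros((4, 4, 4))
        vals[1, 2, 3] = 0.2
        m = tract_mask(self.make_prob(vals), 0.0)
        assert m.values.sum() == 4 * 4 * 4  # p >= 0 everywhere

    def test_unreachable_limit_warns_empty(self):
        vals = np.full((3, 3, 3), 0.5)
        with pytest.warns(UserWarning, match="empty"):
            m = tract_mask(self.make_prob(vals), 1.0)
        assert m.values.sum() == 0

    @pytest.mark.parametrize("maxp,thr,keep", [(0.85, 0.40, True),
                                               (0.25, 0.40, False),
                                               (0.10, 0.0, True)])
    def test_retention_rule(self, maxp, thr, keep):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0] = maxp
        assert retention_filter(self.make_prob(vals), thr) is keep
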