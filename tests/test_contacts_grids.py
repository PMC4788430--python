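import numpy as np
import pytest

from tailensemble.structanalysis import (DensityGrid, SASAParams, contact_ratio,
                                         density_difference, density_grid,
                                         exposure_ratio, pair_distances,
                                         per_position_contact)
from tailensemble.structanalysis.contacts import weighted_contact_fraction


@pytest.fixture
def toy_frames():
    """5 frames, 4 beads: bead 0 is 'terminal', beads 2-3 are 'dna'."""
    frames = np.zeros((5, 4, 3))
    frames[:, 1] = [0.0, 8.0, 0.0]
    frames[:, 2] = [50.0, 0.0, 0.0]
    frames[:, 3] = [50.0, 8.0, 0.0]
    # frames 0-2: bead 0 in contact with bead 2; frames 3-4 far away
    for f in range(3):
        frames[f, 0] = [46.0, 0.0, 0.0]
    for f in (3, 4):
        frames[f, 0] = [0.0, 0.0, 0.0]
    return frames


RADII = np.array([2.0, 2.0, 2.0, 2.0])


class TestPerPositionContact:
    def test_always_far_zero(self):
        frames = np.zeros((3, 2, 3))
        frames[:, 0] = [0.0, 0, 0]
        frames[:, 1] = [200.0, 0, 0]
        w = np.full(3, 1 / 3)
        p = per_position_contact(frames, w, np.array([0]), [np.array([1])],
                                 np.array([2.0, 2.0]))
        assert np.allclose(p, 0.0)

    def test_permanent_contact_one(self):
        frames = np.zeros((4, 2, 3))
        frames[:, 1] = [4.0, 0, 0]
        w = np.full(4, 0.25)
        p = per_position_contact(frames, w, np.array([0]), [np.array([1])],
                                 np.array([2.0, 2.0]))
        assert np.allclose(p, 1.0)

    def test_brute_force_oracle(self, toy_frames, rng):
        weights = rng.random(5)
        weights /= weights.sum()
        tail = np.array([0, 1])
        groups = [np.array([2]), np.array([3])]
        pad = 2.8
        result = per_position_contact(toy_frames, weights, tail, groups, RADII, pad)
        # brute force recount
        for g, group in enumerate(groups):
            expected = 0.0
            for f in range(5):
                hit = False
                for i in tail:
                    for j in group:
                        d = np.linalg.norm(toy_frames[f, i] - toy_frames[f, j])
                        if d <= RADII[i] + RADII[j] + pad:
                            hit = True
                if hit:
                    expected += weights[f]
            assert result[g] == pytest.approx(expected, rel=1e-12)

    def test_empty_group_rejected(self, toy_frames):
        with pytest.raises(ValueError, match="empty"):
            per_position_contact(toy_frames, np.full(5, 0.2), np.array([0]),
                                 [np.array([], dtype=int)], RADII)


class TestContactRatio:
    def test_always_far_zero(self):
        frames = np.zeros((3, 2, 3))
        frames[:, 0] = [0.0, 0, 0]
        frames[:, 1] = [300.0, 0, 0]
        r = contact_ratio(frames, np.full(3, 1 / 3), 0, np.array([1]),
                          np.array([2.0, 2.0]), SASAParams(n_sphere_points=240))
        assert r == 0.0

    def test_wedged_every_frame_one(self):
        frames = np.zeros((3, 2, 3))
        frames[:, 1] = [4.0, 0.0, 0.0]  # touching
        r = contact_ratio(frames, np.full(3, 1 / 3), 0, np.array([1]),
                          np.array([2.0, 2.0]), SASAParams(n_sphere_points=240))
        assert r == 1.0

    def test_matches_per_frame_recount(self, toy_frames, rng):
        from tailensemble.structanalysis import sasa

        weights = rng.random(5)
        weights /= weights.sum()
        params = SASAParams(n_sphere_points=240)
        dna = np.array([2, 3])
        context = np.array([0, 1])
        got = contact_ratio(toy_frames, weights, 0, dna, RADII, params,
                            context_idx=context)
        expected_flags = []
        for f in range(5):
            a_without = sasa(toy_frames[f, context], RADII[context], params,
                             compute_indices=np.array([0]))[0]
            ctx_with = np.concatenate([context, dna])
            a_with = sasa(toy_frames[f, ctx_with], RADII[ctx_with], params,
                          compute_indices=np.array([0]))[0]
            expected_flags.append((a_without - a_with) > 0.1)
        expected = float(np.sum(weights * np.array(expected_flags)))
        assert got == pytest.approx(expected, rel=1e-12)


class TestExposureRatio:
    def test_isolated_matches_reference(self):
        frames = np.zeros((2, 1, 3))
        params = SASAParams(n_sphere_points=960)
        ref_area = 4 * np.pi * (2.0 + 1.4) ** 2
        ratio, flagged = exposure_ratio(frames, np.full(2, 0.5), 0,
                                        np.array([2.0]), ref_area, params)
        assert ratio == pytest.approx(1.0, rel=1e-6)
        assert not flagged

    def test_fully_buried_zero(self):
        frames = np.zeros((2, 2, 3))
        frames[:, 0] = [0.1, 0.0, 0.0]
        radii = np.array([0.5, 6.0])
        ratio, _ = exposure_ratio(frames, np.full(2, 0.5), 0, radii,
                                  reference_area=4 * np.pi * (0.5 + 1.4) ** 2,
                                  params=SASAParams(n_sphere_points=240))
        assert ratio == 0.0

    def test_half_buried_two_sphere_closed_form(self):
        d = 4.0
        r_exp = 2.0 + 1.4
        frames = np.zeros((1, 2, 3))
        frames[0, 1] = [d, 0.0, 0.0]
        params = SASAParams(n_sphere_points=3840)
        iso = 4 * np.pi * r_exp ** 2
        h = r_exp - d / 2.0
        expected = (iso - 2 * np.pi * r_exp * h) / iso
        ratio, _ = exposure_ratio(frames, np.array([1.0]), 0,
                                  np.array([2.0, 2.0]), iso, params)
        assert ratio == pytest.approx(expected, rel=0.005)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            exposure_ratio(np.zeros((1, 1, 3)), np.array([1.0]), 0,
                           np.array([2.0]), reference_area=0.0)


class TestPairDistances:
    def test_static_sites(self):
        frames = np.zeros((3, 2, 3))
        frames[:, 1] = [10.0, 0, 0]
        d = pair_distances(frames, [(0, 1)])
        assert np.allclose(d, 10.0)

    def test_equal_weight_mean(self):
        frames = np.zeros((2, 2, 3))
        frames[0, 1] = [8.0, 0, 0]
        frames[1, 1] = [12.0, 0, 0]
        d = pair_distances(frames, [(0, 1)])
        w = np.array([0.5, 0.5])
        assert float((w * d[:, 0]).sum()) == pytest.approx(10.0)

    def test_brute_force_oracle(self, toy_frames):
        pairs = [(0, 2), (1, 3)]
        d = pair_distances(toy_frames, pairs)
        for f in range(5):
            for k, (i, j) in enumerate(pairs):
                assert d[f, k] == pytest.approx(
                    np.linalg.norm(toy_frames[f, i] - toy_frames[f, j]))

    def test_out_of_range_site(self, toy_frames):
        with pytest.raises(ValueError):
            pair_distances(toy_frames, [(0, 99)])


class TestDensityGrid:
    def test_single_atom_at_origin(self):
        frames = np.zeros((1, 1, 3)) + 0.5
        grid = density_grid(frames, np.array([1.0]), np.array([0]),
                            origin=(0, 0, 0), spacing=1.0, shape=(2, 2, 2))
        assert grid.counts[0, 0, 0] == 1.0
        assert grid.total == 1.0

    def test_linearity_in_weights(self, toy_frames):
        w = np.full(5, 0.2)
        kwargs = dict(sel_idx=np.array([0, 1]), origin=(-10, -10, -10),
                      spacing=2.0, shape=(40, 20, 20))
        g1 = density_grid(toy_frames, w, **kwargs)
        g2 = density_grid(toy_frames, 2 * w, **kwargs)
        assert np.allclose(g2.counts, 2 * g1.counts)

    def test_total_equals_brute_force(self):
        rng = np.random.default_rng(7)
        frames = rng.uniform(0, 10, size=(3, 4, 3))
        w = np.array([0.2, 0.3, 0.5])
        sel = np.array([1, 2])
        grid = density_grid(frames, w, sel, origin=(0, 0, 0), spacing=1.0,
                            shape=(10, 10, 10))
        expected = sum(w[f] * len(sel) for f in range(3))
        assert grid.total + grid.overflow == pytest.approx(expected)

    def test_overflow_warned(self):
        frames = np.zeros((1, 1, 3)) + 100.0
        with pytest.warns(UserWarning, match="outside"):
            grid = density_grid(frames, np.array([1.0]), np.array([0]),
                                origin=(0, 0, 0), spacing=1.0, shape=(2, 2, 2))
        assert grid.overflow == 1.0
        assert grid.total == 0.0

    def test_alignment_recenters_frames(self, rng):
        base = rng.standard_normal((6, 3)) * 5
        theta = 0.8
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = (rot @ base.T).T + np.array([3.0, -1.0, 2.0])
        frames = np.stack([base, moved])
        grid_aligned = density_grid(
            frames, np.array([0.5, 0.5]), np.array([0]),
            origin=(-20, -20, -20), spacing=0.5, shape=(80, 80, 80),
            alignment=(base, np.arange(6)))
        # both frames fall in the same voxel after alignment
        assert np.max(grid_aligned.counts) == pytest.approx(1.0)


class TestDensityDifference:
    def _grid(self, counts):
        return DensityGrid(origin=np.zeros(3), spacing=1.0, counts=np.asarray(counts, float))

    def test_self_difference_zero(self):
        g = self._grid(np.arange(8.0).reshape(2, 2, 2) + 1)
        d = density_difference(g, g)
        assert np.allclose(d.counts, 0.0)

    def test_difference_sums_to_zero(self):
        rng = np.random.default_rng(3)
        a = self._grid(rng.random((3, 3, 3)))
        b = self._grid(rng.random((3, 3, 3)))
        d = density_difference(a, b)
        assert d.counts.sum() == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a = self._grid(rng.random((2, 2, 2)))
        b = self._grid(rng.random((2, 2, 2)))
        assert np.allclose(density_difference(a, b).counts,
                           -density_difference(b, a).counts)

    def test_shape_mismatch_rejected(self):
        a = self._grid(np.ones((2, 2, 2)))
        b = self._grid(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            density_difference(a, b)

    def test_text_roundtrip(self):
        g = self._grid(np.arange(8.0).reshape(2, 2, 2))
        back = DensityGrid.from_text(g.to_text())
        assert np.allclose(back.counts, g.counts)
        assert back.spacing == g.spacing
        assert np.allclose(back.origin, g.origin)


class TestWeightedContactFraction:
    def test_plain_fraction(self):
        flags = np.array([1, 0, 1, 0])
        w = np.full(4, 0.25)
        assert weighted_contact_fraction(flags, w) == pytest.approx(0.5)
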