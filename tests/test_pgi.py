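"""Region growing, layer rings, potential growth index, and the closing ANOVA."""

import numpy as np
import pytest
from scipy import ndimage, stats

from wmh_morph import pgi
from wmh_morph import synthetic_fixtures as synth


def exhaustive_growth_oracle(mask, intensity, gmax, gmin, gamma):
    """Independent oracle: all qualifying voxels 8-connected to the boundary
    through qualifying voxels, found by labeling rather than BFS."""
    qualifying = (~mask) & (gmax - intensity < gamma * (gmax - gmin))
    labels, n = ndimage.label(qualifying, structure=np.ones((3, 3), dtype=bool))
    seeds = pgi.boundary_seeds(mask)
    seed_mask = np.zeros_like(mask)
    seed_mask[seeds[:, 0], seeds[:, 1]] = True
    touching = ndimage.binary_dilation(seed_mask, structure=np.ones((3, 3), dtype=bool))
    keep = set(np.unique(labels[touching & qualifying])) - {0}
    return np.isin(labels, sorted(keep)) & qualifying


class TestBoundarySeeds:
    def test_single_voxel_is_its_own_boundary(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert [tuple(v) for v in pgi.boundary_seeds(mask)] == [(2, 2)]

    def test_three_by_three_square_has_eight_perimeter_voxels(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        seeds = {tuple(v) for v in pgi.boundary_seeds(mask)}
        assert len(seeds) == 8 and (3, 3) not in seeds

    def test_thin_line_is_all_boundary(self):
        mask = np.zeros((5, 8), dtype=bool)
        mask[2, 1:7] = True
        assert len(pgi.boundary_seeds(mask)) == 6

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            pgi.boundary_seeds(np.zeros((3, 3), dtype=bool))


class TestRegionGrow:
    def test_gamma_zero_grows_nothing(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        grown = pgi.region_grow(mask, np.full((6, 6), 100.0), 100.0, 50.0, gamma=0.0)
        assert grown.n_voxels == 0

    def test_threshold_rule_accepts_and_rejects(self):
        # gMax 100, gMin 50, gamma 1.02 -> threshold 51: f=60 accepted, f=40 not
        mask = np.zeros((3, 5), dtype=bool)
        mask[1, 2] = True
        intensity = np.zeros((3, 5))
        intensity[1, 1] = 60.0  # 100 - 60 = 40 < 51
        intensity[1, 3] = 40.0  # 100 - 40 = 60 >= 51
        grown = pgi.region_grow(mask, intensity, 100.0, 50.0, gamma=1.02)
        assert grown.region[1, 1] and not grown.region[1, 3]

    def test_dark_background_grows_nothing(self):
        mask = synth.make_shape("disc", 10)
        mask = np.pad(mask, 5)
        intensity = np.where(mask, 100.0, 10.0)
        grown = pgi.region_grow(mask, intensity, 100.0, 60.0, gamma=1.02)
        assert grown.n_voxels == 0

    def test_negative_gamma_rejected(self):
        mask = np.ones((2, 2), dtype=bool)
        with pytest.raises(ValueError):
            pgi.region_grow(mask, np.ones((2, 2)), 1.0, 0.0, gamma=-0.1)

    def test_forbidden_voxels_never_grow(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 1] = True
        other = np.zeros((5, 5), dtype=bool)
        other[2, 3] = True
        intensity = np.full((5, 5), 100.0)
        grown = pgi.region_grow(mask, intensity, 100.0, 50.0, forbidden=other)
        assert not grown.region[2, 3]
        assert not (grown.region & mask).any()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((24, 24), dtype=bool)
        mask[8:14, 9:15] = synth.make_shape("disc", 6)
        intensity = rng.uniform(0.0, 120.0, size=(24, 24))
        gmax, gmin, gamma = 110.0, 60.0, 1.02
        grown = pgi.region_grow(mask, intensity, gmax, gmin, gamma=gamma)
        oracle = exhaustive_growth_oracle(mask, intensity, gmax, gmin, gamma)
        assert np.array_equal(grown.region, oracle)

    def test_monotone_in_gamma(self, rng):
        mask = np.pad(synth.make_shape("disc", 12), 8)
        intensity = synth.make_intensity(mask, edge_width=4, noise_sd=3.0, rng=7)
        prev = np.zeros_like(mask)
        for gamma in (0.0, 0.5, 0.9, 1.02, 1.3):
            grown = pgi.region_grow(mask, intensity, 115.0, 80.0, gamma=gamma)
            assert (prev <= grown.region).all()  # superset as gamma relaxes
            prev = grown.region


class TestLayers:
    def test_single_voxel_diamond_rings(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        layers = pgi.generate_layers(mask, 3)
        assert layers.sizes == [4, 8, 12]

    def test_layers_disjoint_from_mask_and_each_other(self):
        mask = np.pad(synth.make_shape("blob", 12, seed=3), 6)
        layers = pgi.generate_layers(mask, 3)
        combined = mask.copy()
        for ring in layers.layers:
            assert not (ring & combined).any()
            combined |= ring

    def test_mask_touching_edge_is_clipped(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        layers = pgi.generate_layers(mask, 2)
        assert layers.sizes == [2, 3]


class TestWeightsAndIndex:
    def test_layer_weights_values(self):
        assert np.allclose(pgi.layer_weights(1), [1.0])
        assert np.allclose(pgi.layer_weights(3), [1 / 6, 2 / 6, 3 / 6])
        for n in range(1, 12):
            assert pgi.layer_weights(n).sum() == pytest.approx(1.0)
            assert np.all(np.diff(pgi.layer_weights(n)) > 0)

    def test_empty_region_gives_zero(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        region = pgi.GrowthRegion(np.zeros((7, 7), dtype=bool), 1.02)
        assert pgi.compute_pgi(region, pgi.generate_layers(mask, 3)).p_g == 0.0

    def test_full_single_layer_gives_one(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        layers = pgi.generate_layers(mask, 1)
        region = pgi.GrowthRegion(layers.layers[0].copy(), 1.02)
        assert pgi.compute_pgi(region, layers).p_g == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # GV = (4, 0, 0), |E| = (4, 8, 12) -> P_g = (4/6)/24
        mask = np.zeros((11, 11), dtype=bool)
        mask[5, 5] = True
        layers = pgi.generate_layers(mask, 3)
        region = pgi.GrowthRegion(layers.layers[0].copy(), 1.02)
        result = pgi.compute_pgi(region, layers)
        assert np.array_equal(result.growth_per_layer, [4, 0, 0])
        assert result.p_g == pytest.approx((4 * (1 / 6)) / 24)
        assert result.p_g == pytest.approx(0.0278, abs=5e-4)

    def test_mask_filling_image_rejected(self):
        mask = np.ones((4, 4), dtype=bool)
        region = pgi.GrowthRegion(np.zeros((4, 4), dtype=bool), 1.02)
        with pytest.raises(ValueError):
            pgi.compute_pgi(region, pgi.generate_layers(mask, 2))

    @pytest.mark.parametrize("seed", range(10))
    def test_pgi_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.pad(synth.make_shape("blob", 14, seed=seed), 8)
        intensity = rng.uniform(0.0, 130.0, size=mask.shape)
        result = pgi.pgi_for_lesion(mask, intensity, 120.0, 70.0)
        assert 0.0 <= result.p_g <= 1.0

    def test_capped_growth_matches_uncapped_on_typical_fixture(self):
        mask = np.pad(synth.make_shape("disc", 14), 10)
        intensity = synth.make_intensity(mask, edge_width=4, noise_sd=3.0, rng=11)
        full = pgi.region_grow(mask, intensity, 115.0, 80.0)
        capped = pgi.region_grow(mask, intensity, 115.0, 80.0, max_rings=3)
        layers = pgi.generate_layers(mask, 3)
        assert pgi.compute_pgi(full, layers).p_g == pytest.approx(
            pgi.compute_pgi(capped, layers).p_g
        )


class TestEdgeSteepness:
    def test_shallow_ramps_grow_more_than_step_edges(self):
        mask = np.pad(synth.make_shape("disc", 16), 10)
        p_g = {}
        for w in (0, 2, 4, 6):
            # same noise field across widths isolates the ramp effect
            intensity = synth.make_intensity(mask, edge_width=w, noise_sd=3.0, rng=13)
            despiked_gmax = float(intensity[mask].max())
            despiked_gmin = float(intensity[mask].min())
            p_g[w] = pgi.pgi_for_lesion(mask, intensity, despiked_gmax, despiked_gmin).p_g
        assert p_g[6] > p_g[0]  # strictly higher for the shallow ramp
        values = [p_g[w] for w in (0, 2, 4, 6)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        values = np.tile([0.1, 0.2, 0.3], 2)
        labels = np.repeat([0, 1], 3)
        res = pgi.anova_pgi_by_cluster(values, labels)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_near_separated_groups_large_finite_f(self):
        res = pgi.anova_pgi_by_cluster([0.0, 0.01, 1.0, 1.01], [0, 0, 1, 1])
        assert np.isfinite(res.f) and res.f > 100
        assert res.p < 0.01

    def test_matches_textbook_formula(self, rng):
        groups = [rng.normal(loc, 1.0, size=12) for loc in (0.0, 0.4, 1.0)]
        values = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], 12)
        res = pgi.anova_pgi_by_cluster(values, labels)
        # textbook one-way ANOVA computed from sums of squares
        grand = values.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ss_between / 2) / (ss_within / (36 - 3))
        assert res.f == pytest.approx(f)
        assert res.p == pytest.approx(stats.f.sf(f, 2, 33))

    def test_table_mirrors_group_summaries(self, rng):
        values = rng.uniform(0.0, 0.3, size=30)
        labels = np.repeat([0, 1, 2], 10)
        res = pgi.anova_pgi_by_cluster(values, labels)
        assert list(res.table["n"]) == [10, 10, 10]
        assert res.table["pgi_mean"].iloc[0] == pytest.approx(values[:10].mean())

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            pgi.anova_pgi_by_cluster([0.1, 0.2, 0.3], [0, 0, 1])

    def test_planted_shift_detected(self):
        # 1-SD group shift at n = 100/group: significant in nearly all seeds
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            values = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
            labels = np.repeat([0, 1], 100)
            hits += pgi.anova_pgi_by_cluster(values, labels).p < 0.05
        assert hits >= 38  # >= 95% of seeds
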