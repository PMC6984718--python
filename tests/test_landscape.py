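"""Synthetic landscape generator: determinism, structure, conservation."""

import numpy as np
import pytest
from scipy import stats

from maupscale import (
    GridSpec,
    SpeciesProfile,
    generate_population,
    generate_predictors,
    generate_suitability_mask,
    generate_villages,
)
from maupscale.landscape import _largest_remainder

SEED = 424242


def morans_i_rook(field: np.ndarray) -> float:
    """Brute-force Moran's I with rook neighbours (lag-1 autocorrelation)."""
    z = field - field.mean()
    num = 0.0
    w = 0
    nr, nc = field.shape
    for i in range(nr):
        for j in range(nc):
            if i + 1 < nr:
                num += 2 * z[i, j] * z[i + 1, j]
                w += 2
            if j + 1 < nc:
                num += 2 * z[i, j] * z[i, j + 1]
                w += 2
    return (field.size / w) * num / (z ** 2).sum()


class TestPredictors:
    def test_seeded_determinism(self):
        spec = GridSpec(0, 0, 1.0, 40, 40)
        a = generate_predictors(spec, 3, 5.0, seed=SEED)
        b = generate_predictors(spec, 3, 5.0, seed=SEED)
        for name in a.layer_names:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_standardized(self):
        spec = GridSpec(0, 0, 1.0, 100, 100)
        stack = generate_predictors(spec, 2, 10.0, seed=SEED)
        for layer in stack.layers.values():
            assert abs(layer.mean()) < 0.05
            assert abs(layer.std() - 1.0) < 0.05

    def test_longer_range_means_stronger_autocorrelation(self):
        spec = GridSpec(0, 0, 1.0, 80, 80)
        smooth = generate_predictors(spec, 1, 20.0, seed=SEED)
        rough = generate_predictors(spec, 1, 2.0, seed=SEED)
        i_smooth = morans_i_rook(smooth.layers["pred_00"])
        i_rough = morans_i_rook(rough.layers["pred_00"])
        assert i_smooth > i_rough

    @pytest.mark.parametrize("kwargs", [
        dict(n_layers=0, range_km=5.0),
        dict(n_layers=2, range_km=0.0),
        dict(n_layers=2, range_km=-1.0),
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        spec = GridSpec(0, 0, 1.0, 10, 10)
        with pytest.raises(ValueError):
            generate_predictors(spec, seed=SEED, **kwargs)


class TestSuitabilityMask:
    def test_zero_fraction_all_suitable(self, small_spec):
        stack = generate_predictors(small_spec, 1, 3.0, seed=SEED)
        masked = generate_suitability_mask(stack, 0.0, seed=SEED)
        assert masked.mask.all()

    def test_fraction_honoured(self):
        spec = GridSpec(0, 0, 1.0, 100, 100)
        stack = generate_predictors(spec, 1, 3.0, seed=SEED)
        masked = generate_suitability_mask(stack, 0.3, seed=SEED + 1)
        share = masked.mask.mean()
        assert 0.68 <= share <= 0.72

    def test_seeded_determinism(self, small_spec):
        stack = generate_predictors(small_spec, 1, 3.0, seed=SEED)
        m1 = generate_suitability_mask(stack, 0.25, seed=SEED + 1)
        m2 = generate_suitability_mask(stack, 0.25, seed=SEED + 1)
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_full_fraction_rejected(self, small_stack):
        with pytest.raises(ValueError):
            generate_suitability_mask(small_stack, 1.0, seed=SEED)


class TestVillages:
    def test_contract(self, small_stack):
        villages = generate_villages(small_stack, 500, "uniform", seed=SEED)
        assert len(villages) == 500
        assert len({v.id for v in villages}) == 500
        assert len({(v.x, v.y) for v in villages}) == 500
        spec = small_stack.spec
        for v in villages:
            assert spec.contains(v.x, v.y)
            i, j = spec.index_of(v.x, v.y)
            assert small_stack.mask[i, j]

    def test_clustered_reduces_nn_distance(self, small_stack):
        uni = generate_villages(small_stack, 150, "uniform", seed=SEED)
        clu = generate_villages(small_stack, 150, "clustered", seed=SEED)

        def mean_nn(villages):
            pts = np.array([(v.x, v.y) for v in villages])
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            return d.min(axis=1).mean()

        assert mean_nn(clu) < mean_nn(uni)

    def test_seeded_determinism(self, small_stack):
        a = generate_villages(small_stack, 50, "clustered", seed=SEED)
        b = generate_villages(small_stack, 50, "clustered", seed=SEED)
        assert a == b
        assert [(v.x, v.y) for v in a] == [(v.x, v.y) for v in b]

    def test_too_many_villages_rejected(self, small_stack):
        n_suitable = int(small_stack.mask.sum())
        with pytest.raises(ValueError):
            generate_villages(small_stack, n_suitable + 1, "uniform", seed=SEED)


class TestPopulation:
    def test_total_exact(self, small_stack):
        villages = generate_villages(small_stack, 100, "uniform", seed=SEED)
        profile = SpeciesProfile(name="hens", regime="homogeneous",
                                 effect_sizes={"pred_01": 0.5}, total=123_457)
        villages = generate_population(villages, small_stack, profile, seed=SEED)
        assert sum(v.count("hens") for v in villages) == 123_457

    def test_clustered_is_more_concentrated(self, small_villages):
        def gini(x):
            x = np.sort(np.asarray(x, dtype=float))
            n = len(x)
            return (2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum())

        hom = [v.count("homogeneous") for v in small_villages]
        clu = [v.count("clustered") for v in small_villages]
        assert gini(clu) > gini(hom)

    def test_clustered_occupies_fewer_villages(self, small_villages):
        occ_hom = sum(v.count("homogeneous") > 0 for v in small_villages)
        occ_clu = sum(v.count("clustered") > 0 for v in small_villages)
        assert occ_clu < occ_hom

    def test_null_profile_counts_exchangeable_across_quadrants(self, small_stack):
        """With zero effect sizes the homogeneous regime has no spatial
        signal: counts in the four spatial quadrants come from one
        distribution (Kruskal-Wallis, alpha = 0.01)."""
        villages = generate_villages(small_stack, 200, "uniform", seed=SEED + 7)
        profile = SpeciesProfile(name="null", regime="homogeneous",
                                 effect_sizes={}, total=200_000)
        villages = generate_population(villages, small_stack, profile,
                                       seed=SEED + 8)
        xmid = small_stack.spec.x0 + small_stack.spec.width / 2
        ymid = small_stack.spec.y0 + small_stack.spec.height / 2
        quads = {}
        for v in villages:
            q = (v.x >= xmid, v.y >= ymid)
            quads.setdefault(q, []).append(v.count("null"))
        stat, p = stats.kruskal(*quads.values())
        assert p > 0.01

    def test_missing_layer_rejected(self, small_stack, small_villages):
        profile = SpeciesProfile(name="bad", regime="clustered",
                                 focal_layer="nope", total=10)
        with pytest.raises(KeyError):
            generate_population(list(small_villages), small_stack, profile,
                                seed=SEED)


class TestLargestRemainder:
    def test_exact_total_and_proportionality(self, rng):
        for _ in range(20):
            w = rng.gamma(1.0, 1.0, size=rng.integers(3, 50))
            total = int(rng.integers(1, 10_000))
            alloc = _largest_remainder(w, total)
            assert alloc.sum() == total
            assert (alloc >= 0).all()
            # allocation never deviates from the exact quota by >= 1
            quota = w * total / w.sum()
            assert np.all(np.abs(alloc - quota) < 1.0)

    def test_zero_weights_spread_evenly(self):
        alloc = _largest_remainder(np.zeros(4), 10)
        assert alloc.sum() == 10
        assert alloc.max() - alloc.min() <= 1
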