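"""Evaluation metrics: RMSE, Pearson r, back-aggregation, COR_down."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maupscale import (
    AreaClassScheme,
    aggregate_prediction,
    area_stratified_metrics,
    downscaling_precision,
    pearson,
    rmse,
)
from maupscale.census import (
    aggregate_counts,
    label_raster,
    make_response,
    suitable_areas_all,
)
from maupscale.evaluation import DEFAULT_SCHEMES, aggregate_prediction_all


class TestRmse:
    @pytest.mark.parametrize("obs,pred,expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([0, 0], [1, 1], 1.0),
        ([1, 2, 3], [2, 2, 2], np.sqrt(2 / 3)),
    ])
    def test_known_values(self, obs, pred, expected):
        assert rmse(obs, pred) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=50)
        pred = rng.normal(size=50)
        brute = np.sqrt(sum((o - p) ** 2 for o, p in zip(obs, pred)) / 50)
        assert rmse(obs, pred) == pytest.approx(brute, abs=1e-12)


class TestPearson:
    def test_affine_relation_is_one(self):
        obs = np.arange(10.0)
        assert pearson(obs, 2 * obs + 1) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelation_is_minus_one(self):
        obs = np.arange(10.0)
        assert pearson(obs, -obs) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_gives_nan(self):
        assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=40)
        pred = obs + rng.normal(size=40)
        mo, mp = obs.mean(), pred.mean()
        brute = (sum((o - mo) * (p - mp) for o, p in zip(obs, pred))
                 / np.sqrt(sum((o - mo) ** 2 for o in obs)
                           * sum((p - mp) ** 2 for p in pred)))
        assert pearson(obs, pred) == pytest.approx(brute, abs=1e-12)

    def test_bounded(self, rng):
        for _ in range(20):
            obs = rng.normal(size=10)
            pred = rng.normal(size=10)
            assert -1 <= pearson(obs, pred) <= 1


class TestAggregatePrediction:
    def test_constant_raster_idempotent(self, small_stack, village_system):
        raster = np.full(small_stack.spec.shape, 1.7)
        psu = village_system.psus[0]
        assert aggregate_prediction(raster, psu, small_stack, offset=1.0) == \
            pytest.approx(1.7, abs=1e-12)

    def test_linear_space_averaging(self):
        """Two pixels at linear densities 10 and 30 (offset 0) average to
        20 in linear space: log10(20), not mean of logs."""
        from maupscale.grid import GridSpec, PredictorStack
        from maupscale.zonation import PSU
        from shapely.geometry import box

        spec = GridSpec(0, 0, 1.0, 1, 2)
        stack = PredictorStack(spec=spec, layers={})
        psu = PSU(id="t", polygon=box(0, 0, 2, 1), level="village", shape="IRR")
        raster = np.log10(np.array([[10.0, 30.0]]))
        got = aggregate_prediction(raster, psu, stack, offset=0.0)
        assert got == pytest.approx(np.log10(20.0), abs=1e-12)

    def test_matches_exhaustive_pixel_scan(self, small_stack, village_system,
                                           rng):
        from maupscale.census import suitable_pixel_indices

        raster = rng.normal(size=small_stack.spec.shape)
        for psu in village_system.psus[::29]:
            ii, jj = suitable_pixel_indices(psu.polygon, small_stack)
            if ii.size == 0:
                continue
            lin = np.maximum(10.0 ** raster[ii, jj] - 1.0, 0.0)
            brute = np.log10(lin.mean() + 1.0)
            got = aggregate_prediction(raster, psu, small_stack, offset=1.0)
            assert got == pytest.approx(brute, abs=0)

    def test_vectorised_path_agrees(self, small_stack, village_system, rng):
        raster = rng.normal(size=small_stack.spec.shape)
        labels = label_raster(village_system, small_stack)
        bulk = aggregate_prediction_all(raster, labels,
                                        len(village_system.psus), offset=1.0)
        for k, psu in enumerate(village_system.psus[::13]):
            direct = aggregate_prediction(raster, psu, small_stack, offset=1.0)
            idx = village_system.psus.index(psu)
            if np.isnan(direct):
                assert np.isnan(bulk[idx])
            else:
                assert bulk[idx] == pytest.approx(direct, abs=1e-12)


class TestAreaStratified:
    def test_breakpoint_classification(self):
        scheme = AreaClassScheme((10.0, 20.0))
        assert scheme.classify(15.0) == "c2"
        assert scheme.classify(5.0) == "c1"
        assert scheme.classify(20.0) == "c3"

    def test_default_schemes_follow_design(self):
        assert DEFAULT_SCHEMES["village"].breakpoints == (10.0, 20.0)
        assert DEFAULT_SCHEMES["subdistrict"].breakpoints == (100.0, 200.0)
        assert DEFAULT_SCHEMES["district"].breakpoints == (500.0, 1000.0)

    def test_classes_partition_pairs(self, rng):
        import pandas as pd

        pairs = pd.DataFrame({
            "obs": rng.normal(size=30),
            "pred": rng.normal(size=30),
            "area": rng.uniform(1, 40, size=30),
        })
        scheme = AreaClassScheme((10.0, 20.0))
        out = area_stratified_metrics(pairs, scheme)
        ns = out[out.metric == "RMSE"].set_index("area_class")["n_psus"]
        assert ns["c1"] + ns["c2"] + ns["c3"] == ns["all"] == 30

    def test_sparse_class_gives_nan(self, rng):
        import pandas as pd

        pairs = pd.DataFrame({
            "obs": rng.normal(size=10),
            "pred": rng.normal(size=10),
            "area": np.full(10, 5.0),  # all in c1
        })
        out = area_stratified_metrics(pairs, AreaClassScheme((10.0, 20.0)))
        vals = out.set_index(["metric", "area_class"])["value"]
        assert np.isnan(vals["RMSE", "c2"]) and np.isnan(vals["COR", "c3"])
        assert np.isfinite(vals["RMSE", "c1"])


class TestDownscalingPrecision:
    def test_self_comparison_is_one(self, small_stack, small_villages,
                                    village_system):
        """Rasterizing the observed village densities and aggregating them
        back must reproduce the observations exactly (r = 1)."""
        labels = label_raster(village_system, small_stack)
        areas = suitable_areas_all(village_system, small_stack, labels)
        counts = aggregate_counts(small_villages, village_system, "clustered")
        records, _ = make_response(counts, areas)
        raster = np.full(small_stack.spec.shape, np.nan)
        dens = {r.psu_id: r.log_density for r in records}
        for k, psu in enumerate(village_system.psus):
            if psu.id in dens:
                raster[labels == k] = dens[psu.id]
        cd = downscaling_precision(raster, village_system, records,
                                   small_stack, offset=1.0, labels=labels)
        assert cd == pytest.approx(1.0, abs=1e-9)

    def test_constant_prediction_is_nan(self, small_stack, small_villages,
                                        village_system):
        labels = label_raster(village_system, small_stack)
        areas = suitable_areas_all(village_system, small_stack, labels)
        counts = aggregate_counts(small_villages, village_system, "clustered")
        records, _ = make_response(counts, areas)
        raster = np.full(small_stack.spec.shape, 0.5)
        cd = downscaling_precision(raster, village_system, records,
                                   small_stack, offset=1.0, labels=labels)
        assert np.isnan(cd)

    def test_invariant_to_village_ordering(self, small_stack, small_villages,
                                           village_system, rng):
        labels = label_raster(village_system, small_stack)
        areas = suitable_areas_all(village_system, small_stack, labels)
        counts = aggregate_counts(small_villages, village_system, "homogeneous")
        records, _ = make_response(counts, areas)
        raster = rng.normal(size=small_stack.spec.shape)
        a = downscaling_precision(raster, village_system, records,
                                  small_stack, offset=1.0, labels=labels)
        shuffled = list(records)
        rng.shuffle(shuffled)
        b = downscaling_precision(raster, village_system, shuffled,
                                  small_stack, offset=1.0, labels=labels)
        assert a == pytest.approx(b, abs=1e-15)
        assert a <= 1.0
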