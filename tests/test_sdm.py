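"""Raster I/O, thinning, filtering, features, MaxEnt fit and selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phylosdm import sdm, synthetic
from phylosdm.errors import ParameterError, ProjectionError, RasterError
from phylosdm.sdm import (
    FeatureSpec,
    GridGeometry,
    MaxEntSDM,
    Normalizer,
    OccurrenceSet,
    RasterStack,
    auc_presence_background,
    binarize,
    build_features,
    correlation_filter,
    predict_map,
    sample_background,
    select_model,
    thin_occurrences,
    threshold_10pct,
)


class TestRasterIO:
    def test_roundtrip_bit_identical(self, tmp_path):
        geom = GridGeometry(5, 4, 100.0, 45.0, 0.25)
        rng = np.random.default_rng(0)
        arr = np.round(rng.normal(size=(5, 4)), 6)
        arr[0, 0] = np.nan
        p = tmp_path / "layer.asc"
        sdm.write_ascii_grid(p, geom, arr, fmt="%.6f")
        g2, a2, _ = sdm.read_ascii_grid(p)
        assert g2 == geom
        assert np.isnan(a2[0, 0])
        np.testing.assert_allclose(a2[~np.isnan(arr)], arr[~np.isnan(arr)])

    def test_stack_requires_matching_geometry(self, tmp_path):
        g1 = GridGeometry(3, 3, 0.0, 0.0, 1.0)
        g2 = GridGeometry(3, 3, 0.0, 0.0, 0.5)
        sdm.write_ascii_grid(tmp_path / "a.asc", g1, np.ones((3, 3)))
        sdm.write_ascii_grid(tmp_path / "b.asc", g2, np.ones((3, 3)))
        with pytest.raises(RasterError):
            sdm.read_raster_stack(
                {"a": tmp_path / "a.asc", "b": tmp_path / "b.asc"}
            )

    def test_nodata_mask_intersected(self):
        geom = GridGeometry(3, 3, 0.0, 0.0, 1.0)
        a = np.ones((3, 3)); a[0, 0] = np.nan
        b = np.ones((3, 3)); b[2, 2] = np.nan
        stack = RasterStack(geom, {"a": a, "b": b})
        assert stack.mask.sum() == 7
        assert np.isnan(stack.layers["a"][2, 2])

    def test_cell_lookup_and_center(self):
        geom = GridGeometry(4, 4, 100.0, 40.0, 0.5)
        r, c = geom.cell_of(100.1, 40.1)
        assert (r, c) == (3, 0)  # bottom-left
        lon, lat = geom.cell_center(3, 0)
        assert (lon, lat) == (100.25, 40.25)


class TestThinning:
    def test_close_pair_reduced(self):
        occ = OccurrenceSet(np.array([[100.0, 45.0], [100.005, 45.0]]))
        assert thin_occurrences(occ, 5.0).n == 1

    def test_far_points_kept(self):
        # ~0.1 degree apart at 45N is about 8-11 km
        pts = [[100.0 + 0.1 * i, 45.0] for i in range(5)]
        occ = OccurrenceSet(np.array(pts))
        assert thin_occurrences(occ, 5.0).n == 5

    def test_kept_set_respects_min_distance(self):
        rng = np.random.default_rng(4)
        pts = np.column_stack(
            [rng.uniform(100, 101, 50), rng.uniform(44, 45, 50)]
        )
        thinned = thin_occurrences(OccurrenceSet(pts), 5.0)
        from phylosdm.sdm.evaluate import _great_circle_km

        for a, b in itertools.combinations(thinned.points, 2):
            assert _great_circle_km(a, b) >= 5.0


class TestCorrelationFilter:
    def _stack(self, layers):
        geom = GridGeometry(20, 20, 0.0, 0.0, 0.1)
        return RasterStack(geom, layers)

    def test_identical_layer_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 20))
        stack = self._stack({"a": a.copy(), "b": a.copy()})
        assert len(correlation_filter(stack)) == 1

    def test_independent_layers_kept(self):
        rng = np.random.default_rng(1)
        stack = self._stack(
            {f"l{i}": rng.normal(size=(20, 20)) for i in range(4)}
        )
        assert len(correlation_filter(stack)) == 4

    def test_constructed_high_pair_drops_exactly_one(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(20, 20))
        b = 0.97 * a + math.sqrt(1 - 0.97**2) * rng.normal(size=(20, 20))
        c = rng.normal(size=(20, 20))
        stack = self._stack({"a": a, "b": b, "c": c})
        kept = correlation_filter(stack, r_max=0.8)
        assert len(kept) == 2 and "c" in kept
        # deterministic tie rule drops the alphabetically first of the pair
        assert kept == ["b", "c"]

    def test_keep_list_honoured(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(20, 20))
        stack = self._stack({"a": a.copy(), "b": a.copy()})
        with pytest.warns(UserWarning):
            kept = correlation_filter(
                stack, keep_list=["a", "b"], r_max=0.8
            )
        assert kept == ["a", "b"]


class TestFeatures:
    def test_column_counts(self):
        rng = np.random.default_rng(0)
        Z = rng.uniform(size=(30, 2))
        for classes, expected in [
            ("L", 2),
            ("LQ", 4),
            ("LQP", 5),
            ("LQH", 4 + 2 * 2 * 5),
            ("T", 2 * 5),
        ]:
            F, _ = build_features(Z, FeatureSpec(classes, n_knots=5))
            assert F.shape == (30, expected), classes

    def test_single_layer_linear_only(self):
        F, _ = build_features(
            np.random.default_rng(1).uniform(size=(10, 1)), FeatureSpec("L")
        )
        assert F.shape == (10, 1)

    def test_columns_in_unit_interval(self):
        rng = np.random.default_rng(2)
        Z = rng.uniform(size=(50, 3))
        F, _ = build_features(Z, FeatureSpec("LQHPT", n_knots=4))
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_constant_layer_features_dropped(self):
        Z = np.column_stack(
            [np.full(20, 0.5), np.linspace(0, 1, 20)]
        )
        with pytest.warns(UserWarning):
            F, const = build_features(Z, FeatureSpec("LQ", n_knots=3))
        assert const == frozenset({0})
        assert F.shape[1] == 3  # 2 linear + 1 quadratic (variable layer only)

    def test_normalizer_clamps_and_counts(self):
        norm = Normalizer(np.array([0.0]), np.array([1.0]))
        Z, n_clamped = norm(np.array([[-0.5], [0.5], [2.0]]))
        assert n_clamped == 2
        assert Z.min() == 0.0 and Z.max() == 1.0


class TestMaxEnt:
    def _data(self, small_sdm_data):
        stack = small_sdm_data["stack"]
        names = stack.layer_names
        Xp = stack.values_at(
            small_sdm_data["occ"].snap_to_cells(stack), names
        )
        Xb = stack.values_at(small_sdm_data["bg"], names)
        X = np.vstack([Xp, Xb])
        y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
        return X, y, Xp, Xb

    def test_raw_normalised_over_background(self, small_sdm_data):
        X, y, Xp, Xb = self._data(small_sdm_data)
        m = MaxEntSDM(feature_classes="LQ").fit(X, y)
        assert m.predict_raw(Xb).sum() == pytest.approx(1.0, abs=1e-8)

    def test_logistic_in_unit_interval(self, small_sdm_data):
        X, y, Xp, Xb = self._data(small_sdm_data)
        m = MaxEntSDM(feature_classes="LQ").fit(X, y)
        s = m.predict(Xb)
        assert s.min() > 0.0 and s.max() < 1.0

    def test_positive_gradient_gives_positive_linear_coef(self):
        rng = np.random.default_rng(5)
        xb = rng.uniform(0, 10, size=(500, 1))
        xp = rng.uniform(8, 10, size=(30, 1))  # presences at high values
        X = np.vstack([xp, xb])
        y = np.concatenate([np.ones(30), np.zeros(500)])
        m = MaxEntSDM(feature_classes="L").fit(X, y)
        assert m.coef_[0] > 0

    def test_l1_norm_shrinks_with_rm(self, small_sdm_data):
        X, y, *_ = self._data(small_sdm_data)
        norms = [
            np.abs(MaxEntSDM(feature_classes="LQ", rm=rm).fit(X, y).coef_).sum()
            for rm in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_nonzero_count_weakly_decreases_with_rm(self, small_sdm_data):
        X, y, *_ = self._data(small_sdm_data)
        ks = [
            MaxEntSDM(feature_classes="LQH", rm=rm, n_knots=6).fit(X, y).k_
            for rm in (0.5, 2.0, 8.0)
        ]
        assert ks[0] >= ks[-1]

    def test_sklearn_params_roundtrip(self):
        m = MaxEntSDM(feature_classes="LQH", rm=2.0, n_knots=7)
        params = m.get_params()
        m2 = MaxEntSDM(**params)
        assert m2.get_params() == params
        m2.set_params(rm=1.0)
        assert m2.rm == 1.0

    def test_clamping_counts_out_of_range(self, small_sdm_data):
        X, y, Xp, Xb = self._data(small_sdm_data)
        m = MaxEntSDM(feature_classes="LQ").fit(X, y)
        far = Xb.copy()
        far[:10] = Xb[:10] + 100.0
        m.predict(far)
        assert m.n_clamped_ >= 10


class TestAUC:
    def test_rank_auc_matches_brute_force(self):
        rng = np.random.default_rng(0)
        sp = rng.normal(1.0, 1.0, 60)
        sb = rng.normal(0.0, 1.0, 140)
        brute = np.mean(
            [
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a in sp
                for b in sb
            ]
        )
        assert auc_presence_background(sp, sb) == pytest.approx(brute)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        auc = auc_presence_background(
            rng.uniform(size=300), rng.uniform(size=3000)
        )
        assert abs(auc - 0.5) < 0.05

    def test_separable_scores_give_one(self):
        assert auc_presence_background([2.0, 3.0], [0.0, 1.0]) == 1.0


class TestThreshold:
    def test_decile_grid(self):
        s = np.arange(0.1, 1.01, 0.1)
        assert threshold_10pct(s).value == pytest.approx(0.1)

    def test_all_equal(self):
        assert threshold_10pct(np.full(7, 0.42)).value == pytest.approx(0.42)

    def test_at_least_ninety_percent_retained(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(size=57)
        t = threshold_10pct(s).value
        assert np.mean(s >= t) >= 0.9


class TestSelection:
    def _report(self, rows):
        return pd.DataFrame(rows)

    def test_single_candidate(self):
        rep = self._report(
            [dict(rm=1.0, fc="LQ", auc_test=0.8, auc_diff=0.1, or10=0.1,
                  aicc=100.0, delta_aicc=0.0)]
        )
        assert select_model(rep) == (1.0, "LQ")

    def test_lowest_delta_aicc_wins(self):
        rep = self._report(
            [
                dict(rm=1.0, fc="LQ", auc_test=0.8, auc_diff=0.1, or10=0.1,
                     aicc=105.0, delta_aicc=5.0),
                dict(rm=2.0, fc="H", auc_test=0.7, auc_diff=0.2, or10=0.3,
                     aicc=100.0, delta_aicc=0.0),
            ]
        )
        assert select_model(rep) == (2.0, "H")

    def test_tie_broken_by_or10(self):
        rep = self._report(
            [
                dict(rm=1.0, fc="LQ", auc_test=0.8, auc_diff=0.1, or10=0.2,
                     aicc=100.0, delta_aicc=0.0),
                dict(rm=2.0, fc="L", auc_test=0.8, auc_diff=0.1, or10=0.1,
                     aicc=100.0, delta_aicc=0.0),
            ]
        )
        assert select_model(rep) == (2.0, "L")


class TestPrediction:
    def test_uniform_model_constant_map(self, small_sdm_data):
        stack = small_sdm_data["stack"]
        rng = np.random.default_rng(0)
        # presences drawn uniformly: fitted model should be near-flat, and
        # the projected map must equal the direct prediction cell-by-cell
        cells = stack.valid_cells()
        Xb = stack.values_at(cells[:: max(1, len(cells) // 500)], stack.layer_names)
        Xp = Xb[rng.choice(len(Xb), 30, replace=False)]
        m = MaxEntSDM(feature_classes="L").fit(
            np.vstack([Xp, Xb]),
            np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))]),
        )
        mp = predict_map(m, stack, stack.layer_names)
        direct = m.predict(stack.values_at(cells, stack.layer_names))
        np.testing.assert_allclose(mp[cells[:, 0], cells[:, 1]], direct)

    def test_binarize_threshold_inclusive(self):
        m = np.array([[0.2, 0.5], [np.nan, 0.5]])
        b = binarize(m, 0.5)
        assert b[0, 1] == 1.0 and b[1, 1] == 1.0 and b[0, 0] == 0.0
        assert np.isnan(b[1, 0])

    def test_missing_layer_raises(self, small_sdm_data):
        stack = small_sdm_data["stack"]
        names = stack.layer_names
        Xb = stack.values_at(small_sdm_data["bg"], names)
        Xp = Xb[:30]
        m = MaxEntSDM(feature_classes="L").fit(
            np.vstack([Xp, Xb]),
            np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))]),
        )
        with pytest.raises(ProjectionError):
            predict_map(m, stack, names + ["bio99"])
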