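from itertools import product

import numpy as np
import pandas as pd
import pytest

import chs
from chs.assessment import ROMAN, TYPE_CODES, dominant_variables, \
    suitable_area
from chs.ensemble import BinaryMap
from chs.raster import GridGeoref, cell_areas


@pytest.fixture
def georef():
    return GridGeoref(n_rows=6, n_cols=6, cell_size=0.5,
                      origin_lon=105.0, origin_lat=30.0)


def _bmap(mask, georef, valid=None):
    mask = np.asarray(mask, bool)
    if valid is None:
        valid = np.ones(mask.shape, bool)
    return BinaryMap(suitable=mask, valid=valid, georef=georef)


class TestClassifyTypes:
    def test_truth_table_all_eight_combinations(self, georef):
        """The (climate, soil, UV) triples map onto codes I-VIII exactly:
        II = all suitable, III = UV-unsuitable only, IV = soil-unsuitable
        only, V = climate-unsuitable only, etc."""
        shape = georef.shape
        for climate, soil, uv in product([False, True], repeat=3):
            types = chs.classify_types(
                _bmap(np.full(shape, climate), georef),
                _bmap(np.full(shape, soil), georef),
                _bmap(np.full(shape, uv), georef))
            expected = TYPE_CODES[(climate, soil, uv)]
            assert (types.codes == expected).all()

    def test_named_rows(self, georef):
        shape = georef.shape
        all_suit = _bmap(np.ones(shape), georef)
        none_suit = _bmap(np.zeros(shape), georef)
        assert (chs.classify_types(all_suit, all_suit, all_suit).codes
                == 2).all()   # II
        assert (chs.classify_types(all_suit, all_suit, none_suit).codes
                == 3).all()   # III
        assert (chs.classify_types(none_suit, none_suit, none_suit).codes
                == 1).all()   # I

    def test_chs_is_type_two(self, georef):
        rng = np.random.default_rng(0)
        maps = [_bmap(rng.random(georef.shape) > 0.5, georef)
                for _ in range(3)]
        types = chs.classify_types(*maps)
        np.testing.assert_array_equal(
            types.chs, maps[0].suitable & maps[1].suitable & maps[2].suitable)

    def test_misaligned_grids_rejected(self, georef):
        other = GridGeoref(n_rows=6, n_cols=6, cell_size=0.25,
                           origin_lon=105.0, origin_lat=30.0)
        a = _bmap(np.ones(georef.shape), georef)
        b = _bmap(np.ones(other.shape), other)
        with pytest.raises(ValueError, match="aligned"):
            chs.classify_types(a, b, a)


class TestCertaintyIndex:
    def test_matches_per_cell_counting(self, georef):
        rng = np.random.default_rng(1)
        masks = [rng.random(georef.shape) > 0.5 for _ in range(8)]
        cm = chs.certainty_index(masks, np.ones(georef.shape, bool), georef)
        brute = sum(m.astype(int) for m in masks) / 8
        np.testing.assert_allclose(cm.ci, brute)

    def test_five_of_eight_is_final_suitable(self, georef):
        shape = georef.shape
        masks = [np.ones(shape, bool)] * 5 + [np.zeros(shape, bool)] * 3
        cm = chs.certainty_index(masks, np.ones(shape, bool), georef)
        assert (cm.ci == 0.625).all()
        assert cm.final_suitable.all()

    def test_exactly_half_is_excluded_by_strict_rule(self, georef):
        shape = georef.shape
        masks = [np.ones(shape, bool)] * 4 + [np.zeros(shape, bool)] * 4
        cm = chs.certainty_index(masks, np.ones(shape, bool), georef)
        assert (cm.ci == 0.5).all()
        assert not cm.final_suitable.any()

    def test_single_member_is_identity(self, georef):
        rng = np.random.default_rng(2)
        mask = rng.random(georef.shape) > 0.5
        cm = chs.certainty_index([mask], np.ones(georef.shape, bool), georef)
        assert set(np.unique(cm.ci)) <= {0.0, 1.0}
        np.testing.assert_array_equal(cm.final_suitable, mask)
        np.testing.assert_array_equal(cm.merge, mask)

    def test_empty_list_rejected(self, georef):
        with pytest.raises(ValueError, match="at least one"):
            chs.certainty_index([], np.ones(georef.shape, bool), georef)


class TestAreas:
    def test_area_by_type_partitions_total(self, georef):
        rng = np.random.default_rng(3)
        maps = [_bmap(rng.random(georef.shape) > 0.5, georef)
                for _ in range(3)]
        types = chs.classify_types(*maps)
        areas = cell_areas(georef)
        table = chs.assessment.area_by_type(types, areas)
        assert list(table.index) == list(ROMAN.values())
        assert table.sum() == pytest.approx(areas[types.valid].sum())

    def test_toy_grid_matches_manual_accumulation(self):
        g = GridGeoref(n_rows=3, n_cols=3, cell_size=1.0,
                       origin_lon=0.0, origin_lat=3.0)
        codes = np.array([[2, 2, 1], [1, 3, 3], [3, 2, 8]])
        types = chs.HabitatTypeMap(codes=codes,
                                   valid=np.ones((3, 3), bool), georef=g)
        areas = cell_areas(g)
        table = chs.assessment.area_by_type(types, areas)
        assert table["II"] == pytest.approx(
            areas[0, 0] + areas[0, 1] + areas[2, 1])
        assert table["VIII"] == pytest.approx(areas[2, 2])
        assert table["IV"] == 0.0


class TestChangeStatistics:
    def test_identical_maps_no_change(self, georef):
        rng = np.random.default_rng(4)
        m = _bmap(rng.random(georef.shape) > 0.4, georef)
        ch = chs.change_statistics(m, m)
        assert ch.gain_km2 == 0 and ch.loss_km2 == 0
        assert ch.unchanged_km2 == pytest.approx(suitable_area(m))

    def test_total_loss(self, georef):
        base = _bmap(np.ones(georef.shape), georef)
        fut = _bmap(np.zeros(georef.shape), georef)
        ch = chs.change_statistics(base, fut)
        assert ch.unchanged_km2 == 0
        assert ch.loss_km2 == pytest.approx(cell_areas(georef).sum())

    def test_toy_counts_times_cell_area(self):
        g = GridGeoref(n_rows=3, n_cols=3, cell_size=0.01,
                       origin_lon=0.0, origin_lat=0.015)
        # near the equator with a tiny cell all areas are ~equal
        base = np.array([[1, 1, 1], [1, 1, 1], [1, 0, 0]], bool)
        fut = np.array([[1, 1, 1], [1, 0, 0], [0, 1, 1]], bool)
        ch = chs.change_statistics(_bmap(base, g), _bmap(fut, g))
        a = cell_areas(g).mean()
        assert ch.unchanged_km2 == pytest.approx(4 * a, rel=1e-4)
        assert ch.gain_km2 == pytest.approx(2 * a, rel=1e-4)
        assert ch.loss_km2 == pytest.approx(3 * a, rel=1e-4)

    @pytest.mark.parametrize("trial", range(100))
    def test_conservation_on_random_grids(self, trial):
        rng = np.random.default_rng(trial)
        g = GridGeoref(n_rows=8, n_cols=8, cell_size=0.5,
                       origin_lon=100.0, origin_lat=40.0)
        valid = rng.random(g.shape) > 0.1
        base = _bmap(rng.random(g.shape) > 0.5, g, valid)
        fut = _bmap(rng.random(g.shape) > 0.5, g, valid)
        areas = cell_areas(g)
        ch = chs.change_statistics(base, fut, areas)
        assert ch.baseline_km2 == pytest.approx(
            areas[base.masked() & valid].sum())
        assert ch.future_km2 == pytest.approx(
            areas[fut.masked() & valid].sum())
        assert min(ch.unchanged_km2, ch.gain_km2, ch.loss_km2) >= 0


class TestPercentChange:
    def test_headline_contraction(self):
        # 1.15 -> 0.99 (x10^6 km2) is a 13.91% contraction
        assert chs.percent_change(1.15, 0.99) == 13.91

    def test_mid_period_contraction(self):
        # 1.15 -> 1.07 computes to 6.96% to two decimals
        assert chs.percent_change(1.15, 1.07) == 6.96

    def test_equal_areas_zero(self):
        assert chs.percent_change(2.0, 2.0) == 0.0

    def test_zero_current_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            chs.percent_change(0.0, 1.0)


class TestContributionAnalysis:
    @staticmethod
    def _trained(stack, occ, predictors, seed=0):
        d = chs.TrainingDesign(algorithms=["GLM"], n_pa_sets=1, n_runs=3,
                               n_pa_points=200, seed=seed)
        members, calib = chs.train_members(stack, occ, predictors, d)
        return chs.build_ensemble(members, cutoff=0.0), calib

    def test_normalizes_to_hundred(self, small_stack, occurrences):
        ens, calib = self._trained(small_stack, occurrences,
                                   ["bio1", "bio2"])
        contrib = chs.contribution_analysis(ens, calib, n_perm=3, seed=0)
        assert contrib.sum() == pytest.approx(100.0)

    def test_single_predictor_gets_everything(self, small_stack,
                                              occurrences):
        ens, calib = self._trained(small_stack, occurrences, ["bio1"])
        contrib = chs.contribution_analysis(ens, calib, n_perm=3, seed=0)
        assert contrib["bio1"] == pytest.approx(100.0)

    def test_unused_predictor_contributes_nothing(self, small_stack,
                                                  occurrences):
        ens, calib = self._trained(small_stack, occurrences,
                                   ["bio1", "bio2"])
        # bio2 is irrelevant to the envelope species on bio1
        contrib = chs.contribution_analysis(ens, calib, n_perm=5, seed=0)
        assert contrib["bio1"] > contrib["bio2"]
        assert dominant_variables(contrib) == ["bio1"]

    def test_n_perm_validated(self, small_stack, occurrences):
        ens, calib = self._trained(small_stack, occurrences, ["bio1"])
        with pytest.raises(ValueError, match="n_perm"):
            chs.contribution_analysis(ens, calib, n_perm=0)


class TestDominantVariableRanges:
    def test_uniform_values_interval_contains_midpoint(self, georef):
        g = GridGeoref(n_rows=30, n_cols=30, cell_size=0.1,
                       origin_lon=100.0, origin_lat=30.0)
        st = chs.RasterStack(georef=g)
        rng = np.random.default_rng(0)
        st.add_layer("bio7", rng.uniform(7, 8, g.shape))
        lo, hi = chs.dominant_variable_ranges(
            st, np.ones(g.shape, bool), ["bio7"])["bio7"]
        assert 7 <= lo < 7.5 < hi <= 8

    def test_bimodal_interval_lands_on_taller_mode(self):
        g = GridGeoref(n_rows=40, n_cols=40, cell_size=0.1,
                       origin_lon=100.0, origin_lat=30.0)
        rng = np.random.default_rng(1)
        vals = np.r_[rng.normal(0, 0.3, 1200), rng.normal(5, 0.3, 400)]
        st = chs.RasterStack(georef=g)
        st.add_layer("x", vals.reshape(g.shape))
        lo, hi = chs.dominant_variable_ranges(
            st, np.ones(g.shape, bool), ["x"], mass=0.5)["x"]
        assert lo < 0 < hi < 2  # around the taller mode at 0

    def test_full_mass_spans_observed_range(self):
        g = GridGeoref(n_rows=30, n_cols=30, cell_size=0.1,
                       origin_lon=100.0, origin_lat=30.0)
        rng = np.random.default_rng(2)
        vals = rng.uniform(3, 9, g.shape)
        st = chs.RasterStack(georef=g)
        st.add_layer("x", vals)
        lo, hi = chs.dominant_variable_ranges(
            st, np.ones(g.shape, bool), ["x"], mass=1.0)["x"]
        assert lo == pytest.approx(vals.min())
        assert hi == pytest.approx(vals.max())

    def test_constant_layer_rejected(self):
        g = GridGeoref(n_rows=30, n_cols=30, cell_size=0.1,
                       origin_lon=100.0, origin_lat=30.0)
        st = chs.RasterStack(georef=g)
        st.add_layer("x", np.ones(g.shape))
        with pytest.raises(ValueError, match="constant"):
            chs.dominant_variable_ranges(st, np.ones(g.shape, bool), ["x"])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = chs.kruskal_wallis([1.0, 1.0, 1.0], [1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_hand_ranked_example(self):
        # ranks 1..6 split into {1,2,3} and {4,5,6}: H = 3.857 tie-free
        h, _ = chs.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_rank_invariance_under_label_permutation(self):
        a = [3.0, 1.0, 4.0, 1.5]
        b = [2.0, 5.0, 0.5, 2.5]
        h1, _ = chs.kruskal_wallis(a, b)
        h2, _ = chs.kruskal_wallis(b, a)
        assert h1 == pytest.approx(h2)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            chs.kruskal_wallis([1.0, 2.0])
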