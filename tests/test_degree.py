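import numpy as np
import pytest

from voxgraph.correlation import ConnectionRecord, CorrelationConfig
from voxgraph.degree import (
    AdaptiveHistogram,
    CentralityResult,
    SparsityConfig,
    ThresholdConfig,
    dc_sparsity,
    dc_sparsity_exact,
    dc_threshold,
    finalize_sparsity,
    hist_insert,
    sparsity_k_target,
    tie_break_precision,
)
from voxgraph.errors import ConfigError, DegenerateInputError

from conftest import brute_force_dc, line_ts, random_ts


def fill_histogram(values, k_target, cfg=None):
    h = AdaptiveHistogram(k_target=k_target, cfg=cfg)
    for idx, v in enumerate(values):
        hist_insert(h, ConnectionRecord(0, idx + 1, float(v)))
    return h


class TestThresholdMode:
    def test_perfect_correlation_triplet(self):
        ts = line_ts([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        res = dc_threshold(ts, ThresholdConfig(0.0))
        np.testing.assert_array_equal(res.binary_map, [1, 1, 0])
        np.testing.assert_allclose(res.weighted_map, [1.0, 1.0, 0.0], atol=1e-12)
        assert res.retained_connections == 1

    def test_admit_everything(self):
        # the cutoff is strict ("exceed"), so admitting pairs at r = -1
        # needs a threshold strictly below -1
        ts = line_ts([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        res = dc_threshold(ts, ThresholdConfig(-1.0 - 1e-9))
        np.testing.assert_array_equal(res.binary_map, [2, 2, 2])
        np.testing.assert_allclose(res.weighted_map, [0.0, 0.0, -2.0], atol=1e-6)

    @pytest.mark.parametrize("thr", [0.0, 0.3])
    def test_matches_brute_force(self, rng, thr):
        ts = random_ts(rng, 30, 20)
        res = dc_threshold(ts, ThresholdConfig(thr))
        binary, weighted, retained = brute_force_dc(ts.values, thr)
        np.testing.assert_array_equal(res.binary_map, binary)
        np.testing.assert_allclose(res.weighted_map, weighted, atol=1e-10)
        assert res.retained_connections == retained

    def test_monotone_in_threshold(self, rng):
        ts = random_ts(rng, 25, 15)
        prev = dc_threshold(ts, ThresholdConfig(-0.5)).binary_map
        for thr in (0.0, 0.3, 0.6):
            cur = dc_threshold(ts, ThresholdConfig(thr)).binary_map
            assert np.all(cur <= prev)
            prev = cur

    def test_degenerate_input(self):
        with pytest.raises(DegenerateInputError):
            dc_threshold(line_ts([[1, 2, 3]]))

    def test_threshold_config_range(self):
        with pytest.raises(ConfigError):
            ThresholdConfig(1.0)


class TestAdaptiveHistogram:
    def test_pruning_raises_admission_threshold(self):
        """Two high records already satisfy k=2, so every bin below the
        one holding them is unneeded: pruning repeats until the lowest
        retained bin is the survivors' own, and the late low record is
        rejected on arrival."""
        h = fill_histogram([0.99, 0.98, 0.01], k_target=2)
        assert h.admission_threshold == pytest.approx(0.98)
        assert sorted(r.r for r in h.records()) == [0.98, 0.99]

    def test_subthreshold_insert_is_noop(self):
        h = fill_histogram([0.99, 0.98, 0.01], k_target=2)
        before = h.total_stored
        hist_insert(h, ConnectionRecord(7, 8, 0.015))
        assert h.total_stored == before

    def test_admission_threshold_steps_are_bin_widths(self, rng):
        h = AdaptiveHistogram(k_target=10, cfg=SparsityConfig(1.0))
        seen = [h.admission_threshold]
        for idx, v in enumerate(rng.uniform(0, 1, size=500)):
            hist_insert(h, ConnectionRecord(0, idx + 1, float(v)))
            seen.append(h.admission_threshold)
        steps = np.diff(seen)
        assert np.all(steps >= 0)
        width = SparsityConfig(1.0).bin_width
        for s in steps[steps > 0]:
            assert s / width == pytest.approx(round(s / width))

    def test_pruning_never_discards_top_k(self, rng):
        """Full-sort oracle: the stored set always covers the true top-k."""
        values = rng.uniform(0, 1, size=2000)
        h = AdaptiveHistogram(k_target=50, cfg=SparsityConfig(1.0))
        ii = np.zeros(2000, dtype=np.intp)
        jj = np.arange(1, 2001, dtype=np.intp)
        h.insert_many(ii, jj, values)
        stored = {r.r for r in h.records()}
        top50 = set(np.sort(values)[-50:])
        assert top50 <= stored


class TestFinalizeSparsity:
    def test_six_values_top_two(self):
        h = fill_histogram([0.9, 0.8, 0.1, 0.5, 0.4, 0.3], k_target=2)
        sel = finalize_sparsity(h)
        assert sorted(sel.r.tolist()) == [0.8, 0.9]
        assert sel.final_threshold == pytest.approx(0.8)

    def test_k_equals_total_keeps_everything(self):
        vals = [0.9, 0.8, 0.5, 0.4, 0.3]
        h = fill_histogram(vals, k_target=len(vals))
        sel = finalize_sparsity(h)
        assert sorted(sel.r.tolist()) == sorted(vals)
        assert sel.final_threshold == pytest.approx(min(vals))

    def test_matches_full_sort_up_to_subbin_ties(self, rng):
        values = rng.uniform(0, 1, size=10_000)
        k = 200
        h = AdaptiveHistogram(k_target=k, cfg=SparsityConfig(1.0))
        h.insert_many(
            np.zeros(values.size, dtype=np.intp),
            np.arange(1, values.size + 1, dtype=np.intp),
            values,
        )
        sel = finalize_sparsity(h)
        retained = set(np.round(sel.r, 15))
        top_k = np.sort(values)[-k:]
        assert set(np.round(top_k, 15)) <= retained
        # overshoot only from records inside one secondary sub-bin
        extras = sel.r.size - k
        sub_width = tie_break_precision(SparsityConfig(1.0))
        kth = top_k[0]
        if extras:
            below = sel.r[sel.r < kth]
            assert below.size == extras
            assert np.all(kth - below < sub_width)

    def test_empty_histogram_rejected(self):
        h = AdaptiveHistogram(k_target=3, cfg=SparsityConfig(1.0))
        with pytest.raises(DegenerateInputError):
            finalize_sparsity(h)

    def test_shortfall_returns_everything_with_warning(self):
        h = fill_histogram([0.9, 0.8], k_target=5)
        with pytest.warns(UserWarning, match="cannot be met"):
            sel = finalize_sparsity(h)
        assert sorted(sel.r.tolist()) == [0.8, 0.9]
        assert sel.shortfall


class TestSparsityMode:
    def test_four_voxel_top_two_pairs(self, rng):
        # engineered distinct pairwise correlations
        ts = random_ts(rng, 4, 30)
        p = 33.0  # k_target = ceil(0.33 * 6) = 2
        assert sparsity_k_target(4, p) == 2
        res = dc_sparsity(ts, SparsityConfig(sparsity_percent=p,
                                             floor_threshold=-0.9999))
        oracle = dc_sparsity_exact(ts, SparsityConfig(sparsity_percent=p,
                                                      floor_threshold=-0.9999))
        np.testing.assert_array_equal(res.binary_map, oracle.binary_map)

    def test_full_sparsity_is_complete_graph(self, rng):
        ts = random_ts(rng, 12, 20)
        res = dc_sparsity(ts, SparsityConfig(sparsity_percent=100.0,
                                             floor_threshold=-0.9999))
        assert res.binary_map.sum() == 12 * 11
        np.testing.assert_array_equal(res.binary_map, np.full(12, 11))

    def test_matches_brute_force_top_k(self, rng):
        ts = random_ts(rng, 60, 25)
        cfg = SparsityConfig(sparsity_percent=1.0)
        res = dc_sparsity(ts, cfg)
        oracle = dc_sparsity_exact(ts, cfg)
        k = sparsity_k_target(60, 1.0)
        assert res.retained_connections >= k
        if res.retained_connections == oracle.retained_connections:
            np.testing.assert_array_equal(res.binary_map, oracle.binary_map)
            np.testing.assert_allclose(res.weighted_map, oracle.weighted_map,
                                       atol=1e-10)
        else:  # boundary-tie overshoot: maps dominate the oracle's
            assert np.all(res.binary_map >= oracle.binary_map)

    def test_block_size_independence(self, rng):
        ts = random_ts(rng, 50, 20)
        cfg = SparsityConfig(sparsity_percent=2.0)
        ref = dc_sparsity(ts, cfg, CorrelationConfig(block_size=50))
        for bs in (1, 7, 16):
            got = dc_sparsity(ts, cfg, CorrelationConfig(block_size=bs))
            np.testing.assert_array_equal(ref.binary_map, got.binary_map)
            np.testing.assert_allclose(ref.weighted_map, got.weighted_map,
                                       atol=1e-10)
            assert ref.final_threshold == pytest.approx(got.final_threshold,
                                                        abs=1e-12)

    def test_threshold_at_final_threshold_reproduces_map(self, rng):
        """A threshold run at (just under) the sparsity run's final
        threshold selects the same connection set."""
        ts = random_ts(rng, 40, 30)
        cfg = SparsityConfig(sparsity_percent=5.0)
        sp = dc_sparsity(ts, cfg)
        thr = np.nextafter(sp.final_threshold, -1.0)
        th = dc_threshold(ts, ThresholdConfig(thr))
        np.testing.assert_array_equal(sp.binary_map, th.binary_map)
        np.testing.assert_allclose(sp.weighted_map, th.weighted_map, atol=1e-10)

    def test_conservation_both_modes(self, rng):
        ts = random_ts(rng, 35, 15)
        th = dc_threshold(ts, ThresholdConfig(0.2))
        sp = dc_sparsity(ts, SparsityConfig(sparsity_percent=3.0))
        assert th.binary_map.sum() == 2 * th.retained_connections
        assert sp.binary_map.sum() == 2 * sp.retained_connections

    def test_shortfall_warns_and_uses_what_exists(self, rng):
        ts = random_ts(rng, 20, 10)
        cfg = SparsityConfig(sparsity_percent=50.0, floor_threshold=0.95)
        with pytest.warns(UserWarning):
            res = dc_sparsity(ts, cfg)
        assert res.shortfall

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SparsityConfig(sparsity_percent=0.0)
        with pytest.raises(ConfigError):
            SparsityConfig(sparsity_percent=101.0)
        with pytest.raises(ConfigError):
            SparsityConfig(sparsity_percent=1.0, primary_bins=1)


def test_result_invariants(rng):
    ts = random_ts(rng, 20, 12)
    res = dc_threshold(ts, ThresholdConfig(0.1))
    assert np.all(res.binary_map >= 0)
    assert np.all(res.binary_map <= ts.n_vox - 1)
    assert np.all(res.weighted_map <= res.binary_map + 1e-12)
    with pytest.raises(AssertionError):
        CentralityResult(
            binary_map=np.array([1, 1]),
            weighted_map=np.zeros(2),
            mode="threshold",
            retained_connections=5,
        )
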