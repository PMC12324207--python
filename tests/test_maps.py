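"""Rate maps, fields, spatial information, COM — against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spatialcode as sc
from spatialcode import maps, synthetic


def parked_trajectory(x, y, seconds, sample_rate=30.0):
    n = int(seconds * sample_rate)
    t = np.arange(n) / sample_rate
    return sc.Trajectory(t=t, x=np.full(n, x), y=np.full(n, y),
                         sample_rate=sample_rate)


class TestOccupancy:
    def test_parked_path_fills_one_bin(self):
        traj = parked_trajectory(5.0, 5.0, 10.0)
        occ = maps.occupancy_map(traj, bin_size=2.0, extent=40.0)
        assert occ.dwell[2, 2] == pytest.approx(10.0, rel=0.01)
        assert occ.dwell.sum() == pytest.approx(occ.dwell[2, 2])
        assert occ.valid.sum() == 1 and occ.valid[2, 2]

    def test_uniform_sweep_has_low_dwell_variation(self, sweep_traj):
        occ = maps.occupancy_map(sweep_traj, bin_size=2.0, extent=40.0)
        dw = occ.dwell[occ.valid]
        assert dw.std() / dw.mean() < 0.2

    def test_brief_visits_marked_invalid(self):
        traj = parked_trajectory(5.0, 5.0, 0.07)
        occ = maps.occupancy_map(traj, bin_size=2.0, extent=40.0)
        assert not occ.valid[2, 2]

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            sc.Trajectory(t=np.array([]), x=np.array([]), y=np.array([]))


class TestRateMap:
    def test_single_bin_rate(self):
        traj = parked_trajectory(5.0, 5.0, 2.0)
        spikes = sc.SpikeTrain("u", np.linspace(0.1, 1.9, 6))
        rm = maps.rate_map(traj, spikes, bin_size=2.0, extent=40.0,
                           kernel_bins=0)
        assert rm.rate[2, 2] == pytest.approx(3.0, rel=0.02)

    def test_homogeneous_unit_mean_rate(self, sweep_traj):
        train = synthetic.gen_spikes(sweep_traj, lambda x, y: 5.0 + 0 * x,
                                     seed=1)
        rm = maps.rate_map(sweep_traj, train, bin_size=2.0, extent=40.0,
                           kernel_bins=0)
        assert abs(rm.rate[rm.valid].mean() - 5.0) / 5.0 < 0.1

    def test_unsmoothed_map_conserves_spikes(self, traj40):
        tuning = synthetic.make_tuning(
            "place", {"peak_rate": 10.0, "width": 4.0}, 40.0,
            np.random.default_rng(3))
        train = synthetic.gen_spikes(traj40, tuning, seed=7)
        occ = maps.occupancy_map(traj40, bin_size=2.0, extent=40.0)
        rm = maps.rate_map(traj40, train, occ=occ, kernel_bins=0)
        recovered = np.sum(rm.rate[rm.valid] * occ.dwell[rm.valid])
        sx, sy = traj40.position_at(train.spike_times)
        in_valid = occ.valid[np.clip((sy // 2).astype(int), 0, 19),
                             np.clip((sx // 2).astype(int), 0, 19)]
        assert recovered == pytest.approx(in_valid.sum(), rel=1e-9)

    def test_spikes_outside_span_rejected(self, traj40):
        spikes = sc.SpikeTrain("u", np.array([traj40.t[-1] + 5.0]))
        with pytest.raises(ValueError):
            maps.rate_map(traj40, spikes, extent=40.0)


def _flood_fill_fields(rate, valid, threshold, min_bins):
    """Brute-force 4-connectivity component oracle."""
    supra = valid & (rate >= threshold) & (rate > 0)
    seen = np.zeros_like(supra)
    comps = []
    for start in zip(*np.nonzero(supra)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if (0 <= rr < rate.shape[0] and 0 <= cc < rate.shape[1]
                        and supra[rr, cc] and not seen[rr, cc]):
                    seen[rr, cc] = True
                    stack.append((rr, cc))
        if len(comp) >= min_bins:
            comps.append(sorted(comp))
    return sorted(comps)


def _ratemap_from_array(rate, bin_size=2.0, valid=None):
    rate = np.asarray(rate, dtype=float)
    if valid is None:
        valid = np.ones_like(rate, dtype=bool)
    return maps.RateMap(rate=rate, bin_size=bin_size,
                        extent=bin_size * rate.shape[0], valid=valid)


class TestFields:
    def test_plateau_is_one_field(self):
        rate = np.zeros((10, 10))
        rate[2:4, 2:7] = 5.0
        fs = maps.detect_fields(_ratemap_from_array(rate))
        assert fs.n_fields == 1
        assert fs.fields[0].shape[0] == 10
        assert fs.areas[0] == pytest.approx(10 * 4.0)

    def test_seven_bin_blob_rejected(self):
        rate = np.zeros((10, 10))
        rate[1, 1:8] = 5.0  # 7 contiguous bins
        fs = maps.detect_fields(_ratemap_from_array(rate))
        assert fs.n_fields == 0

    def test_components_match_flood_fill_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            rate = rng.uniform(0, 10, size=(15, 15))
            rate[rate < 6] = 0.0
            rm = _ratemap_from_array(rate)
            fs = maps.detect_fields(rm)
            oracle = _flood_fill_fields(rate, rm.valid,
                                        0.2 * rate.max(), 8)
            got = sorted(sorted(map(tuple, f.tolist())) for f in fs.fields)
            assert got == oracle

    def test_all_zero_map_yields_empty_fieldset(self):
        fs = maps.detect_fields(_ratemap_from_array(np.zeros((10, 10))))
        assert fs.n_fields == 0 and fs.total_area == 0.0


class TestRateMetrics:
    def test_mfr_from_counts(self):
        rm = _ratemap_from_array(np.zeros((5, 5)))
        fs = maps.detect_fields(rm)
        m = maps.rate_metrics(rm, fs, sc.SpikeTrain("u", np.linspace(0, 59, 300)),
                              duration=60.0)
        assert m.mfr == pytest.approx(5.0)

    def test_in_out_index(self):
        rate = np.full((10, 10), 1.0)  # below the 20% field threshold
        rate[3:6, 3:6] = 10.0
        rm = _ratemap_from_array(rate)
        fs = maps.detect_fields(rm)
        m = maps.rate_metrics(rm, fs, sc.SpikeTrain("u", np.array([1.0])),
                              duration=60.0)
        assert m.infield_mfr == pytest.approx(10.0)
        assert m.outfield_mfr == pytest.approx(1.0)
        assert m.in_out_index == pytest.approx(10.0)

    def test_metrics_equal_partition_means(self):
        rng = np.random.default_rng(5)
        rate = rng.uniform(0, 8, size=(12, 12))
        rm = _ratemap_from_array(rate)
        fs = maps.detect_fields(rm)
        m = maps.rate_metrics(rm, fs, sc.SpikeTrain("u", np.array([1.0])),
                              duration=10.0)
        mask = fs.membership_mask(rate.shape)
        assert m.infield_mfr == pytest.approx(rate[mask].mean())
        assert m.outfield_mfr == pytest.approx(rate[~mask].mean())

    def test_zero_outfield_flagged_not_infinite(self):
        rate = np.zeros((10, 10))
        rate[0:3, 0:3] = 5.0
        rm = _ratemap_from_array(rate)
        fs = maps.detect_fields(rm)
        m = maps.rate_metrics(rm, fs, sc.SpikeTrain("u", np.array([1.0])),
                              duration=10.0)
        assert not m.index_defined and np.isnan(m.in_out_index)


def _si_oracle(rate, dwell, valid):
    p = np.where(valid, dwell, 0.0)
    p = p / p.sum()
    F = sum(p[i, j] * rate[i, j]
            for i in range(rate.shape[0]) for j in range(rate.shape[1])
            if valid[i, j])
    total = 0.0
    for i in range(rate.shape[0]):
        for j in range(rate.shape[1]):
            if valid[i, j] and rate[i, j] > 0:
                total += p[i, j] * rate[i, j] * np.log2(rate[i, j] / F)
    return total


class TestSpatialInformation:
    def test_uniform_rate_gives_zero(self):
        rm = _ratemap_from_array(np.full((5, 5), 3.0))
        occ = maps.OccupancyMap(dwell=np.full((5, 5), 1.0), bin_size=2.0,
                                extent=10.0)
        assert maps.spatial_information(rm, occ) == pytest.approx(0.0, abs=1e-12)

    def test_single_active_bin_closed_form(self):
        """One of 4 equally occupied bins at 8 Hz: F=2, I = 2*log2(4) = 4."""
        rate = np.array([[8.0, 0.0], [0.0, 0.0]])
        rm = _ratemap_from_array(rate)
        occ = maps.OccupancyMap(dwell=np.full((2, 2), 1.0), bin_size=2.0,
                                extent=4.0)
        assert maps.spatial_information(rm, occ) == pytest.approx(4.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            rate = rng.uniform(0, 10, size=(8, 8))
            dwell = rng.uniform(0.05, 2.0, size=(8, 8))
            occ = maps.OccupancyMap(dwell=dwell, bin_size=2.0, extent=16.0)
            rm = _ratemap_from_array(rate, valid=occ.valid)
            si = maps.spatial_information(rm, occ)
            assert si == pytest.approx(
                _si_oracle(rate, dwell, occ.valid), abs=1e-10)
            assert si >= 0

    def test_silent_unit_gives_zero(self):
        rm = _ratemap_from_array(np.zeros((5, 5)))
        occ = maps.OccupancyMap(dwell=np.ones((5, 5)), bin_size=2.0,
                                extent=10.0)
        assert maps.spatial_information(rm, occ) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_nonnegative_for_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        rate = rng.uniform(0, 10, size=(6, 6))
        dwell = rng.uniform(0.11, 1.0, size=(6, 6))
        occ = maps.OccupancyMap(dwell=dwell, bin_size=2.0, extent=12.0)
        rm = _ratemap_from_array(rate)
        assert maps.spatial_information(rm, occ) >= -1e-12

    def test_place_cell_si_exceeds_constant_unit(self, traj40):
        """A place cell carries far more spatial information than a
        constant-rate unit at matched mean rate."""
        occ = maps.occupancy_map(traj40, bin_size=2.0, extent=40.0)
        wins = 0
        for seed in range(10):
            tuning = synthetic.make_tuning(
                "place", {"peak_rate": 10.0, "width": 4.0}, 40.0,
                np.random.default_rng(seed))
            place = synthetic.gen_spikes(traj40, tuning, seed=seed)
            mfr = place.n_spikes / traj40.duration
            const = synthetic.gen_spikes(traj40, lambda x, y: mfr + 0 * x,
                                         seed=seed + 1000)
            si_p = maps.spatial_information(
                maps.rate_map(traj40, place, occ=occ), occ)
            si_c = maps.spatial_information(
                maps.rate_map(traj40, const, occ=occ), occ)
            wins += si_p > 3 * si_c
        assert wins >= 9


class TestCom:
    def test_central_bump(self):
        rate = np.zeros((20, 20))
        rate[9:11, 9:11] = 5.0
        rm = _ratemap_from_array(rate)
        res = maps.com_stats(rm)
        assert res.com == pytest.approx((20.0, 20.0))
        assert res.dist_from_center == pytest.approx(0.0)

    def test_identical_sessions_zero_shift(self):
        rate = np.random.default_rng(3).uniform(0, 5, size=(20, 20))
        rm = _ratemap_from_array(rate)
        assert maps.com_stats(rm, rm).shift == pytest.approx(0.0)

    def test_translated_bump_shift(self):
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[5:8, 5:8] = 4.0
        b[5:8, 8:11] = 4.0  # 3 bins right = 6 cm
        shift = maps.com_stats(_ratemap_from_array(a),
                               _ratemap_from_array(b)).shift
        assert shift == pytest.approx(6.0)

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError):
            maps.com_stats(_ratemap_from_array(np.zeros((5, 5))))


def test_fields_partition_valid_bins(small_mec_session):
    s = small_mec_session
    occ = maps.occupancy_map(s.trajectory, bin_size=2.0, extent=100.0)
    for train in list(s.spikes.values())[:4]:
        rm = maps.rate_map(s.trajectory, train, occ=occ, kernel_bins=10)
        fs = maps.detect_fields(rm)
        mask = fs.membership_mask(rm.rate.shape)
        assert not (mask & ~rm.valid).any()  # fields only on valid bins
        flat = [tuple(b) for f in fs.fields for b in f.tolist()]
        assert len(flat) == len(set(flat))  # disjoint
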