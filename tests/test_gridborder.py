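"""Autocorrelograms, grid scores, border scores, and their oracles."""

import numpy as np
import pytest

import spatialcode as sc
from spatialcode import gridborder, maps, synthetic


def _ratemap(rate, bin_size=2.0, valid=None):
    rate = np.asarray(rate, dtype=float)
    if valid is None:
        valid = np.ones_like(rate, dtype=bool)
    return maps.RateMap(rate=rate, bin_size=bin_size,
                        extent=bin_size * rate.shape[0], valid=valid)


def _pearson_lag_oracle(rate, valid, dy, dx):
    """Direct evaluation of the lagged product-moment correlation."""
    n = rate.shape[0]
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            ii, jj = i - dy, j - dx
            if 0 <= ii < n and 0 <= jj < n and valid[i, j] and valid[ii, jj]:
                xs.append(rate[i, j])
                ys.append(rate[ii, jj])
    if len(xs) < 20:
        return np.nan
    return np.corrcoef(xs, ys)[0, 1]


class TestAutocorrelation:
    def test_zero_lag_is_one(self):
        rng = np.random.default_rng(1)
        rm = _ratemap(rng.uniform(0, 5, size=(12, 12)))
        ac = gridborder.spatial_autocorrelation(rm)
        assert ac.r[ac.center] == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        rate = rng.uniform(0, 5, size=(10, 10))
        valid = rng.uniform(size=(10, 10)) > 0.1
        rm = _ratemap(rate, valid=valid)
        ac = gridborder.spatial_autocorrelation(rm)
        cy, cx = ac.center
        for dy, dx in ((0, 0), (1, 0), (0, 3), (-2, 2), (4, -1)):
            expected = _pearson_lag_oracle(rate, valid, dy, dx)
            got = ac.r[cy + dy, cx + dx]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-7)

    def test_stripes_periodicity(self):
        x = np.arange(30)
        rate = np.tile(2.0 + 2.0 * np.cos(2 * np.pi * x / 10), (30, 1))
        ac = gridborder.spatial_autocorrelation(_ratemap(rate))
        cy, cx = ac.center
        assert ac.r[cy, cx + 10] > 0.9
        assert ac.r[cy, cx + 5] < -0.9

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        rm = _ratemap(rng.uniform(0, 5, size=(11, 11)))
        ac = gridborder.spatial_autocorrelation(rm)
        flipped = ac.r[::-1, ::-1]
        both = np.isfinite(ac.r) & np.isfinite(flipped)
        assert np.allclose(ac.r[both], flipped[both], atol=1e-9)

    def test_too_few_valid_bins_rejected(self):
        rm = _ratemap(np.ones((4, 4)))
        with pytest.raises(ValueError):
            gridborder.spatial_autocorrelation(rm)


def _grid_map(n=50, bin_size=2.0, spacing=40.0, theta=0.1):
    xc = (np.arange(n) + 0.5) * bin_size
    X, Y = np.meshgrid(xc, xc)
    k = 4 * np.pi / (np.sqrt(3) * spacing)
    s = np.zeros_like(X)
    for a in (theta, theta + np.pi / 3, theta + 2 * np.pi / 3):
        s += np.cos(k * np.cos(a) * X + k * np.sin(a) * Y)
    return np.maximum(s, 0)


class TestGridScore:
    def test_ideal_grid_scores_high(self):
        ac = gridborder.spatial_autocorrelation(_ratemap(_grid_map()))
        gs = gridborder.grid_score(ac)
        assert gs.defined and gs.score > 0.5

    def test_rotationally_symmetric_autocorrelogram_scores_near_zero(self):
        # isotropic central bump + isotropic ring: every rotation correlates
        # equally, so six-fold symmetry cannot be detected
        n = 41
        yy, xx = np.indices((n, n))
        d = np.hypot(yy - n // 2, xx - n // 2)
        r = np.exp(-d ** 2 / (2 * 3.0 ** 2)) + 0.6 * np.exp(
            -(d - 12.0) ** 2 / (2 * 2.0 ** 2))
        ac = gridborder.Autocorrelogram(r=r, n_overlap=np.full((n, n), 100))
        gs = gridborder.grid_score(ac)
        assert gs.defined and abs(gs.score) < 0.05

    def test_single_plane_wave_scores_negative(self):
        x = np.arange(40)
        rate = np.tile(2.0 + 2.0 * np.cos(2 * np.pi * x / 12), (40, 1))
        gs = gridborder.grid_score(
            gridborder.spatial_autocorrelation(_ratemap(rate)))
        assert gs.defined and gs.score < 0

    def test_generator_grid_cell_scores_high(self, small_mec_session):
        s = small_mec_session
        occ = maps.occupancy_map(s.trajectory, bin_size=2.0, extent=100.0)
        scores = []
        for uid, lab in s.true_labels.items():
            if lab != "grid":
                continue
            rm = maps.rate_map(s.trajectory, s.spikes[uid], occ=occ,
                               kernel_bins=10)
            gs = gridborder.grid_score(
                gridborder.spatial_autocorrelation(rm))
            if gs.defined:
                scores.append(gs.score)
        assert scores and np.mean(scores) > 0.5


def _border_oracle(rmap, fields, extent):
    """Brute-force cM / dm re-evaluation from raw field bin lists."""
    n = rmap.rate.shape[0]
    cM = 0.0
    for f in fields.fields:
        for wall_bins, n_wall in (
                ([b for b in f if b[0] == 0], n),
                ([b for b in f if b[0] == n - 1], n),
                ([b for b in f if b[1] == 0], n),
                ([b for b in f if b[1] == n - 1], n)):
            cM = max(cM, len(wall_bins) / n_wall)
    num, den = 0.0, 0.0
    for f in fields.fields:
        for r, c in f:
            w = rmap.rate[r, c]
            d = min(r, n - 1 - r, c, n - 1 - c) * rmap.bin_size
            num += w * d
            den += w
    dm = (num / den) / (extent / 2.0)
    return cM, dm, (cM - dm) / (cM + dm)


class TestBorderScore:
    def test_full_wall_strip_scores_plus_one(self):
        rate = np.zeros((20, 20))
        rate[0, :] = 5.0
        rm = _ratemap(rate)
        bs = gridborder.border_score(rm, maps.detect_fields(rm))
        assert bs.b == pytest.approx(1.0)
        assert bs.cM == pytest.approx(1.0) and bs.dm == pytest.approx(0.0)

    def test_central_field_scores_minus_one(self):
        rate = np.zeros((20, 20))
        rate[8:12, 8:12] = 5.0
        rm = _ratemap(rate)
        bs = gridborder.border_score(rm, maps.detect_fields(rm))
        assert bs.b == pytest.approx(-1.0)
        assert bs.cM == pytest.approx(0.0)

    def test_half_wall_coverage_hand_values(self):
        # field: one-bin strip along half of the top wall -> cM=0.5, dm=0
        rate = np.zeros((20, 20))
        rate[0, :10] = 5.0
        rm = _ratemap(rate)
        bs = gridborder.border_score(rm, maps.detect_fields(rm))
        assert bs.b == pytest.approx(1.0)  # (0.5 - 0) / (0.5 + 0)
        # same strip shifted to dm fraction 0.25: rows at 5 bins from wall
        # would break wall contact, so widen: strip spanning rows 0..10 at
        # uniform rate gives cM = 0.5 (10/20 columns) and dm from the rows
        rate2 = np.zeros((20, 20))
        rate2[0:11, :10] = 5.0
        rm2 = _ratemap(rate2)
        fs2 = maps.detect_fields(rm2)
        bs2 = gridborder.border_score(rm2, fs2)
        cM, dm, b = _border_oracle(rm2, fs2, rm2.extent)
        assert bs2.b == pytest.approx(b, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        checked = 0
        for _ in range(10):
            rate = rng.uniform(0, 10, size=(16, 16))
            rate[rate < 5] = 0.0
            rm = _ratemap(rate)
            fs = maps.detect_fields(rm)
            if fs.n_fields == 0:
                continue
            bs = gridborder.border_score(rm, fs)
            cM, dm, b = _border_oracle(rm, fs, rm.extent)
            assert bs.cM == pytest.approx(cM, abs=1e-12)
            assert bs.dm == pytest.approx(dm, abs=1e-12)
            assert bs.b == pytest.approx(b, abs=1e-12)
            checked += 1
        assert checked >= 3

    def test_no_fields_undefined(self):
        rm = _ratemap(np.zeros((20, 20)))
        bs = gridborder.border_score(rm, maps.detect_fields(rm))
        assert not bs.defined

    def test_border_cells_outscore_grid_cells(self, small_mec_session):
        s = small_mec_session
        occ = maps.occupancy_map(s.trajectory, bin_size=2.0, extent=100.0)
        by_type = {"border": [], "grid": []}
        for uid, lab in s.true_labels.items():
            if lab not in by_type:
                continue
            rm = maps.rate_map(s.trajectory, s.spikes[uid], occ=occ,
                               kernel_bins=10)
            bs = gridborder.border_score(rm, maps.detect_fields(rm))
            if bs.defined:
                by_type[lab].append(bs.b)
        assert np.mean(by_type["border"]) > np.mean(by_type["grid"])


class TestAcPca:
    def _acs_from_maps(self, mats):
        return [gridborder.spatial_autocorrelation(_ratemap(m))
                for m in mats]

    def test_identical_inputs_give_zero_scores(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 5, size=(12, 12))
        acs = self._acs_from_maps([m] * 5)
        scores, ev = gridborder.ac_principal_components(acs, k=3)
        assert np.allclose(scores, 0.0, atol=1e-9)

    def test_two_archetypes_separated_by_pc1(self):
        rng = np.random.default_rng(5)
        grid = _grid_map(n=20, spacing=20.0)
        stripe = np.tile(2 + 2 * np.cos(2 * np.pi * np.arange(20) / 8),
                         (20, 1))
        mats = [grid + rng.normal(0, 0.05, grid.shape) for _ in range(5)] + \
               [stripe + rng.normal(0, 0.05, stripe.shape) for _ in range(5)]
        acs = self._acs_from_maps(mats)
        scores, ev = gridborder.ac_principal_components(acs, k=3)
        assert ev[0] > 0.5
        a, b = scores[:5, 0], scores[5:, 0]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_output_arity_and_rank_guard(self):
        rng = np.random.default_rng(6)
        acs = self._acs_from_maps(
            [rng.uniform(0, 5, size=(10, 10)) for _ in range(6)])
        scores, ev = gridborder.ac_principal_components(acs, k=3)
        assert scores.shape == (6, 3) and ev.shape == (3,)
        with pytest.raises(ValueError):
            gridborder.ac_principal_components(acs[:3], k=3)
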