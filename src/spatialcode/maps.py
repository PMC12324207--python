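"""Occupancy and firing-rate maps, firing fields, and per-unit spatial metrics.

The substrate of the spatial analyses is the binned firing-rate map: the
arena is divided into square bins (2 x 2 cm by default), per-bin firing
rate is the spike count divided by dwell time, bins occupied for less than
0.1 s are excluded, and the map is smoothed with a Gaussian kernel (5 x 5
bins for CA1 sessions, 10 x 10 for MEC sessions).  Firing fields are
connected groups of at least 8 edge-adjacent bins whose rate is at least
20% of the unit's peak rate.  From map and fields we derive mean firing
rates (overall / in-field / out-of-field), the spatial-information rate in
bits/s, total field area, and the rate-weighted center of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Trajectory",
    "SpikeTrain",
    "OccupancyMap",
    "RateMap",
    "FieldSet",
    "RateMetrics",
    "ComResult",
    "occupancy_map",
    "rate_map",
    "detect_fields",
    "rate_metrics",
    "spatial_information",
    "com_stats",
    "MIN_DWELL_S",
    "FIELD_RATE_FRACTION",
    "FIELD_MIN_BINS",
]

#: Minimum per-bin dwell time (s); bins below are excluded from analysis.
MIN_DWELL_S = 0.1
#: Field bins must reach this fraction of the unit's peak rate.
FIELD_RATE_FRACTION = 0.2
#: Minimum number of contiguous bins forming a firing field.
FIELD_MIN_BINS = 8


@dataclass
class Trajectory:
    """Position tracking: timestamps (s) and x/y positions (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size == 0:
            raise ValueError("empty trajectory")
        if self.t.size != self.x.size or self.t.size != self.y.size:
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("positions must be finite")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def speed(self) -> np.ndarray:
        """Instantaneous speed (cm/s) from finite differences, length n-1."""
        dt = np.diff(self.t)
        return np.hypot(np.diff(self.x), np.diff(self.y)) / dt

    def position_at(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated position at arbitrary times."""
        times = np.asarray(times, dtype=float)
        return np.interp(times, self.t, self.x), np.interp(times, self.t, self.y)


@dataclass
class SpikeTrain:
    """Sorted spike times (s) for one unit."""

    unit_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            self.spike_times = np.sort(self.spike_times)
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("spike times must be non-negative")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class OccupancyMap:
    """Per-bin dwell time (s) with a validity mask (dwell >= 0.1 s)."""

    dwell: np.ndarray
    bin_size: float
    extent: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dwell = np.asarray(self.dwell, dtype=float)
        if self.valid is None:
            self.valid = self.dwell >= MIN_DWELL_S

    @property
    def n_bins(self) -> int:
        return self.dwell.shape[0]

    def probability(self) -> np.ndarray:
        """Occupancy probability p(x_i), renormalized over valid bins."""
        p = np.where(self.valid, self.dwell, 0.0)
        total = p.sum()
        if total <= 0:
            raise ValueError("no valid occupancy")
        return p / total


@dataclass
class RateMap:
    """Binned firing rate (Hz); invalid bins are excluded from statistics."""

    rate: np.ndarray
    bin_size: float
    extent: float
    valid: np.ndarray
    smoothing_kernel: int = 0

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def peak_rate(self) -> float:
        vals = self.rate[self.valid]
        return float(vals.max()) if vals.size else 0.0

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centers; rate[i, j] covers x-bin i (columns) / y-bin j? No:
        rate[row, col] with row = y index, col = x index, 0-based, half-open
        bins [k*b, (k+1)*b)."""
        n_rows, n_cols = self.rate.shape
        xc = (np.arange(n_cols) + 0.5) * self.bin_size
        yc = (np.arange(n_rows) + 0.5) * self.bin_size
        return xc, yc


@dataclass
class FieldSet:
    """Firing fields: connected components of supra-threshold bins."""

    fields: list[np.ndarray]  # each an (n, 2) array of (row, col) indices
    areas: np.ndarray  # cm^2 per field
    peak_rate: float
    threshold_rate: float
    bin_size: float

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum()) if self.n_fields else 0.0

    def membership_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for f in self.fields:
            mask[f[:, 0], f[:, 1]] = True
        return mask


@dataclass
class RateMetrics:
    """Summary firing-rate metrics for one unit."""

    mfr: float
    infield_mfr: float
    outfield_mfr: float
    in_out_index: float  # NaN when out-of-field MFR is zero (flagged)
    si: float
    field_area: float
    infield_peak: float = float("nan")
    index_defined: bool = True
    silent: bool = False


@dataclass
class ComResult:
    """Rate-weighted center of mass and derived distances."""

    com: tuple[float, float]
    dist_from_center: float
    shift: float | None = None


def occupancy_map(traj: Trajectory, bin_size: float = 2.0,
                  extent: float | None = None) -> OccupancyMap:
    """Bin dwell time on a square grid and mark bins with >= 0.1 s occupancy.

    Each tracking frame contributes its frame duration to the bin containing
    the sample; bin intervals are half-open [k*b, (k+1)*b).
    """
    if extent is None:
        extent = float(max(traj.x.max(), traj.y.max()))
    n = int(np.ceil(extent / bin_size))
    dt = np.empty_like(traj.t)
    dt[:-1] = np.diff(traj.t)
    dt[-1] = dt[-2] if traj.t.size > 1 else 1.0 / traj.sample_rate
    col = np.clip((traj.x // bin_size).astype(int), 0, n - 1)
    row = np.clip((traj.y // bin_size).astype(int), 0, n - 1)
    dwell = np.zeros((n, n))
    np.add.at(dwell, (row, col), dt)
    return OccupancyMap(dwell=dwell, bin_size=bin_size, extent=extent)


def _masked_gaussian_smooth(rate: np.ndarray, valid: np.ndarray,
                            kernel_bins: int) -> np.ndarray:
    """Gaussian smoothing restricted to valid bins.

    sd = kernel_bins / 5 (1 bin for a 5x5 kernel, 2 for 10x10), truncated at
    the kernel extent; weights renormalized over the valid support so that
    excluded bins neither receive nor contribute rate.
    """
    sd = kernel_bins / 5.0
    radius = kernel_bins // 2
    truncate = radius / sd if sd > 0 else 0.0
    num = ndimage.gaussian_filter(np.where(valid, rate, 0.0), sigma=sd,
                                  truncate=truncate, mode="constant")
    den = ndimage.gaussian_filter(valid.astype(float), sigma=sd,
                                  truncate=truncate, mode="constant")
    out = np.zeros_like(rate)
    np.divide(num, den, out=out, where=den > 0)
    return np.where(valid, out, 0.0)


def rate_map(traj: Trajectory, spikes: SpikeTrain, bin_size: float = 2.0,
             extent: float | None = None, kernel_bins: int = 5,
             occ: OccupancyMap | None = None) -> RateMap:
    """Per-bin firing rate = spike count / dwell, then Gaussian smoothing.

    Spike positions are obtained by linear interpolation of the 30 Hz
    tracking at each spike time.  ``kernel_bins=0`` disables smoothing.
    """
    if occ is None:
        occ = occupancy_map(traj, bin_size=bin_size, extent=extent)
    bin_size = occ.bin_size
    n = occ.dwell.shape[0]
    st = spikes.spike_times
    if st.size and (st[0] < traj.t[0] - 1e-9 or st[-1] > traj.t[-1] + 1e-9):
        raise ValueError(
            f"unit {spikes.unit_id}: spikes outside trajectory span")
    counts = np.zeros_like(occ.dwell)
    if st.size:
        sx, sy = traj.position_at(st)
        col = np.clip((sx // bin_size).astype(int), 0, n - 1)
        row = np.clip((sy // bin_size).astype(int), 0, n - 1)
        np.add.at(counts, (row, col), 1.0)
    rate = np.zeros_like(occ.dwell)
    np.divide(counts, occ.dwell, out=rate, where=occ.valid)
    if kernel_bins > 1:
        rate = _masked_gaussian_smooth(rate, occ.valid, kernel_bins)
    return RateMap(rate=rate, bin_size=bin_size, extent=occ.extent,
                   valid=occ.valid.copy(), smoothing_kernel=kernel_bins)


# 4-connectivity: field bins must share an edge
_EDGE_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def detect_fields(rmap: RateMap, rate_fraction: float = FIELD_RATE_FRACTION,
                  min_bins: int = FIELD_MIN_BINS) -> FieldSet:
    """Firing fields: edge-connected components of bins >= 20% of peak rate,
    keeping only components of at least 8 bins."""
    peak = rmap.peak_rate
    threshold = rate_fraction * peak
    fields: list[np.ndarray] = []
    if peak > 0:
        supra = rmap.valid & (rmap.rate >= threshold) & (rmap.rate > 0)
        labeled, n_comp = ndimage.label(supra, structure=_EDGE_STRUCTURE)
        for k in range(1, n_comp + 1):
            rows, cols = np.nonzero(labeled == k)
            if rows.size >= min_bins:
                fields.append(np.column_stack([rows, cols]))
    areas = np.array([f.shape[0] * rmap.bin_size ** 2 for f in fields])
    return FieldSet(fields=fields, areas=areas, peak_rate=peak,
                    threshold_rate=threshold, bin_size=rmap.bin_size)


def rate_metrics(rmap: RateMap, fields: FieldSet, spikes: SpikeTrain,
                 duration: float, occ: OccupancyMap | None = None) -> RateMetrics:
    """Overall/in-field/out-of-field mean rates, their ratio, SI, field area.

    The overall MFR is session spike count / session duration.  In-field and
    out-of-field MFRs are plain means of the map over field bins and over
    valid non-field bins.  When the out-of-field MFR is zero the ratio is
    reported as NaN and flagged rather than as infinity.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    mfr = spikes.n_spikes / duration
    infield_mask = fields.membership_mask(rmap.rate.shape)
    outfield_mask = rmap.valid & ~infield_mask
    infield_vals = rmap.rate[infield_mask]
    infield_mfr = float(infield_vals.mean()) if infield_vals.size else 0.0
    infield_peak = float(infield_vals.max()) if infield_vals.size else 0.0
    out_vals = rmap.rate[outfield_mask]
    outfield_mfr = float(out_vals.mean()) if out_vals.size else 0.0
    if outfield_mfr > 0:
        index, defined = infield_mfr / outfield_mfr, True
    else:
        index, defined = float("nan"), False
    si, silent = (0.0, True)
    if occ is not None:
        si, silent = _si_with_flag(rmap, occ)
    return RateMetrics(mfr=mfr, infield_mfr=infield_mfr,
                       outfield_mfr=outfield_mfr, in_out_index=index,
                       si=si, field_area=fields.total_area,
                       infield_peak=infield_peak, index_defined=defined,
                       silent=silent)


def _si_with_flag(rmap: RateMap, occ: OccupancyMap) -> tuple[float, bool]:
    p = occ.probability()[rmap.valid]
    f = rmap.rate[rmap.valid]
    F = float(np.sum(p * f))
    if F <= 0:
        return 0.0, True
    pos = f > 0
    return float(np.sum(p[pos] * f[pos] * np.log2(f[pos] / F))), False


def spatial_information(rmap: RateMap, occ: OccupancyMap) -> float:
    """Spatial-information rate I = sum_i p(x_i) f(x_i) log2(f(x_i)/F) in
    bits/s, with F = sum_i p(x_i) f(x_i) the overall rate.

    p is the occupancy probability renormalized over valid bins; bins with
    zero rate contribute zero.  A silent unit (F = 0) yields 0.
    """
    si, _ = _si_with_flag(rmap, occ)
    return si


def com_stats(map_a: RateMap, map_b: RateMap | None = None,
              extent: float | None = None) -> ComResult:
    """Rate-weighted center of mass, its distance from the arena center,
    and (given a second session's map) the inter-session COM shift."""
    extent = extent if extent is not None else map_a.extent

    def _com(m: RateMap) -> tuple[float, float]:
        w = np.where(m.valid, m.rate, 0.0)
        total = w.sum()
        if total <= 0:
            raise ValueError("COM undefined for an all-zero map")
        xc, yc = m.bin_centers()
        return (float((w.sum(axis=0) * xc).sum() / total),
                float((w.sum(axis=1) * yc).sum() / total))

    com_a = _com(map_a)
    center = (extent / 2.0, extent / 2.0)
    dist = float(np.hypot(com_a[0] - center[0], com_a[1] - center[1]))
    shift = None
    if map_b is not None:
        if map_b.rate.shape != map_a.rate.shape:
            raise ValueError("session maps must share grid geometry")
        com_b = _com(map_b)
        shift = float(np.hypot(com_a[0] - com_b[0], com_a[1] - com_b[1]))
    return ComResult(com=com_a, dist_from_center=dist, shift=shift)
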