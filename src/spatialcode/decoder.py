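"""Bayesian two-step position decoding with a Gaussian continuity constraint.

The decoder discretizes the arena into a ``grid_n x grid_n`` grid (60 bins
per side by default; 0.67 cm bins in a 40 cm chamber), builds per-unit
encoding rate maps f_i(x) from a 10-min encoding period (smoothed with a
5 x 5 Gaussian of sd 1 bin), and reconstructs position over a 1-min
decoding period with a sliding window (width 1.5 s, step 0.1 s).  Within
each window with spike counts n_i the posterior is

    P(x | n) ∝ P(x) · Π_i f_i(x)^{n_i} · exp(-τ Σ_i f_i(x))

evaluated in the log domain, multiplied by a Gaussian continuity prior
exp(-‖x_{t-1} - x‖² / 2σ_t²) centered on the previous estimate, with
σ_t = K · V^d and V the movement speed implied by the two preceding
estimates (K = 12, d = 1 by default).  The estimate x̂ is the argmax bin
center; per-window error is the Euclidean distance to the true position at
the window center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .maps import SpikeTrain, Trajectory

__all__ = ["DecoderConfig", "PosteriorMap", "DecodedPath",
           "BayesianDecoder", "decode_path", "posterior"]


@dataclass
class DecoderConfig:
    grid_n: int = 60
    window: float = 1.5
    step: float = 0.1
    encode_span: float = 600.0
    decode_span: float = 60.0
    smooth_size: int = 5
    smooth_sd: float = 1.0
    K: float = 12.0
    d: float = 1.0
    rate_floor: float = 0.01  # Hz; avoids zero-probability lockout
    speed_floor: float = 0.25  # cm/s; keeps the continuity prior proper

    def __post_init__(self) -> None:
        if not (self.window > self.step > 0):
            raise ValueError("require window > step > 0")
        if self.grid_n < 2:
            raise ValueError("grid_n must be at least 2")
        if self.K <= 0:
            raise ValueError("K must be positive")


@dataclass
class PosteriorMap:
    """Normalized position probability over the decoding grid."""

    p: np.ndarray
    window_center: float = float("nan")


@dataclass
class DecodedPath:
    t: np.ndarray
    x_hat: np.ndarray
    y_hat: np.ndarray
    x_true: np.ndarray
    y_true: np.ndarray
    errors: np.ndarray

    @property
    def mean_error(self) -> float:
        return float(self.errors.mean())


def _log_posterior(counts: np.ndarray, log_f: np.ndarray,
                   sum_f: np.ndarray, tau: float,
                   log_prior: np.ndarray | None) -> np.ndarray:
    ll = counts @ log_f.reshape(len(counts), -1)
    ll = ll.reshape(sum_f.shape) - tau * sum_f
    if log_prior is not None:
        ll = ll + log_prior
    return ll


def _normalize(log_p: np.ndarray) -> np.ndarray:
    log_p = log_p - log_p.max()
    p = np.exp(log_p)
    return p / p.sum()


def posterior(counts: np.ndarray, rate_maps: np.ndarray, tau: float,
              log_prior: np.ndarray | None = None) -> PosteriorMap:
    """Single-window posterior P(x|n) for spike counts ``counts`` against
    per-unit rate maps ``rate_maps`` of shape (n_units, grid_n, grid_n)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    log_f = np.log(rate_maps)
    sum_f = rate_maps.sum(axis=0)
    lp = _log_posterior(counts, log_f, sum_f, tau, log_prior)
    return PosteriorMap(p=_normalize(lp))


class BayesianDecoder(BaseEstimator):
    """Scikit-learn style estimator around the two-step decoder.

    ``fit(traj, spikes)`` builds the encoding model from the first
    ``encode_span`` seconds; ``predict(traj, spikes)`` reconstructs the
    path over the following ``decode_span`` seconds.  Set ``K=np.inf`` to
    disable the continuity constraint (pure one-step decoding).

    Attributes (after ``fit``)
    --------------------------
    rate_maps_ : (n_units, grid_n, grid_n) floored encoding maps, Hz.
    unit_ids_ : units retained (silent encoding units are dropped).
    mean_speed_ : encoding-period mean running speed, cm/s (V fallback).
    """

    def __init__(self, grid_n: int = 60, window: float = 1.5,
                 step: float = 0.1, encode_span: float = 600.0,
                 decode_span: float = 60.0, smooth_size: int = 5,
                 smooth_sd: float = 1.0, K: float = 12.0, d: float = 1.0,
                 rate_floor: float = 0.01, speed_floor: float = 0.25,
                 arena_side: float | None = None):
        self.grid_n = grid_n
        self.window = window
        self.step = step
        self.encode_span = encode_span
        self.decode_span = decode_span
        self.smooth_size = smooth_size
        self.smooth_sd = smooth_sd
        self.K = K
        self.d = d
        self.rate_floor = rate_floor
        self.speed_floor = speed_floor
        self.arena_side = arena_side

    # -- encoding ---------------------------------------------------------
    def fit(self, traj: Trajectory, spikes: dict[str, SpikeTrain]):
        if self.encode_span < 2 * self.window:
            raise ValueError("encoding span must cover at least two windows")
        L = self.arena_side or float(max(traj.x.max(), traj.y.max()))
        self.arena_side_ = L
        self.bin_size_ = L / self.grid_n
        t0 = traj.t[0]
        enc_end = t0 + self.encode_span
        sel = traj.t < enc_end
        if traj.duration < self.encode_span + self.decode_span:
            raise ValueError(
                "session shorter than encoding + decoding span")
        ex, ey, et = traj.x[sel], traj.y[sel], traj.t[sel]
        dt = np.empty_like(et)
        dt[:-1] = np.diff(et)
        dt[-1] = dt[-2]
        col = np.clip((ex / self.bin_size_).astype(int), 0, self.grid_n - 1)
        row = np.clip((ey / self.bin_size_).astype(int), 0, self.grid_n - 1)
        dwell = np.zeros((self.grid_n, self.grid_n))
        np.add.at(dwell, (row, col), dt)

        truncate = ((self.smooth_size - 1) / 2) / self.smooth_sd
        maps, kept, dropped = [], [], []
        for uid, train in spikes.items():
            st = train.spike_times
            st = st[(st >= t0) & (st < enc_end)]
            if st.size == 0:
                dropped.append(uid)
                continue
            sx = np.interp(st, et, ex)
            sy = np.interp(st, et, ey)
            c = np.clip((sx / self.bin_size_).astype(int), 0, self.grid_n - 1)
            r = np.clip((sy / self.bin_size_).astype(int), 0, self.grid_n - 1)
            counts = np.zeros_like(dwell)
            np.add.at(counts, (r, c), 1.0)
            rate = np.zeros_like(dwell)
            np.divide(counts, dwell, out=rate, where=dwell > 0)
            rate = ndimage.gaussian_filter(rate, sigma=self.smooth_sd,
                                           truncate=truncate)
            maps.append(np.maximum(rate, self.rate_floor))
            kept.append(uid)
        if not maps:
            raise RuntimeError("no units with encoding spikes; cannot decode")
        self.rate_maps_ = np.asarray(maps)
        self.unit_ids_ = kept
        self.dropped_units_ = dropped
        sp = np.hypot(np.diff(ex), np.diff(ey)) / np.diff(et)
        self.mean_speed_ = float(sp.mean())
        return self

    # -- decoding ---------------------------------------------------------
    def predict(self, traj: Trajectory, spikes: dict[str, SpikeTrain]
                ) -> DecodedPath:
        if not hasattr(self, "rate_maps_"):
            raise RuntimeError("decoder is not fitted")
        tau = self.window
        t0 = traj.t[0]
        dec_start = t0 + self.encode_span
        dec_end = min(dec_start + self.decode_span, traj.t[-1])
        centers = np.arange(dec_start + tau / 2, dec_end - tau / 2 + 1e-9,
                            self.step)
        n_w = centers.size
        n_units = len(self.unit_ids_)
        counts = np.empty((n_w, n_units))
        for j, uid in enumerate(self.unit_ids_):
            st = spikes[uid].spike_times
            lo = np.searchsorted(st, centers - tau / 2, side="left")
            hi = np.searchsorted(st, centers + tau / 2, side="left")
            counts[:, j] = hi - lo

        log_f = np.log(self.rate_maps_).reshape(n_units, -1)
        sum_f = self.rate_maps_.sum(axis=0).ravel()
        log_like = counts @ log_f - tau * sum_f  # (n_w, grid_n^2)

        n = self.grid_n
        b = self.bin_size_
        xc = (np.arange(n) + 0.5) * b
        yc = (np.arange(n) + 0.5) * b
        XX, YY = np.meshgrid(xc, yc)  # row = y, col = x
        xb, yb = XX.ravel(), YY.ravel()

        use_continuity = np.isfinite(self.K)
        est_x = np.empty(n_w)
        est_y = np.empty(n_w)
        prev: list[tuple[float, float]] = []
        for i in range(n_w):
            lp = log_like[i].copy()
            if use_continuity and prev:
                if len(prev) >= 2:
                    V = np.hypot(prev[-1][0] - prev[-2][0],
                                 prev[-1][1] - prev[-2][1]) / self.step
                else:
                    V = self.mean_speed_
                # V floored at a sub-movement speed so a momentarily static
                # estimate cannot collapse the prior to a delta function
                V = max(V, self.speed_floor)
                sigma = self.K * V ** self.d
                lp = lp - ((xb - prev[-1][0]) ** 2
                           + (yb - prev[-1][1]) ** 2) / (2 * sigma ** 2)
            k = int(np.argmax(lp))  # ties: lowest linear bin index
            est_x[i], est_y[i] = xb[k], yb[k]
            prev.append((est_x[i], est_y[i]))

        tx = np.interp(centers, traj.t, traj.x)
        ty = np.interp(centers, traj.t, traj.y)
        errors = np.hypot(est_x - tx, est_y - ty)
        return DecodedPath(t=centers, x_hat=est_x, y_hat=est_y,
                           x_true=tx, y_true=ty, errors=errors)

    def posteriors(self, traj: Trajectory, spikes: dict[str, SpikeTrain]
                   ) -> list[PosteriorMap]:
        """Per-window normalized posteriors of the two-step decoder."""
        if not hasattr(self, "rate_maps_"):
            raise RuntimeError("decoder is not fitted")
        tau = self.window
        dec_start = traj.t[0] + self.encode_span
        dec_end = min(dec_start + self.decode_span, traj.t[-1])
        centers = np.arange(dec_start + tau / 2, dec_end - tau / 2 + 1e-9,
                            self.step)
        path = self.predict(traj, spikes)
        n = self.grid_n
        b = self.bin_size_
        xc = (np.arange(n) + 0.5) * b
        XX, YY = np.meshgrid(xc, xc)
        out = []
        log_f = np.log(self.rate_maps_)
        sum_f = self.rate_maps_.sum(axis=0)
        for i, c in enumerate(centers):
            cts = np.array([
                np.searchsorted(spikes[u].spike_times, c + tau / 2, "left")
                - np.searchsorted(spikes[u].spike_times, c - tau / 2, "left")
                for u in self.unit_ids_], dtype=float)
            lp = _log_posterior(cts, log_f, sum_f, tau, None)
            if np.isfinite(self.K) and i >= 1:
                if i >= 2:
                    V = np.hypot(path.x_hat[i - 1] - path.x_hat[i - 2],
                                 path.y_hat[i - 1] - path.y_hat[i - 2]) / self.step
                else:
                    V = self.mean_speed_
                sigma = self.K * max(V, self.speed_floor) ** self.d
                lp = lp - ((XX - path.x_hat[i - 1]) ** 2
                           + (YY - path.y_hat[i - 1]) ** 2) / (2 * sigma ** 2)
            out.append(PosteriorMap(p=_normalize(lp), window_center=float(c)))
        return out


def decode_path(traj: Trajectory, spikes: dict[str, SpikeTrain],
                config: DecoderConfig | None = None,
                arena_side: float | None = None) -> DecodedPath:
    """Fit the encoding model and reconstruct the decoding-period path."""
    cfg = config or DecoderConfig()
    dec = BayesianDecoder(grid_n=cfg.grid_n, window=cfg.window,
                          step=cfg.step, encode_span=cfg.encode_span,
                          decode_span=cfg.decode_span,
                          smooth_size=cfg.smooth_size,
                          smooth_sd=cfg.smooth_sd, K=cfg.K, d=cfg.d,
                          rate_floor=cfg.rate_floor,
                          speed_floor=cfg.speed_floor,
                          arena_side=arena_side)
    dec.fit(traj, spikes)
    return dec.predict(traj, spikes)
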