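"""LFP band power during movement: bout detection, PSD, band AUC.

Band powers are quantified as the area under the Welch power spectral
density within each configured band — theta 4-12 Hz, beta 20-30 Hz,
gamma1 30-50 Hz, gamma2 50-90 Hz, gamma3 90-150 Hz — computed on
fixed-length bouts of movement (smoothed running speed above threshold
sustained for a minimum duration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .maps import Trajectory
from .synthetic import LfpSignal

__all__ = ["DEFAULT_BANDS", "BandPower", "detect_movement_bouts",
           "band_power", "psd"]

#: name -> (low Hz, high Hz).  gamma1 follows the 30-50 Hz convention.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 12.0),
    "beta": (20.0, 30.0),
    "gamma1": (30.0, 50.0),
    "gamma2": (50.0, 90.0),
    "gamma3": (90.0, 150.0),
}


@dataclass
class BandPower:
    band: str
    low: float
    high: float
    auc: float
    bout_id: int


def detect_movement_bouts(traj: Trajectory, speed_thresh: float = 2.0,
                          min_dur: float = 1.0, bout_len: float = 5.0
                          ) -> list[tuple[float, float]]:
    """Epochs of sustained movement, standardized to fixed-length bouts.

    Speed is smoothed (0.5 s Gaussian), thresholded, and runs above
    threshold lasting at least ``min_dur`` are tiled into non-overlapping
    ``bout_len`` windows (a run shorter than ``bout_len`` but at least
    ``min_dur`` yields no standardized bout unless ``bout_len <= min_dur``).
    """
    sp = traj.speed()
    sp = ndimage.gaussian_filter1d(sp, sigma=0.5 * traj.sample_rate)
    moving = sp > speed_thresh
    bouts: list[tuple[float, float]] = []
    # runs of consecutive moving samples
    edges = np.diff(moving.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if moving.size and moving[0]:
        starts.insert(0, 0)
    if moving.size and moving[-1]:
        stops.append(moving.size)
    for s, e in zip(starts, stops):
        t_start, t_end = traj.t[s], traj.t[min(e, traj.t.size - 1)]
        if t_end - t_start < min_dur:
            continue
        t = t_start
        while t + bout_len <= t_end + 1e-9:
            bouts.append((t, t + bout_len))
            t += bout_len
    if not bouts:
        warnings.warn("no movement bouts found")
    return bouts


def psd(lfp: LfpSignal, t_start: float | None = None,
        t_end: float | None = None, window_s: float = 1.0
        ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD (1 s Hann windows, 50% overlap) of an LFP segment."""
    fs = lfp.sample_rate
    i0 = 0 if t_start is None else int(round(t_start * fs))
    i1 = lfp.samples.size if t_end is None else int(round(t_end * fs))
    seg = lfp.samples[i0:i1]
    nperseg = int(round(window_s * fs))
    if seg.size < 2 * nperseg:
        raise ValueError("segment shorter than two PSD windows")
    return signal.welch(seg, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2)


def band_power(lfp: LfpSignal, bouts: list[tuple[float, float]] | None = None,
               bands: dict[str, tuple[float, float]] | None = None
               ) -> list[BandPower]:
    """Per-bout, per-band area under the PSD.

    ``bouts=None`` analyzes the whole trace as a single bout.  Bouts too
    short for two PSD windows are skipped with a warning.
    """
    bands = bands or DEFAULT_BANDS
    top = max(high for _, high in bands.values())
    if lfp.sample_rate < 2 * top:
        raise ValueError("sample rate below Nyquist for the top band edge")
    if bouts is None:
        bouts = [(0.0, lfp.samples.size / lfp.sample_rate)]
    out: list[BandPower] = []
    for bout_id, (t0, t1) in enumerate(bouts):
        try:
            freqs, pxx = psd(lfp, t0, t1)
        except ValueError:
            warnings.warn(f"bout {bout_id} shorter than two PSD windows; "
                          "skipped")
            continue
        for name, (low, high) in bands.items():
            sel = (freqs >= low) & (freqs <= high)
            auc = float(np.trapezoid(pxx[sel], freqs[sel])) if sel.sum() > 1 else 0.0
            out.append(BandPower(band=name, low=low, high=high, auc=auc,
                                 bout_id=bout_id))
    return out
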