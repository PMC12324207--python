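"""Ground-truth-labeled synthetic sessions: trajectories, spikes, LFP, images.

Every downstream stage of the package is exercised on data from this module,
which emulates the statistical structure of open-field tetrode recordings:

* a smooth random-walk trajectory (mean-reverting Ornstein-Uhlenbeck
  velocity, reflecting walls) sampled at 30 Hz inside a square arena
  (40 cm for CA1-style sessions, 100 cm for MEC-style sessions);
* inhomogeneous-Poisson spike trains generated by thinning against a
  tuning function evaluated along the path — isotropic Gaussian place
  fields, three-cosine hexagonal grid fields rectified at zero, wall-locked
  exponentially decaying border fields, and weakly modulated high-rate
  interneurons;
* LFP as a sum of narrow-band oscillations (theta/beta/gamma) on a
  1/f-shaped noise floor;
* fluorescence-style images of curvilinear bright vessels with optional
  bright circular artifacts, together with the noiseless ground-truth mask.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .maps import SpikeTrain, Trajectory

__all__ = [
    "SyntheticConfig",
    "SyntheticSession",
    "LfpSignal",
    "gen_trajectory",
    "gen_spikes",
    "gen_lfp",
    "gen_vessel_image",
    "gen_session",
    "make_tuning",
    "DEFAULT_TUNING",
    "DEFAULT_LFP_SPEC",
    "DEFAULT_IMAGE_SPEC",
    "ca1_config",
    "mec_config",
]

#: Default tuning parameters per cell type (cm, Hz).
DEFAULT_TUNING: dict[str, dict] = {
    "place": {"peak_rate": 10.0, "width": 4.0},
    "grid": {"peak_rate": 15.0, "spacing": 40.0},
    "border": {"peak_rate": 10.0, "decay": 8.0},
    "interneuron": {"base_rate": 15.0, "modulation": 0.2},
    "aperiodic_spatial": {"peak_rate": 8.0, "width": 10.0},
}

#: (center Hz, amplitude, bandwidth Hz) — theta, beta, gamma1..3 components.
DEFAULT_LFP_SPEC: list[tuple[float, float, float]] = [
    (8.0, 1.0, 1.0),
    (25.0, 0.35, 2.0),
    (40.0, 0.2, 3.0),
    (70.0, 0.15, 5.0),
    (120.0, 0.1, 8.0),
]

DEFAULT_IMAGE_SPEC: dict = {
    "shape": (256, 256),
    "vessel_count": 3,
    "vessel_width": 9,
    "artifact_count": 2,
    "artifact_radius": 6,
    "noise_sd": 0.03,
}


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic recording session."""

    seed: int = 0
    arena_side: float = 40.0
    duration: float = 600.0
    sample_rate: float = 30.0
    mean_speed: float = 8.0  # cm/s, target of the OU velocity process
    persistence: float = 0.7  # s, velocity autocorrelation time
    cell_counts: dict[str, int] = dc_field(
        default_factory=lambda: {"place": 30})
    tuning_params: dict[str, dict] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TUNING.items()})
    lfp_spec: list[tuple[float, float, float]] = dc_field(
        default_factory=lambda: list(DEFAULT_LFP_SPEC))
    lfp_sample_rate: float = 1000.0
    lfp_noise_amp: float = 0.2
    image_spec: dict = dc_field(
        default_factory=lambda: dict(DEFAULT_IMAGE_SPEC))
    n_images: int = 0

    def __post_init__(self) -> None:
        if self.arena_side <= 0:
            raise ValueError("arena_side must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def ca1_config(seed: int = 0, **kw) -> SyntheticConfig:
    """CA1-style session: 40 cm arena, 20 min, place cells + interneurons."""
    kw.setdefault("cell_counts", {"place": 30, "interneuron": 10})
    kw.setdefault("duration", 1200.0)
    return SyntheticConfig(seed=seed, arena_side=40.0, **kw)


def mec_config(seed: int = 0, **kw) -> SyntheticConfig:
    """MEC-style session: 100 cm arena, 15 min, the four MEC cell classes."""
    kw.setdefault("cell_counts", {"grid": 30, "interneuron": 20,
                                  "border": 15, "aperiodic_spatial": 15})
    kw.setdefault("duration", 900.0)
    return SyntheticConfig(seed=seed, arena_side=100.0, **kw)


@dataclass
class LfpSignal:
    """Raw LFP trace (arbitrary amplitude units, fixed sample rate)."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")


@dataclass
class SyntheticSession:
    """A complete labeled session: the universal test fixture."""

    config: SyntheticConfig
    trajectory: Trajectory
    spikes: dict[str, SpikeTrain]
    true_labels: dict[str, str]
    lfp: LfpSignal
    tuning: dict[str, dict] = dc_field(default_factory=dict)
    images: list[tuple[np.ndarray, np.ndarray]] = dc_field(default_factory=list)


def gen_trajectory(config: SyntheticConfig) -> Trajectory:
    """Smooth random walk: OU velocity process with reflecting walls.

    The two velocity components follow independent mean-reverting processes
    whose stationary distribution gives a Rayleigh speed with the requested
    mean; wall crossings are reflected and the offending velocity component
    flipped, so positions stay inside [0, arena_side]^2.
    """
    if config.duration < 60:
        raise ValueError("duration must be at least 60 s")
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate
    n = int(round(config.duration * config.sample_rate))
    tau = config.persistence
    # per-component stationary sd s gives Rayleigh mean speed s*sqrt(pi/2)
    s = config.mean_speed / np.sqrt(np.pi / 2.0)
    sigma = s * np.sqrt(2.0 / tau)
    L = config.arena_side
    x = np.empty(n)
    y = np.empty(n)
    pos = rng.uniform(0.2 * L, 0.8 * L, size=2)
    vel = rng.normal(0.0, s, size=2)
    sq = sigma * np.sqrt(dt)
    noise = rng.normal(size=(n, 2))
    for i in range(n):
        vel = vel - (vel / tau) * dt + sq * noise[i]
        pos = pos + vel * dt
        for d in (0, 1):
            if pos[d] < 0:
                pos[d] = -pos[d]
                vel[d] = -vel[d]
            elif pos[d] > L:
                pos[d] = 2 * L - pos[d]
                vel[d] = -vel[d]
        pos = np.clip(pos, 0.0, L)
        x[i], y[i] = pos
    t = np.arange(n) * dt
    return Trajectory(t=t, x=x, y=y, sample_rate=config.sample_rate)


def make_tuning(cell_type: str, params: dict, arena_side: float,
                rng: np.random.Generator):
    """Return a vectorized tuning function rate(x, y) in Hz for one unit.

    place / aperiodic_spatial — isotropic Gaussian bump;
    grid — thresholded sum of three plane-wave cosines at 60 deg separations;
    border — rate decaying exponentially with distance from one wall;
    interneuron — high base rate with weak sinusoidal spatial modulation.
    """
    L = arena_side
    if cell_type in ("place", "aperiodic_spatial"):
        peak = params["peak_rate"]
        width = params["width"]
        cx = params.get("center", (None, None))[0]
        if cx is None:
            cx, cy = rng.uniform(0.15 * L, 0.85 * L, size=2)
        else:
            cx, cy = params["center"]

        def tuning(x, y, peak=peak, w=width, cx=cx, cy=cy):
            return peak * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * w ** 2))
        return tuning

    if cell_type == "grid":
        peak = params["peak_rate"]
        spacing = params["spacing"]
        theta = params.get("orientation")
        if theta is None:
            theta = rng.uniform(0, np.pi / 3)
        phase = params.get("phase")
        if phase is None:
            phase = rng.uniform(0, spacing, size=2)
        k = 4 * np.pi / (np.sqrt(3) * spacing)
        angles = theta + np.array([0.0, np.pi / 3, 2 * np.pi / 3])
        kx = k * np.cos(angles)
        ky = k * np.sin(angles)

        def tuning(x, y, peak=peak, kx=kx, ky=ky, phase=phase):
            s = np.zeros(np.broadcast(x, y).shape)
            for a in range(3):
                s = s + np.cos(kx[a] * (x - phase[0]) + ky[a] * (y - phase[1]))
            return peak * np.maximum(s, 0.0) / 3.0
        return tuning

    if cell_type == "border":
        peak = params["peak_rate"]
        decay = params["decay"]
        wall = params.get("wall")
        if wall is None:
            wall = rng.integers(0, 4)

        def tuning(x, y, peak=peak, decay=decay, wall=wall, L=L):
            d = [x, L - x, y, L - y][wall]
            return peak * np.exp(-np.asarray(d) / decay)
        return tuning

    if cell_type == "interneuron":
        base = params["base_rate"]
        mod = params["modulation"]
        phase = rng.uniform(0, 2 * np.pi, size=2)

        def tuning(x, y, base=base, mod=mod, phase=phase, L=L):
            m = 1 + mod * 0.5 * (np.sin(2 * np.pi * np.asarray(x) / L + phase[0])
                                 + np.sin(2 * np.pi * np.asarray(y) / L + phase[1]))
            return base * m
        return tuning

    raise ValueError(f"unsupported cell type: {cell_type!r}")


def gen_spikes(traj: Trajectory, tuning, seed: int,
               unit_id: str = "u0") -> SpikeTrain:
    """Inhomogeneous-Poisson spikes by thinning against the tuning function.

    Candidate spikes are drawn from a homogeneous process at the peak rate
    along the path and accepted with probability rate/peak; the rate is held
    constant within each 30 Hz tracking frame.
    """
    rng = np.random.default_rng(seed)
    lam = np.asarray(tuning(traj.x, traj.y), dtype=float)
    if np.any(lam < 0):
        raise ValueError("tuning function must be non-negative")
    lam_max = lam.max()
    if lam_max == 0:
        return SpikeTrain(unit_id=unit_id, spike_times=np.empty(0))
    t0, t1 = traj.t[0], traj.t[-1]
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    frame = np.clip(((cand - t0) * traj.sample_rate).astype(int),
                    0, lam.size - 1)
    keep = rng.uniform(size=n_cand) < lam[frame] / lam_max
    return SpikeTrain(unit_id=unit_id, spike_times=cand[keep])


def gen_lfp(spec: list[tuple[float, float, float]], duration: float,
            sample_rate: float = 1000.0, seed: int = 0,
            noise_amp: float = 0.2) -> LfpSignal:
    """Sum of narrow-band oscillations plus 1/f-shaped background noise.

    Each (center Hz, amplitude, bandwidth Hz) component is a sinusoid whose
    instantaneous frequency wanders within the stated bandwidth, giving a
    spectral peak of finite width.  Setting ``noise_amp=0`` removes the
    background floor.
    """
    for f0, _, _ in spec:
        if sample_rate < 2 * f0:
            raise ValueError(
                f"sample_rate {sample_rate} violates Nyquist for {f0} Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate
    sig = np.zeros(n)
    for f0, amp, bw in spec:
        if amp == 0:
            continue
        drift = ndimage.gaussian_filter1d(
            rng.normal(size=n), sigma=sample_rate * 0.25, mode="wrap")
        sd = drift.std()
        drift = drift / sd * (bw / 2.0) if sd > 0 else drift
        phase = 2 * np.pi * np.cumsum(f0 + drift) * dt
        phase += rng.uniform(0, 2 * np.pi)
        sig += amp * np.sin(phase)
    if noise_amp > 0:
        white = rng.normal(size=n)
        spec_w = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, dt)
        shape = np.zeros_like(freqs)
        shape[1:] = 1.0 / np.sqrt(freqs[1:])
        pink = np.fft.irfft(spec_w * shape, n=n)
        std = pink.std()
        if std > 0:
            sig += noise_amp * pink / std
    return LfpSignal(samples=sig, sample_rate=sample_rate)


def gen_vessel_image(image_spec: dict | None = None, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray, list[tuple[tuple[int, int], int]]]:
    """Synthetic fluorescence image: bright curvilinear vessels, optional
    bright circular artifacts, Gaussian noise.

    Returns ``(image, ground_truth_mask, artifact_list)`` where the mask is
    the noiseless vessel footprint and each artifact is ((row, col), radius).
    Artifact disks are placed disjoint from the vessel mask.
    """
    spec = dict(DEFAULT_IMAGE_SPEC)
    if image_spec:
        spec.update(image_spec)
    shape = tuple(spec["shape"])
    if min(shape) < 128:
        raise ValueError("image dimensions must be at least 128 x 128")
    radius = int(spec["artifact_radius"])
    if radius >= min(shape):
        raise ValueError("artifact radius must be smaller than the image")
    rng = np.random.default_rng(seed)
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(int(spec["vessel_count"])):
        # persistent random walk entering from a random border point
        side = rng.integers(0, 4)
        if side == 0:
            r, c, ang = 0.0, rng.uniform(0, w), np.pi / 2
        elif side == 1:
            r, c, ang = float(h - 1), rng.uniform(0, w), -np.pi / 2
        elif side == 2:
            r, c, ang = rng.uniform(0, h), 0.0, 0.0
        else:
            r, c, ang = rng.uniform(0, h), float(w - 1), np.pi
        n_steps = int(1.5 * max(h, w))
        for _ in range(n_steps):
            rr, cc = int(round(r)), int(round(c))
            if 0 <= rr < h and 0 <= cc < w:
                mask[rr, cc] = True
            ang += rng.normal(0, 0.15)
            r += np.sin(ang)
            c += np.cos(ang)
            if not (-10 <= r < h + 10 and -10 <= c < w + 10):
                break
    width = int(spec["vessel_width"])
    if width > 1:
        mask = ndimage.binary_dilation(
            mask, structure=_disk(width // 2))
    img = np.where(mask, 0.8, 0.1).astype(float)
    # keep artifacts clear of vessels and of the border
    artifacts: list[tuple[tuple[int, int], int]] = []
    forbidden = ndimage.binary_dilation(mask, structure=_disk(radius + 3))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(int(spec["artifact_count"])):
        for _try in range(200):
            cr = rng.integers(radius + 2, h - radius - 2)
            cc = rng.integers(radius + 2, w - radius - 2)
            if not forbidden[cr, cc]:
                break
        else:
            continue
        disk = (yy - cr) ** 2 + (xx - cc) ** 2 <= radius ** 2
        img[disk] = 1.0
        forbidden |= ndimage.binary_dilation(disk, structure=_disk(radius + 3))
        artifacts.append(((int(cr), int(cc)), radius))
    noise_sd = float(spec["noise_sd"])
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, size=shape)
    return img, mask, artifacts


def _disk(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return yy ** 2 + xx ** 2 <= radius ** 2


def gen_session(config: SyntheticConfig) -> SyntheticSession:
    """Assemble a full labeled session from one configuration.

    Unit seeds and per-unit tuning draws derive deterministically from
    ``config.seed``, so the whole session is reproducible byte-for-byte.
    """
    traj = gen_trajectory(config)
    master = np.random.default_rng(config.seed)
    param_rng = np.random.default_rng(master.integers(2 ** 31))
    spikes: dict[str, SpikeTrain] = {}
    labels: dict[str, str] = {}
    tuning_used: dict[str, dict] = {}
    idx = 0
    for cell_type, count in config.cell_counts.items():
        params = config.tuning_params.get(cell_type, DEFAULT_TUNING[cell_type])
        for _ in range(count):
            uid = f"u{idx:03d}"
            tuning = make_tuning(cell_type, params, config.arena_side,
                                 param_rng)
            seed = int(master.integers(2 ** 31))
            spikes[uid] = gen_spikes(traj, tuning, seed=seed, unit_id=uid)
            labels[uid] = cell_type
            tuning_used[uid] = {"cell_type": cell_type}
            idx += 1
    lfp = gen_lfp(config.lfp_spec, config.duration,
                  sample_rate=config.lfp_sample_rate,
                  seed=int(master.integers(2 ** 31)),
                  noise_amp=config.lfp_noise_amp)
    images = []
    for _ in range(config.n_images):
        img, mask, _arts = gen_vessel_image(
            config.image_spec, seed=int(master.integers(2 ** 31)))
        images.append((img, mask))
    return SyntheticSession(config=config, trajectory=traj, spikes=spikes,
                            true_labels=labels, lfp=lfp, tuning=tuning_used,
                            images=images)
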