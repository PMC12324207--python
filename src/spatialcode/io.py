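"""Session bundles on disk, configuration echo, and the pipeline driver.

A session directory holds plain tabular/array files:

    manifest.json          arena size, preset, sample rates, seed provenance
    positions.csv          t, x, y (s / cm)
    spikes/<unit>.csv      one spike-time column, t
    labels.csv             unit, cell_type (synthetic sessions only)
    lfp.npy + lfp.json     raw float trace + {"sample_rate": Hz}
    images/img_<k>.tif     fluorescence images (+ mask_<k>.tif ground truth)

``run_pipeline`` executes analysis stages in dependency order and writes
TSV outputs plus a config echo for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, cellclass, decoder, gridborder, lfp as lfp_mod, maps
from .synthetic import LfpSignal, SyntheticSession

__all__ = ["save_session", "load_session", "run_pipeline", "SessionBundle",
           "PRESETS"]

#: preset -> (bin_size cm, smoothing kernel bins)
PRESETS = {"ca1": (2.0, 5), "mec": (2.0, 10)}

STAGE_DEPS = {"maps": [], "gridborder": ["maps"], "classify": ["maps", "gridborder"],
              "decode": [], "lfp": [], "behavior": []}


class SessionBundle:
    """Validated handles to the artifacts of one session directory."""

    def __init__(self, path: Path, manifest: dict,
                 trajectory: maps.Trajectory,
                 spikes: dict[str, maps.SpikeTrain],
                 labels: dict[str, str] | None,
                 lfp: LfpSignal | None):
        self.path = path
        self.manifest = manifest
        self.trajectory = trajectory
        self.spikes = spikes
        self.labels = labels
        self.lfp = lfp

    @property
    def preset(self) -> str:
        return self.manifest.get("preset", "ca1")

    @property
    def arena_side(self) -> float:
        return float(self.manifest["arena_side"])


def save_session(session: SyntheticSession, out_dir: str | Path,
                 preset: str | None = None) -> Path:
    """Write a synthetic session as a plain-file bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj = session.trajectory
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(
        out / "positions.csv", index=False)
    spikes_dir = out / "spikes"
    spikes_dir.mkdir(exist_ok=True)
    for uid, train in session.spikes.items():
        pd.DataFrame({"t": train.spike_times}).to_csv(
            spikes_dir / f"{uid}.csv", index=False)
    pd.DataFrame(sorted(session.true_labels.items()),
                 columns=["unit", "cell_type"]).to_csv(
        out / "labels.csv", index=False)
    np.save(out / "lfp.npy", session.lfp.samples)
    (out / "lfp.json").write_text(json.dumps(
        {"sample_rate": session.lfp.sample_rate}))
    if session.images:
        import tifffile
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for k, (img, mask) in enumerate(session.images):
            tifffile.imwrite(img_dir / f"img_{k}.tif",
                             img.astype(np.float32))
            tifffile.imwrite(img_dir / f"mask_{k}.tif",
                             mask.astype(np.uint8))
    if preset is None:
        preset = "mec" if session.config.arena_side > 60 else "ca1"
    manifest = {
        "arena_side": session.config.arena_side,
        "preset": preset,
        "sample_rate": session.config.sample_rate,
        "lfp_sample_rate": session.lfp.sample_rate,
        "seed": session.config.seed,
        "n_units": len(session.spikes),
        "files": {"positions": "positions.csv", "spikes": "spikes",
                  "labels": "labels.csv", "lfp": "lfp.npy"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_session(path: str | Path) -> SessionBundle:
    """Load and validate a session bundle directory."""
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise FileNotFoundError(f"no manifest.json in {path}")
    manifest = json.loads(mf.read_text())
    for key in ("arena_side", "preset", "sample_rate"):
        if key not in manifest:
            raise ValueError(f"manifest missing required field {key!r}")
    if manifest["preset"] not in PRESETS:
        raise ValueError(f"unknown preset {manifest['preset']!r}")
    pos_file = path / manifest["files"]["positions"]
    if not pos_file.exists():
        raise FileNotFoundError(f"missing positions file {pos_file}")
    pos = pd.read_csv(pos_file)
    traj = maps.Trajectory(t=pos["t"].to_numpy(), x=pos["x"].to_numpy(),
                           y=pos["y"].to_numpy(),
                           sample_rate=manifest["sample_rate"])
    spikes_dir = path / manifest["files"].get("spikes", "spikes")
    if not spikes_dir.is_dir():
        raise FileNotFoundError(f"missing spikes directory {spikes_dir}")
    spikes = {}
    for f in sorted(spikes_dir.glob("*.csv")):
        spikes[f.stem] = maps.SpikeTrain(
            unit_id=f.stem, spike_times=pd.read_csv(f)["t"].to_numpy())
    labels = None
    lab_file = path / manifest["files"].get("labels", "labels.csv")
    if lab_file.exists():
        lab = pd.read_csv(lab_file)
        labels = dict(zip(lab["unit"], lab["cell_type"]))
    lfp_sig = None
    lfp_file = path / manifest["files"].get("lfp", "lfp.npy")
    if lfp_file.exists():
        sidecar = json.loads((path / "lfp.json").read_text())
        lfp_sig = LfpSignal(samples=np.load(lfp_file),
                            sample_rate=sidecar["sample_rate"])
    return SessionBundle(path=path, manifest=manifest, trajectory=traj,
                         spikes=spikes, labels=labels, lfp=lfp_sig)


def _unit_metrics_table(bundle: SessionBundle) -> pd.DataFrame:
    bin_size, kernel = PRESETS[bundle.preset]
    traj = bundle.trajectory
    occ = maps.occupancy_map(traj, bin_size=bin_size,
                             extent=bundle.arena_side)
    rows = []
    for uid, train in bundle.spikes.items():
        rmap = maps.rate_map(traj, train, kernel_bins=kernel, occ=occ)
        fields = maps.detect_fields(rmap)
        m = maps.rate_metrics(rmap, fields, train, traj.duration, occ=occ)
        try:
            com = maps.com_stats(rmap)
            com_x, com_y, com_d = com.com[0], com.com[1], com.dist_from_center
        except ValueError:
            com_x = com_y = com_d = float("nan")
        rows.append({"unit": uid, "mfr": m.mfr, "infield_mfr": m.infield_mfr,
                     "outfield_mfr": m.outfield_mfr,
                     "in_out_index": m.in_out_index, "si": m.si,
                     "field_area": m.field_area, "com_x": com_x,
                     "com_y": com_y, "com_dist": com_d})
    return pd.DataFrame(rows)


def _gridborder_table(bundle: SessionBundle) -> pd.DataFrame:
    bin_size, kernel = PRESETS[bundle.preset]
    traj = bundle.trajectory
    occ = maps.occupancy_map(traj, bin_size=bin_size,
                             extent=bundle.arena_side)
    rows, acs, uids = [], [], []
    for uid, train in bundle.spikes.items():
        rmap = maps.rate_map(traj, train, kernel_bins=kernel, occ=occ)
        fields = maps.detect_fields(rmap)
        ac = gridborder.spatial_autocorrelation(rmap)
        gs = gridborder.grid_score(ac)
        bs = gridborder.border_score(rmap, fields)
        acs.append(ac)
        uids.append(uid)
        rows.append({"unit": uid, "grid_score": gs.score,
                     "border_score": bs.b})
    scores, _ = gridborder.ac_principal_components(acs, k=3)
    df = pd.DataFrame(rows)
    for j in range(3):
        df[f"pc{j + 1}"] = scores[:, j]
    return df


def run_pipeline(session_dir: str | Path, stages: list[str],
                 out_dir: str | Path | None = None, seed: int = 0,
                 config: dict | None = None) -> Path:
    """Run analysis stages on a session bundle, writing TSV outputs.

    Stage dependencies (``classify`` needs ``maps`` and ``gridborder``)
    must be satisfied by the requested stage list.
    """
    config = config or {}
    for st in stages:
        if st not in STAGE_DEPS:
            raise ValueError(f"unknown stage {st!r}")
        for dep in STAGE_DEPS[st]:
            if dep not in stages:
                raise ValueError(f"stage {st!r} requires {dep!r}")
    bundle = load_session(session_dir)
    out = Path(out_dir) if out_dir else bundle.path / "results"
    out.mkdir(parents=True, exist_ok=True)
    echo = {"stages": stages, "seed": seed, "config": config,
            "preset": bundle.preset}
    (out / "config_echo.json").write_text(json.dumps(echo, indent=2))

    if "maps" in stages:
        _unit_metrics_table(bundle).to_csv(out / "unit_metrics.tsv",
                                           sep="\t", index=False)
    if "gridborder" in stages:
        _gridborder_table(bundle).to_csv(out / "gridborder.tsv", sep="\t",
                                         index=False)
    if "classify" in stages:
        bin_size, kernel = PRESETS[bundle.preset]
        assign = cellclass.classify_session(
            bundle.trajectory, bundle.spikes, bin_size=bin_size,
            kernel_bins=kernel, seed=seed)
        pd.DataFrame({"unit": assign.unit_ids,
                      "cluster": assign.cluster_ids,
                      "cell_type": assign.cell_types,
                      "emb_x": assign.embedding[:, 0],
                      "emb_y": assign.embedding[:, 1]}).to_csv(
            out / "assignments.tsv", sep="\t", index=False)
        assign.cluster_profiles.to_csv(out / "cluster_profiles.tsv",
                                       sep="\t")
    if "decode" in stages:
        cfg = decoder.DecoderConfig(**config.get("decoder", {}))
        path = decoder.decode_path(bundle.trajectory, bundle.spikes, cfg,
                                   arena_side=bundle.arena_side)
        pd.DataFrame({"t": path.t, "x_hat": path.x_hat,
                      "y_hat": path.y_hat, "x": path.x_true,
                      "y": path.y_true, "error": path.errors}).to_csv(
            out / "decoded_path.tsv", sep="\t", index=False)
        (out / "decode_summary.json").write_text(json.dumps(
            {"mean_error_cm": path.mean_error, "n_windows": len(path.t)}))
    if "lfp" in stages:
        if bundle.lfp is None:
            raise ValueError("session has no LFP trace")
        bouts = lfp_mod.detect_movement_bouts(bundle.trajectory)
        powers = lfp_mod.band_power(bundle.lfp, bouts or None)
        pd.DataFrame([{"bout": p.bout_id, "band": p.band, "auc": p.auc}
                      for p in powers]).to_csv(out / "band_power.tsv",
                                               sep="\t", index=False)
    if "behavior" in stages:
        trials_file = Path(session_dir) / "trials.csv"
        if trials_file.exists():
            df = pd.read_csv(trials_file)
            recs = [behavior.TrialRecord(
                trial_id=str(r.trial), latency=r.latency,
                errors=int(r.errors), escaped=bool(r.escaped))
                for r in df.itertuples()]
            scored = pd.DataFrame({
                "trial": [t.trial_id for t in recs],
                "strategy": [behavior.classify_strategy(t) for t in recs]})
            scored.to_csv(out / "strategies.tsv", sep="\t", index=False)
            (out / "strategy_score.json").write_text(json.dumps(
                {"score": behavior.strategy_score(recs)}))
    # content hash over all outputs for reproducibility checks
    digest = hashlib.sha256()
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "content_hash.txt":
            digest.update(f.name.encode())
            digest.update(f.read_bytes())
    (out / "content_hash.txt").write_text(digest.hexdigest())
    return out
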