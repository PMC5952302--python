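"""File formats for run outputs: rasters, snapshots, metrics, manifests.

Rasters are tab-separated (neuron_id, spike_time_ms); weight snapshots are
``.npy`` arrays with an optional plain-text CSV fallback; metric series are
CSV; each run directory carries a summary JSON and batches a manifest with
SHA-256 checksums of every file they reference.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ExperimentResult
from .params import ExperimentConfig


def raster_to_frame(raster) -> pd.DataFrame:
    rows = [
        pd.DataFrame({"neuron_id": i + 1, "spike_time_ms": np.asarray(times)})
        for i, times in enumerate(raster)
        if len(times)
    ]
    if not rows:
        return pd.DataFrame(columns=["neuron_id", "spike_time_ms"])
    return pd.concat(rows, ignore_index=True)


def frame_to_raster(df: pd.DataFrame, n_neurons: int) -> list[np.ndarray]:
    out = [np.empty(0) for _ in range(n_neurons)]
    for nid, sub in df.groupby("neuron_id"):
        out[int(nid) - 1] = np.sort(sub["spike_time_ms"].to_numpy(float))
    return out


def sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def save_result(result: ExperimentResult, out_dir, csv_snapshots: bool = False) -> dict:
    """Write one run's artifacts; returns the file map (relative paths)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    result.config.to_yaml(out / "config.yaml")
    files["config"] = "config.yaml"

    raster_to_frame(result.raster).to_csv(out / "raster.tsv", sep="\t", index=False)
    files["raster"] = "raster.tsv"

    result.schedule.to_tsv(out / "schedule.tsv")
    files["schedule"] = "schedule.tsv"

    result.metrics.to_csv(out / "metrics.csv", index=False)
    files["metrics"] = "metrics.csv"

    for t_s, c in result.snapshots.items():
        tag = f"weights_t{t_s:g}s"
        if csv_snapshots:
            np.savetxt(out / f"{tag}.csv", c, delimiter=",")
            files[tag] = f"{tag}.csv"
        else:
            np.save(out / f"{tag}.npy", c)
            files[tag] = f"{tag}.npy"

    summary = run_summary(result)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    files["summary"] = "summary.json"
    return files


def run_summary(result: ExperimentResult) -> dict:
    """Scalar per-run summary: connectivity and synchronization checkpoints."""
    from . import analysis

    per = result.config.periods
    t_on, t_off = per.stim_on_s, per.stim_on_s + per.stim_off_s
    # the study convention averages R over the preceding 5 s; short fixtures
    # shrink the window to the recorded pre-stimulation history
    window_s = min(5.0, per.stdp_only_s, per.stim_on_s, per.stim_off_s)
    out = {
        "protocol": result.config.protocol,
        "K": result.config.K,
        "sample_id": result.config.sample_id,
        "n_spikes": int(result.stats.get("n_spikes", 0)),
    }
    for label, t_s in (("t0", 0.0), ("on", t_on), ("off", t_off)):
        C_av, c_EE, c_II = analysis.mean_weights(result.snapshots[t_s], result.M)
        out[f"C_av_{label}"] = C_av
        out[f"c_EE_{label}"] = c_EE
        out[f"c_II_{label}"] = c_II
        out[f"R_av_{label}"] = result.r_av(t_s, window_s=window_s)
    return out


def load_result(run_dir) -> ExperimentResult:
    """Reload a saved run; snapshots come back from .npy (or CSV) files."""
    from .engine import ExperimentResult
    from .model import mexican_hat_matrix
    from .stimulation import OnsetSchedule

    run_dir = Path(run_dir)
    cfg = ExperimentConfig.from_yaml(run_dir / "config.yaml")
    raster = frame_to_raster(
        pd.read_csv(run_dir / "raster.tsv", sep="\t"), cfg.net.N
    )
    schedule = OnsetSchedule.from_tsv(
        run_dir / "schedule.tsv", cfg.protocol, cfg.stim.Ts
    )
    metrics = pd.read_csv(run_dir / "metrics.csv")
    snapshots = {}
    for f in run_dir.glob("weights_t*s.npy"):
        t_s = float(f.stem[len("weights_t"):-1])
        snapshots[t_s] = np.load(f)
    for f in run_dir.glob("weights_t*s.csv"):
        t_s = float(f.stem[len("weights_t"):-1])
        if t_s not in snapshots:
            snapshots[t_s] = np.loadtxt(f, delimiter=",")
    return ExperimentResult(
        config=cfg, schedule=schedule, raster=raster, snapshots=snapshots,
        metrics=metrics, M=mexican_hat_matrix(cfg.net),
    )


def write_manifest(out_dir, entries: list[dict]) -> Path:
    """Write a batch manifest with checksums; returns its path."""
    out = Path(out_dir)
    for entry in entries:
        for rel in entry.get("files", {}).values():
            p = out / entry["run_dir"] / rel
            entry.setdefault("checksums", {})[rel] = sha256(p) if p.exists() else None
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)
    return path
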