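"""Result export: CSV tables, JSON summaries, reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import DeltaGGrid, GSeries


def _package_version() -> str:
    try:
        return version("intertrack")
    except PackageNotFoundError:  # pragma: no cover - editable quirk
        return "unknown"


def config_hash(cfg) -> str:
    """Stable sha256 of the serialised configuration."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def write_manifest(cfg, seed: int, out_dir: Path, extra: dict | None = None) -> Path:
    manifest = {
        "config_sha256": config_hash(cfg),
        "seed": int(seed),
        "version": _package_version(),
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def series_frame(series_list: list[GSeries]) -> pd.DataFrame:
    """Long frame of every replicate's logged series."""
    frames = []
    for rep, s in enumerate(series_list):
        f = s.to_frame()
        f.insert(0, "replicate", rep)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def aggregate_series(series_list: list[GSeries]) -> pd.DataFrame:
    """Mean ± standard error of G over replicates, per (species, time)."""
    long = series_frame(series_list)
    g = long.groupby(["species", "time_ps"])["G"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "G_mean", "sem": "G_se", "count": "n"})


def export_results(
    cfg,
    seed: int,
    out_dir,
    *,
    series: list[GSeries] | None = None,
    grid: DeltaGGrid | None = None,
    summary: dict | None = None,
) -> list[Path]:
    """Write CSV/JSON outputs plus a manifest; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if series:
        p = out / "gseries.csv"
        series_frame(series).to_csv(p, index=False)
        written.append(p)
        p = out / "gseries_aggregate.csv"
        aggregate_series(series).to_csv(p, index=False)
        written.append(p)
    if grid is not None:
        p = out / "delta_g_grid.csv"
        grid.to_csv(p)
        written.append(p)
    if summary is not None:
        p = out / "summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        written.append(p)
    written.append(write_manifest(cfg, seed, out))
    return written


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def reaction_log_frame(state, reactions) -> pd.DataFrame:
    """Reaction log as a tidy frame (time, channel, position, track ids)."""
    rows = [
        {
            "time_ps": t,
            "channel": reactions.channels[c].label(),
            "x_nm": x,
            "y_nm": y,
            "z_nm": z,
            "track_i": ti,
            "track_j": tj,
        }
        for (t, c, x, y, z, ti, tj) in state.reaction_log
    ]
    return pd.DataFrame(
        rows,
        columns=["time_ps", "channel", "x_nm", "y_nm", "z_nm", "track_i", "track_j"],
    )
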