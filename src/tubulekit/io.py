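"""File formats and provenance.

Kymographs travel as single-channel TIFF plus a JSON calibration sidecar
(``<name>.json`` next to the image).  Traces, arcs and profiles are plain
CSV with fixed column schemas and fixed units (s, um, nm); readers
validate units and monotonicity.  Every writer can drop a provenance
record (config + seed + version) beside its outputs.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .core import EndTrace, Kymograph, KymoSpec, RawProfile, TubuleTrace

TRACE_COLUMNS = ["time_s", "position_um", "end", "truth_phase"]
TUBULE_COLUMNS = ["trace_id", "z_section", "point_index", "x_nm", "y_nm"]
PROFILE_COLUMNS = ["profile_id", "position_um"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".tif" else path.with_suffix(".json")


def write_kymograph(kymo: Kymograph, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, kymo.image.astype(np.float32))
    meta = {
        "pixel_size_um": kymo.spec.pixel_size,
        "frame_interval_s": kymo.spec.frame_interval,
        "duration_s": kymo.spec.duration,
        "seed_span": list(kymo.seed_span),
        "psf_sigma_px": kymo.spec.psf_sigma,
        "signal": kymo.spec.signal,
        "background": kymo.spec.background,
        "seed_length_um": kymo.spec.seed_length,
        "rng_seed": kymo.spec.rng_seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_kymograph(path) -> Kymograph:
    path = Path(path)
    image = np.asarray(tifffile.imread(path), dtype=float)
    if image.ndim != 2:
        raise ValueError("kymograph TIFF must be a single-channel 2-D image")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ValueError(f"missing calibration sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    spec = KymoSpec(
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_s"],
        duration=meta.get("duration_s", image.shape[0] * meta["frame_interval_s"]),
        psf_sigma=meta.get("psf_sigma_px", 0.0),
        signal=meta.get("signal", 2.0),
        background=meta.get("background", 0.0),
        seed_length=meta.get("seed_length_um", 1.5),
        rng_seed=meta.get("rng_seed", 0),
    )
    return Kymograph(image=image, spec=spec, seed_span=tuple(meta["seed_span"]))


def write_traces(traces: Sequence[EndTrace], path) -> None:
    frames = []
    for k, tr in enumerate(traces):
        phase = np.full(tr.times.shape, "", dtype=object)
        if tr.truth:
            for seg in tr.truth:
                sel = (tr.times >= seg.t_start - 1e-9) & (tr.times <= seg.t_end + 1e-9)
                phase[sel] = seg.phase
        frames.append(pd.DataFrame({
            "trace_id": tr.meta.get("trace_id", k),
            "time_s": tr.times,
            "position_um": tr.positions,
            "end": tr.end,
            "truth_phase": phase,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list:
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "position_um", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns {missing} (units must be declared in headers)")
    traces = []
    key = "trace_id" if "trace_id" in df.columns else None
    groups = df.groupby(key) if key else [(0, df)]
    for tid, sub in groups:
        t = sub["time_s"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"trace {tid}: time_s must be strictly increasing")
        traces.append(EndTrace(
            times=t,
            positions=sub["position_um"].to_numpy(dtype=float),
            end=str(sub["end"].iloc[0]),
            meta={"trace_id": tid},
        ))
    return traces


def write_tubule_traces(traces: Sequence[TubuleTrace], path) -> None:
    rows = []
    for k, tr in enumerate(traces):
        tid = tr.label or str(k)
        for i, (x, y) in enumerate(tr.points):
            rows.append((tid, 0, i, x, y, "point", tr.group or ""))
        rows.append((tid, 0, -1, tr.O[0], tr.O[1], "O", tr.group or ""))
        rows.append((tid, 0, -2, tr.X[0], tr.X[1], "X", tr.group or ""))
    pd.DataFrame(rows, columns=TUBULE_COLUMNS + ["role", "group"]).to_csv(path, index=False)


def read_tubule_traces(path) -> list:
    df = pd.read_csv(path)
    missing = [c for c in TUBULE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tubule CSV missing columns {missing}")
    traces = []
    for (tid, z), sub in df.groupby(["trace_id", "z_section"]):
        pts = sub[sub["role"] == "point"].sort_values("point_index")[["x_nm", "y_nm"]].to_numpy()
        O = sub[sub["role"] == "O"][["x_nm", "y_nm"]].to_numpy()
        X = sub[sub["role"] == "X"][["x_nm", "y_nm"]].to_numpy()
        if len(O) != 1 or len(X) != 1:
            raise ValueError(f"trace {tid}/{z}: need exactly one O and one X landmark")
        group = str(sub["group"].iloc[0]) if "group" in sub and str(sub["group"].iloc[0]) else None
        traces.append(TubuleTrace(points=pts, O=O[0], X=X[0], label=f"{tid}/{z}", group=group))
    return traces


def write_profiles(profiles: Sequence[RawProfile], path) -> None:
    frames = []
    for k, p in enumerate(profiles):
        d = {"profile_id": k, "position_um": p.positions}
        for c, name in enumerate(p.channel_names):
            d[f"intensity_{name}"] = p.intensities[:, c]
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles(path) -> list:
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV missing columns {missing}")
    chan_cols = [c for c in df.columns if c.startswith("intensity_")]
    if not chan_cols:
        raise ValueError("profile CSV has no intensity_* columns")
    out = []
    for _, sub in df.groupby("profile_id"):
        out.append(RawProfile(
            positions=sub["position_um"].to_numpy(dtype=float),
            intensities=sub[chan_cols].to_numpy(dtype=float),
            channel_names=tuple(c.removeprefix("intensity_") for c in chan_cols),
        ))
    return out


def write_provenance(out_path, config: dict, seed) -> Path:
    """Provenance record (config hash + seed + version) beside an output."""
    out_path = Path(out_path)
    blob = json.dumps(config, sort_keys=True, default=str)
    rec = {
        "version": __version__,
        "rng_seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    p = out_path.parent / (out_path.name + ".provenance.json")
    p.write_text(json.dumps(rec, indent=1, default=str))
    return p
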