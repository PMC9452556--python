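"""Readers and writers for traces, grids, masks and run metadata.

Formats: trace tables are CSV (a ``time_s`` column plus one column per
ROI) with a JSON sidecar holding labels and the stimulation onset; images
and grids travel as single-channel TIFF (32-bit float at grid
resolution); tabular results as CSV with 9 significant digits; reports as
JSON.  Z-stack TIFFs are collapsed by mean projection on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .events import RoiTrace, SliceRecording, ProcessedTrace, ActivitySummary
from .prq import GridImage

__all__ = [
    "FLOAT_FORMAT",
    "write_trace_table",
    "read_trace_table",
    "read_tiff_projected",
    "write_tiff",
    "read_image_set",
    "write_grid",
    "read_grid",
    "write_events_csv",
    "write_summary_csv",
    "load_config",
]

FLOAT_FORMAT = "%.9g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace_table(recording: SliceRecording, path: str | Path) -> None:
    """Write a recording as time+ROI CSV plus a JSON sidecar."""
    path = Path(path)
    n = recording.traces[0].values.size
    data = {"time_s": np.arange(n) / recording.frame_rate_hz}
    for t in recording.traces:
        if t.values.size != n:
            raise ValueError("all traces must share a length to share a table")
        data[t.roi_id] = t.values
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    sidecar = {
        "slice_id": recording.slice_id,
        "frame_rate_hz": recording.frame_rate_hz,
        "stim_onset_s": recording.stim_onset_s,
        "subregions": {t.roi_id: t.subregion for t in recording.traces},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_trace_table(path: str | Path) -> SliceRecording:
    """Read a trace CSV + sidecar back into a validated recording."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty or "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: need a 'time_s' column plus at least one ROI column")
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1))[0])
        raise ValueError(f"{path}: NaN value at row {row}")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise ValueError(f"missing sidecar {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    for key in ("frame_rate_hz", "subregions"):
        if key not in sidecar:
            raise ValueError(f"{sc_path}: missing sidecar key '{key}'")
    traces = []
    for col in df.columns:
        if col == "time_s":
            continue
        if col not in sidecar["subregions"]:
            raise ValueError(f"{sc_path}: no subregion label for ROI '{col}'")
        traces.append(
            RoiTrace(
                roi_id=col,
                subregion=sidecar["subregions"][col],
                values=df[col].to_numpy(),
                frame_rate_hz=sidecar["frame_rate_hz"],
                stim_onset_s=sidecar.get("stim_onset_s"),
            )
        )
    return SliceRecording(
        slice_id=sidecar.get("slice_id", path.stem),
        traces=traces,
        stim_onset_s=sidecar.get("stim_onset_s"),
    )


def read_tiff_projected(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF; mean-project a z-stack to one plane."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=0)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image or a z-stack, got shape {arr.shape}")
    return arr


def write_tiff(array: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32))


def read_image_set(manifest: str | Path) -> dict:
    """Read the image/mask bundle named by a YAML manifest.

    Expected keys: ``image`` (or ``basal``/``stim``), ``nucleus_mask``,
    optional ``subregion_masks`` (name -> path), optional ``controls``
    (list of paths).  All paths are relative to the manifest.
    """
    manifest = Path(manifest)
    spec = yaml.safe_load(manifest.read_text())
    root = manifest.parent

    def load(rel: str) -> np.ndarray:
        p = root / rel
        if not p.exists():
            raise FileNotFoundError(f"manifest entry not found: {p}")
        return read_tiff_projected(p)

    out: dict = {}
    for key in ("image", "basal", "stim", "afferent"):
        if key in spec:
            out[key] = load(spec[key])
    if "nucleus_mask" in spec:
        out["nucleus_mask"] = load(spec["nucleus_mask"]) > 0.5
    out["subregion_masks"] = {
        name: load(rel) > 0.5 for name, rel in spec.get("subregion_masks", {}).items()
    }
    out["controls"] = [load(rel) for rel in spec.get("controls", [])]
    shapes = {v.shape for k, v in out.items() if isinstance(v, np.ndarray)}
    shapes |= {m.shape for m in out["subregion_masks"].values()}
    shapes |= {c.shape for c in out["controls"]}
    if len(shapes) > 1:
        raise ValueError(f"{manifest}: image/mask shapes differ: {sorted(shapes)}")
    return out


def write_grid(grid: GridImage, stem: str | Path) -> None:
    """Serialize a grid image as float TIFF plus long-format CSV."""
    stem = Path(stem)
    write_tiff(grid.values, stem.with_suffix(".tif"))
    rows, cols = np.indices(grid.shape)
    df = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "value": grid.values.ravel(),
            "in_nucleus": grid.nucleus_mask.ravel().astype(int),
        }
    )
    for name, m in grid.subregion_masks.items():
        df[f"in_{name}"] = m.ravel().astype(int)
    df.to_csv(stem.with_suffix(".csv"), index=False, float_format=FLOAT_FORMAT)


def read_grid(stem: str | Path, pixel_size_um: float = 50.0, condition: str = "basal") -> GridImage:
    """Read a grid image written by :func:`write_grid`."""
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"))
    nr, nc = int(df["row"].max()) + 1, int(df["col"].max()) + 1
    values = df["value"].to_numpy().reshape(nr, nc)
    nucleus = df["in_nucleus"].to_numpy().reshape(nr, nc).astype(bool)
    subs = {
        col[len("in_"):]: df[col].to_numpy().reshape(nr, nc).astype(bool)
        for col in df.columns
        if col.startswith("in_") and col != "in_nucleus"
    }
    return GridImage(
        values=values,
        nucleus_mask=nucleus,
        subregion_masks=subs,
        pixel_size_um=pixel_size_um,
        condition=condition,
        slice_id=stem.stem,
    )


def write_events_csv(processed: Sequence[ProcessedTrace], path: str | Path) -> None:
    rows = [
        {
            "roi_id": pt.roi_id,
            "subregion": pt.subregion,
            "peak_time_s": e.peak_time_s,
            "amplitude": e.amplitude,
            "event_threshold": pt.event_threshold,
        }
        for pt in processed
        for e in pt.events
    ]
    cols = ["roi_id", "subregion", "peak_time_s", "amplitude", "event_threshold"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_summary_csv(
    summaries: Sequence[tuple[str, str, ActivitySummary]], path: str | Path
) -> None:
    """Write (slice_id, subregion, summary) rows as a tidy CSV."""
    rows = []
    for slice_id, subregion, s in summaries:
        row = {
            "slice_id": slice_id,
            "subregion": subregion,
            "window": s.window,
            "n_rois": s.n_rois,
            "responding_fraction": s.responding_fraction,
            "frequency_per_min": s.frequency_per_min,
            "amplitude_mean": s.amplitude_mean,
        }
        for name, v in (s.change_from_basal or {}).items():
            row[f"change_{name}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration file into a plain dict."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
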