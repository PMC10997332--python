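"""Session container I/O: one HDF5 archive per session.

Arrays (ROI traces, speed, flow) are stored as named datasets; the
metadata record, including the container schema version, travels as a
JSON string attribute.  Round trips are lossless and version-checked;
unsupported schema versions raise instead of being silently coerced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .session import Session
from .synth import Cohort, CohortGroundTruth

SCHEMA_VERSION = "1"

_REQUIRED_ARRAYS = ("traces", "speed", "flow")


class SchemaError(ValueError):
    pass


def write_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "roi_ids": session.roi_ids,
        "fs_hz": session.fs_hz,
        "mouse_id": session.mouse_id,
        "session_id": session.session_id,
        "condition": session.condition,
        "treatment": session.treatment,
        "indicator": session.indicator,
        "genotype": session.genotype,
        "traces_kind": session.traces_kind,
        "detrended": session.detrended,
        "meta": session.meta,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=session.traces)
        f.create_dataset("speed", data=session.speed)
        f.create_dataset("flow", data=session.flow)
        markers = session.markers
        f.create_dataset("markers/time_s",
                         data=markers["time_s"].to_numpy(dtype=float))
        types = markers["type"].astype(str).to_list() if len(markers) else []
        f.create_dataset("markers/type",
                         data=np.array(types, dtype=h5py.string_dtype()))
        if "duration_s" in markers.columns and len(markers):
            f.create_dataset(
                "markers/duration_s",
                data=markers["duration_s"].to_numpy(dtype=float))
        f.attrs["metadata"] = json.dumps(meta)
    return path


def read_session(path: str | Path) -> Session:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "metadata" not in f.attrs:
            raise SchemaError(f"{path}: no metadata block")
        meta = json.loads(f.attrs["metadata"])
        version = meta.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"{path}: unsupported schema version {version!r} "
                f"(reader supports {SCHEMA_VERSION!r})")
        for name in _REQUIRED_ARRAYS:
            if name not in f:
                raise SchemaError(f"{path}: missing array: {name}")
        traces = f["traces"][()]
        speed = f["speed"][()]
        flow = f["flow"][()]
        marker_cols: dict[str, Any] = {}
        if "markers" in f:
            marker_cols["time_s"] = f["markers/time_s"][()]
            marker_cols["type"] = [t.decode() if isinstance(t, bytes) else t
                                   for t in f["markers/type"][()]]
            if "markers/duration_s" in f:
                marker_cols["duration_s"] = f["markers/duration_s"][()]
    n = traces.shape[1] if traces.ndim == 2 else -1
    for name, arr in (("speed", speed), ("flow", flow)):
        if arr.shape != (n,):
            raise SchemaError(f"{path}: corrupted array: {name} has shape "
                              f"{arr.shape}, expected ({n},)")
    markers = pd.DataFrame(marker_cols) if marker_cols else None
    kwargs = dict(
        traces=traces, roi_ids=list(meta["roi_ids"]), speed=speed,
        flow=flow, fs_hz=float(meta["fs_hz"]), mouse_id=meta["mouse_id"],
        session_id=meta["session_id"], condition=meta["condition"],
        treatment=meta["treatment"], indicator=meta["indicator"],
        genotype=meta["genotype"], traces_kind=meta["traces_kind"],
        detrended=bool(meta["detrended"]), meta=meta.get("meta", {}),
    )
    if markers is not None:
        kwargs["markers"] = markers
    return Session(**kwargs)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> list[Path]:
    """One HDF5 file per session plus a ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [write_session(s, out_dir / f"{s.session_id}.h5")
             for s in cohort.sessions]
    sidecar = {
        "ground_truth": cohort.truth.to_jsonable(),
        "sim_config": cohort.cfg.to_dict(),
        "geometry": {
            "coords_mm": {k: list(v)
                          for k, v in cohort.geometry.coords_mm.items()},
            "bregma_lambda_mm": cohort.geometry.bregma_lambda_mm,
        },
    }
    (out_dir / "ground_truth.json").write_text(
        json.dumps(sidecar, indent=1))
    return paths


def read_sessions(in_dir: str | Path) -> list[Session]:
    in_dir = Path(in_dir)
    return [read_session(p) for p in sorted(in_dir.glob("*.h5"))]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the full configuration, recorded in every artifact."""
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
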