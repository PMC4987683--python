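"""Plain-text interchange: CSV tables, YAML configs, JSON truth records.

File formats:

- ``series.csv``: long table ``eb_id,time_h,count`` of filtered point counts.
- ``cloud_<eb>.csv``: per-EB point clouds ``time_h,x_um,y_um,z_um,intensity``.
- ``ct_matrix.csv``: genes × EBs CT matrix, empty cell = failed reaction.
- ``metadata.csv``: ``eb_id,harvest_h,group,radius_um`` (plus ``devA_h``).
- ``truth.json``: generator latents for recovery tests.
- config: YAML mirror of CohortConfig.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import EBTimeSeries, ImpulseParams
from .pointcloud import PointCloudFrame
from .qpcrnorm import ExpressionPanel

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_cloud_csv",
    "read_cloud_csv",
    "write_panel_csv",
    "read_panel_csv",
    "write_truth_json",
    "read_truth_json",
    "load_config",
    "save_config",
]


def write_series_csv(series: list[EBTimeSeries], path: str | Path) -> None:
    rows = [
        {"eb_id": s.eb_id, "time_h": t, "count": c}
        for s in series
        for t, c in zip(s.times, s.counts)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> list[EBTimeSeries]:
    df = pd.read_csv(path)
    out = []
    for eb_id, sub in df.groupby("eb_id", sort=False):
        sub = sub.sort_values("time_h")
        out.append(
            EBTimeSeries(
                eb_id=str(eb_id),
                times=sub["time_h"].to_numpy(),
                counts=sub["count"].to_numpy(),
            )
        )
    return out


def write_cloud_csv(frames: list[PointCloudFrame], path: str | Path) -> None:
    rows = []
    for f in frames:
        for (x, y, z), inten in zip(f.points, f.intensities):
            rows.append(
                {"time_h": f.time, "x_um": x, "y_um": y, "z_um": z, "intensity": inten}
            )
    pd.DataFrame(rows, columns=["time_h", "x_um", "y_um", "z_um", "intensity"]).to_csv(
        path, index=False
    )


def read_cloud_csv(path: str | Path) -> list[PointCloudFrame]:
    df = pd.read_csv(path)
    frames = []
    for t, sub in df.groupby("time_h", sort=True):
        frames.append(
            PointCloudFrame(
                time=float(t),
                points=sub[["x_um", "y_um", "z_um"]].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
            )
        )
    return frames


def write_panel_csv(
    panel: ExpressionPanel, ct_path: str | Path, metadata_path: str | Path
) -> None:
    panel.ct.to_csv(ct_path, index_label="gene")
    panel.metadata.to_csv(metadata_path, index_label="eb_id")


def read_panel_csv(ct_path: str | Path, metadata_path: str | Path) -> ExpressionPanel:
    ct = pd.read_csv(ct_path, index_col="gene")
    metadata = pd.read_csv(metadata_path, index_col="eb_id")
    return ExpressionPanel(ct=ct, metadata=metadata)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, ImpulseParams):
        return dataclasses.asdict(obj)
    if isinstance(obj, pd.DataFrame):
        return {"index": list(obj.index), "columns": list(obj.columns),
                "data": obj.to_numpy().tolist()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(truth), indent=1))


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_config(config, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    yaml.safe_dump(d, open(path, "w"), sort_keys=False)


def load_config(path: str | Path):
    from .synthgen import CohortConfig, NoiseModel

    d = yaml.safe_load(Path(path).read_text())
    if "noise_model" in d and isinstance(d["noise_model"], dict):
        d["noise_model"] = NoiseModel(**d["noise_model"])
    if "radius_bounds" in d:
        d["radius_bounds"] = tuple(d["radius_bounds"])
    return CohortConfig(**d)
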