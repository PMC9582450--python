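"""Readers and writers for the pipeline's file formats.

Images are PNG (8/16-bit) or TIFF (including 32-bit float); masks are
8-bit PNG; graphs are JSON; features, per-point profiles, patient
records and cohort tables are CSV; configs are YAML.  Write-then-read
is the identity for graphs (coordinates to 1e-9) and exact for integer
images and CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import REPORT_CLASSES, FundusImage
from .graph import VesselGraph, VesselSegment
from .stats import CohortTable, PatientRecord

TAU_COLUMNS = [f"tau_{cls}" for cls in REPORT_CLASSES]


# --------------------------------------------------------------------------- images


def read_image(path: str | Path) -> FundusImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A): take the green channel, the vessel channel
        arr = arr[..., 1]
    return FundusImage(np.asarray(arr, float), provenance=str(path))


def write_image(path: str | Path, image: FundusImage | np.ndarray) -> None:
    """PNG: rescaled to the full 8- or 16-bit range; TIFF: float32 verbatim."""
    path = Path(path)
    arr = image.pixels if isinstance(image, FundusImage) else np.asarray(image, float)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
        return
    lo, hi = float(arr.min()), float(arr.max())
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    iio.imwrite(path, (scaled * 255).round().astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


# --------------------------------------------------------------------------- graphs


def graph_to_json(graph: VesselGraph) -> str:
    d = {
        "coordinate_convention": "0-based (row, col), pixel centers at integers",
        "disk_center": graph.disk_center,
        "disk_radius_px": graph.disk_radius_px,
        "segments": [
            {
                "seg_id": s.seg_id,
                "points": s.points.tolist(),
                "radius_px": s.radius_px.tolist(),
                "av_label": s.av_label,
                "hierarchy_label": s.hierarchy_label,
            }
            for s in graph.segments
        ],
        "adjacency": {str(k): sorted(v) for k, v in graph.adjacency.items()},
    }
    return json.dumps(d)


def graph_from_json(text: str) -> VesselGraph:
    d = json.loads(text)
    segments = [
        VesselSegment(
            seg_id=s["seg_id"],
            points=np.array(s["points"], float),
            radius_px=np.array(s["radius_px"], float),
            av_label=s["av_label"],
            hierarchy_label=s["hierarchy_label"],
        )
        for s in d["segments"]
    ]
    adjacency = {int(k): set(v) for k, v in d["adjacency"].items()}
    dc = d.get("disk_center")
    return VesselGraph(
        segments=segments,
        adjacency=adjacency,
        disk_center=tuple(dc) if dc else None,
        disk_radius_px=d.get("disk_radius_px"),
    )


def save_graph(path: str | Path, graph: VesselGraph) -> None:
    Path(path).write_text(graph_to_json(graph))


def load_graph(path: str | Path) -> VesselGraph:
    return graph_from_json(Path(path).read_text())


# --------------------------------------------------------------------------- patients


def patients_to_csv(path: str | Path, records: list[PatientRecord]) -> None:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "group": r.group}
        for cls, col in zip(REPORT_CLASSES, TAU_COLUMNS):
            v = r.tau.get(cls)
            row[col] = np.nan if v is None else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def patients_from_csv(path: str | Path) -> list[PatientRecord]:
    """Read per-patient records; empty tau cells become missing (None)."""
    df = pd.read_csv(path)
    required = {"patient_id", "group", *TAU_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        tau = {}
        for cls, col in zip(REPORT_CLASSES, TAU_COLUMNS):
            v = row[col]
            tau[cls] = None if pd.isna(v) else float(v)
        records.append(PatientRecord(str(row["patient_id"]), str(row["group"]), tau))
    return records


def save_cohort_table(out_dir: str | Path, table: CohortTable) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genesis_csv": out_dir / "table_genesis.csv",
        "severity_csv": out_dir / "table_severity.csv",
        "json": out_dir / "cohort_tables.json",
    }
    table.genesis.to_csv(paths["genesis_csv"], index=False)
    table.severity.to_csv(paths["severity_csv"], index=False)
    payload = {
        "genesis": table.genesis.to_dict(orient="records"),
        "severity": table.severity.to_dict(orient="records"),
        "n_excluded": table.n_excluded,
    }
    paths["json"].write_text(json.dumps(payload, indent=1, default=float))
    return paths


# --------------------------------------------------------------------------- config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
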