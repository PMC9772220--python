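"""Plain-text serialization: TSV matrices with JSON sidecar metadata.

Everything the pipeline writes is TSV (tab-separated, header row) or JSON,
so experiment bundles stay diffable and portable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import FieldTimeSeries, LeadField
from .geometry import SensorArray
from .source_sim import MIScenario, SourceTimeSeries

__all__ = [
    "save_matrix_tsv",
    "load_matrix_tsv",
    "save_sources",
    "load_sources",
    "save_sensors",
    "load_sensors",
    "save_lead_field",
    "load_lead_field",
    "save_field",
    "load_field",
    "save_lcurve",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_matrix_tsv(path, matrix: np.ndarray, columns=None) -> None:
    df = pd.DataFrame(np.asarray(matrix), columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_matrix_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def save_sources(s: SourceTimeSeries, path) -> None:
    """Rows = nodes, columns = time samples (header: times in ms); scenario
    metadata goes to a ``.json`` sidecar."""
    path = Path(path)
    save_matrix_tsv(path, s.values, columns=[f"{t:g}" for t in s.times])
    meta = {
        "mesh_label": s.mesh_label,
        "scenario": None if s.scenario is None else vars(s.scenario),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_sources(path) -> SourceTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    times = np.array([float(c) for c in df.columns])
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    scen = meta.get("scenario")
    return SourceTimeSeries(
        df.to_numpy(dtype=float),
        times,
        meta.get("mesh_label", ""),
        MIScenario(**scen) if scen else None,
    )


def save_sensors(sensors: SensorArray, path) -> None:
    path = Path(path)
    save_matrix_tsv(path, sensors.positions, columns=["x", "y", "z"])
    _sidecar(path).write_text(
        json.dumps(
            {
                "grid_rows": sensors.grid_rows,
                "grid_cols": sensors.grid_cols,
                "spacing": sensors.spacing,
                "plane_normal": sensors.plane_normal.tolist(),
                "label": sensors.label,
            }
        )
    )


def load_sensors(path) -> SensorArray:
    path = Path(path)
    pos = load_matrix_tsv(path)
    meta = json.loads(_sidecar(path).read_text())
    return SensorArray(
        pos,
        meta["grid_rows"],
        meta["grid_cols"],
        meta["spacing"],
        np.asarray(meta["plane_normal"]),
        meta.get("label", "grid"),
    )


def save_lead_field(L: LeadField, path) -> None:
    """Stores the component-major flattened (3M) x Q design matrix."""
    path = Path(path)
    save_matrix_tsv(path, L.design_matrix("all"))
    _sidecar(path).write_text(
        json.dumps(
            {
                "n_sensors": L.n_sensors,
                "n_sources": L.n_sources,
                "source_label": L.source_label,
                "sensor_label": L.sensor_label,
                "mu0_over_4pi": L.mu0_over_4pi,
                "unit_scale": L.unit_scale,
            }
        )
    )


def load_lead_field(path) -> LeadField:
    path = Path(path)
    mat = load_matrix_tsv(path)
    meta = json.loads(_sidecar(path).read_text())
    tensor = LeadField.unflatten(mat, meta["n_sensors"])
    return LeadField(
        tensor,
        meta.get("source_label", ""),
        meta.get("sensor_label", ""),
        meta.get("mu0_over_4pi", 1e-7),
        meta.get("unit_scale", 1.0),
    )


def save_field(field: FieldTimeSeries, path) -> None:
    """Component-major stacked (3M) x T samples plus provenance sidecar."""
    path = Path(path)
    save_matrix_tsv(path, field.stacked(), columns=[f"{t:g}" for t in field.times])
    _sidecar(path).write_text(
        json.dumps(
            {
                "sensor_label": field.sensor_label,
                "provenance": field.provenance,
                "snr_db": field.snr_db,
                "seed": field.seed,
            }
        )
    )


def load_field(path) -> FieldTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    times = np.array([float(c) for c in df.columns])
    meta = json.loads(_sidecar(path).read_text())
    return FieldTimeSeries.from_stacked(
        df.to_numpy(dtype=float),
        times,
        sensor_label=meta.get("sensor_label", ""),
        provenance=meta.get("provenance", "clean"),
        snr_db=meta.get("snr_db"),
        seed=meta.get("seed"),
    )


def save_lcurve(points, path) -> None:
    df = pd.DataFrame(
        {
            "lambda": [p.lam for p in points],
            "residual_norm": [p.residual_norm for p in points],
            "solution_norm": [p.solution_norm for p in points],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
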