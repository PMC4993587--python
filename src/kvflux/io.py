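"""Reading and writing the package's plain-text formats.

Conventions: comma-separated CSV with a mandatory header row, '.' decimal,
UTF-8; units encoded in column names (time_ms, flux, pressure_mmHg,
active_um, ...).  Sweep files carry one column per step voltage labeled
``mV_<value>``; acquisition metadata (protocol, capacitance) live in a
JSON descriptor next to the CSV.  Event annotations for laser-Doppler
traces live in a sidecar JSON rather than inside the CSV so traces stay
tool-agnostic.  Malformed inputs raise :class:`FormatError` naming the
file and, where possible, the offending column.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .protocols import CurrentFamily, VoltageProtocol
from .vascular import EvokedFieldTrace, LDFTrace, PressureDiameterSeries

__all__ = [
    "write_family",
    "read_family",
    "write_pressure_series",
    "read_pressure_series",
    "write_ldf_trace",
    "read_ldf_trace",
    "write_fields",
    "read_fields",
    "write_json",
    "read_json",
    "read_yaml",
    "to_jsonable",
]

PathLike = Union[str, Path]


def _read_csv(path: PathLike) -> pd.DataFrame:
    try:
        # round_trip parsing keeps write-then-read exact at full precision
        return pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise FormatError(f"{path}: file not found") from None
    except Exception as exc:
        raise FormatError(f"{path}: could not parse CSV ({exc})") from exc


def _require_columns(df: pd.DataFrame, cols, path: PathLike):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def to_jsonable(obj):
    """Recursively convert dataclasses, numpy scalars/arrays and DataFrames
    into JSON-serializable structures."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(path: PathLike, payload) -> None:
    Path(path).write_text(json.dumps(to_jsonable(payload), indent=2, sort_keys=True) + "\n")


def read_json(path: PathLike) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except FileNotFoundError:
        raise FormatError(f"{path}: file not found") from None
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}") from exc


def read_yaml(path: PathLike) -> dict:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except FileNotFoundError:
        raise FormatError(f"{path}: file not found") from None
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: invalid YAML ({exc})") from exc
    return data or {}


# -- current families ---------------------------------------------------------

def _mv_label(v: float) -> str:
    return f"mV_{v:g}"


def write_family(family: CurrentFamily, sweeps_csv: PathLike, descriptor_json: PathLike) -> None:
    """Write sweeps as CSV (time_ms + mV_<v> columns, full precision) and a
    JSON descriptor (protocol, capacitance_pF, cell_id)."""
    df = family.sweeps.copy()
    df.columns = [_mv_label(float(c)) for c in df.columns]
    df.index.name = "time_ms"
    df.to_csv(sweeps_csv, float_format="%.17g")
    write_json(descriptor_json, {
        "protocol": family.protocol.to_dict(),
        "capacitance_pF": family.capacitance,
        "cell_id": family.cell_id,
    })


def read_family(sweeps_csv: PathLike, descriptor_json: PathLike) -> CurrentFamily:
    desc = read_json(descriptor_json)
    for key in ("protocol", "capacitance_pF"):
        if key not in desc:
            raise FormatError(f"{descriptor_json}: missing key '{key}'")
    protocol = VoltageProtocol.from_dict(desc["protocol"])
    df = _read_csv(sweeps_csv)
    _require_columns(df, ["time_ms"], sweeps_csv)
    df = df.set_index("time_ms")
    cols = {}
    for c in df.columns:
        if not c.startswith("mV_"):
            raise FormatError(f"{sweeps_csv}: unexpected column '{c}' (expected 'mV_<value>')")
        try:
            cols[c] = float(c[3:])
        except ValueError:
            raise FormatError(f"{sweeps_csv}: cannot parse voltage from column '{c}'") from None
    df = df.rename(columns=cols)
    return CurrentFamily(
        protocol=protocol,
        sweeps=df,
        capacitance=float(desc["capacitance_pF"]),
        cell_id=str(desc.get("cell_id", "")),
    )


# -- pressure myography --------------------------------------------------------

def write_pressure_series(series: PressureDiameterSeries, csv_path: PathLike) -> None:
    series.data.to_csv(csv_path, index=False, float_format="%.17g")


def read_pressure_series(csv_path: PathLike, vessel_id: str = "", condition: str = "") -> PressureDiameterSeries:
    df = _read_csv(csv_path)
    _require_columns(df, ["pressure_mmHg", "active_um", "passive_um"], csv_path)
    return PressureDiameterSeries(data=df, vessel_id=vessel_id, condition=condition)


# -- laser-Doppler traces ------------------------------------------------------

def write_ldf_trace(trace: LDFTrace, csv_path: PathLike, sidecar_json: PathLike) -> None:
    pd.DataFrame({"time_s": trace.time, "flux": trace.flux}).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    write_json(sidecar_json, {
        "biological_zero": trace.biological_zero,
        "events": [{"label": l, "start_s": a, "end_s": b} for l, a, b in trace.events],
    })


def read_ldf_trace(csv_path: PathLike, sidecar_json: Optional[PathLike] = None) -> LDFTrace:
    df = _read_csv(csv_path)
    _require_columns(df, ["time_s", "flux"], csv_path)
    zero, events = 0.0, []
    if sidecar_json is not None:
        side = read_json(sidecar_json)
        zero = float(side.get("biological_zero", 0.0))
        for i, ev in enumerate(side.get("events", [])):
            try:
                events.append((str(ev["label"]), float(ev["start_s"]), float(ev["end_s"])))
            except (KeyError, TypeError, ValueError):
                raise FormatError(f"{sidecar_json}: malformed event at index {i}") from None
    return LDFTrace(
        time=df["time_s"].to_numpy(dtype=float),
        flux=df["flux"].to_numpy(dtype=float),
        events=events,
        biological_zero=zero,
    )


# -- evoked field potentials ---------------------------------------------------

def write_fields(trace: EvokedFieldTrace, csv_path: PathLike) -> None:
    data = {"time_ms": trace.time_ms}
    for j in range(trace.sweeps.shape[0]):
        data[f"sweep_{j + 1}"] = trace.sweeps[j]
    pd.DataFrame(data).to_csv(csv_path, index=False, float_format="%.17g")


def read_fields(csv_path: PathLike, analysis_window: tuple = (0.0, 80.0)) -> EvokedFieldTrace:
    df = _read_csv(csv_path)
    _require_columns(df, ["time_ms"], csv_path)
    sweep_cols = [c for c in df.columns if c.startswith("sweep_")]
    if not sweep_cols:
        raise FormatError(f"{csv_path}: no 'sweep_<n>' columns")
    sweeps = np.vstack([df[c].to_numpy(dtype=float) for c in sweep_cols])
    return EvokedFieldTrace(
        time_ms=df["time_ms"].to_numpy(dtype=float),
        sweeps=sweeps,
        analysis_window=analysis_window,
    )
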