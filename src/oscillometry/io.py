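"""CSV/JSON readers and writers for waveforms, oscillograms, and results.

Waveforms travel as two-column CSV with unit-suffixed headers
(``time_s``, ``pressure_mmHg``); oscillograms as
(``cuff_pressure_mmHg``, ``amplitude``, ``kind``, ``normalized``).  Floats are
serialized at full precision so write/read round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .construction import MeasuredOscillogram
from .waveforms import SampledWaveform

WAVEFORM_COLUMNS = ("time_s", "pressure_mmHg")
SCHEMA_VERSION = 1


def write_waveform_csv(path, wf: SampledWaveform) -> None:
    df = pd.DataFrame({"time_s": wf.times, "pressure_mmHg": wf.values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_waveform_csv(path) -> SampledWaveform:
    """Read and validate a uniformly sampled waveform CSV.

    Rejects missing/renamed columns (units are asserted from the header
    names), non-monotone time, non-uniform sampling beyond 1e-6 s jitter, and
    non-finite values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing} (units are asserted from "
            f"the header names {list(WAVEFORM_COLUMNS)})"
        )
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["pressure_mmHg"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError(f"{path}: non-finite values")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time_s is not strictly increasing (non-monotone time)")
    mean_dt = float(np.mean(dt))
    if np.max(np.abs(dt - mean_dt)) > 1e-6:
        raise ValueError(f"{path}: non-uniform sampling (jitter beyond 1e-6 s)")
    return SampledWaveform(t, v, 1.0 / mean_dt)


def write_oscillogram_csv(path, osc: MeasuredOscillogram) -> None:
    df = pd.DataFrame(
        {
            "cuff_pressure_mmHg": osc.cuff_pressures,
            "amplitude": osc.amplitudes,
            "kind": osc.kind.value,
            "normalized": osc.normalized,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_oscillogram_csv(path, complete: bool = True) -> MeasuredOscillogram:
    """Read an oscillogram CSV (completeness is carried by the QC report)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"cuff_pressure_mmHg", "amplitude", "kind", "normalized"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    Pc = df["cuff_pressure_mmHg"].to_numpy(dtype=float)
    return MeasuredOscillogram(
        kind=str(df["kind"].iloc[0]),
        cuff_pressures=Pc,
        amplitudes=df["amplitude"].to_numpy(dtype=float),
        Pc_min=float(Pc.min()),
        Pc_max=float(Pc.max()),
        normalized=bool(df["normalized"].iloc[0]),
        complete=complete,
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_json(path, payload: dict) -> None:
    body = {"schema_version": SCHEMA_VERSION}
    body.update(_jsonable(payload))
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
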