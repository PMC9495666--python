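"""CSV/JSON readers and writers for the pipeline's on-disk interfaces.

Canonical dialects:

* markers:   ``time_s, RASI_z_mm, LASI_z_mm, RPSI_z_mm, LPSI_z_mm``
* strides:   ``cycle_index, stride_s``
* Q/P:       ``time_s, Q_m, P_mps``
* cycles:    ``cycle, T_s, f_hz, ekbar_Jkg``
* attractor: 1200 rows of ``bin, mean_Q_m, sd_Q_m, mean_P_mps, sd_P_mps``

Every JSON document written by the pipeline carries the package version
and a SHA-256 hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cycles import Attractor, GaitCycleTable
from .errors import FormatError
from .signals import MARKER_LABELS, MarkerSet, UniformSignal
from .si_metrics import StrideSeries

MARKER_COLUMNS = ["time_s"] + [f"{lab}_z_mm" for lab in MARKER_LABELS]


def config_hash(config: dict) -> str:
    """Deterministic SHA-256 of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_json(path: str | Path, payload: dict, config: dict | None = None) -> None:
    from . import __version__

    doc = dict(payload)
    doc["_meta"] = {
        "package_version": __version__,
        "config_hash": config_hash(config or {}),
        "config": config or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=float) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# --- markers ---------------------------------------------------------------


def write_markers_csv(path: str | Path, markers: MarkerSet) -> None:
    n = len(markers)
    df = pd.DataFrame({"time_s": np.arange(n) / markers.rate})
    for lab in MARKER_LABELS:
        df[f"{lab}_z_mm"] = markers.data[lab]
    df.to_csv(path, index=False, float_format="%.9f")


def read_markers_csv(path: str | Path) -> MarkerSet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"cannot parse marker CSV {path}: {exc}") from exc
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"marker CSV {path} missing column(s) {missing}")
    if len(df) < 2:
        raise FormatError(f"marker CSV {path} has fewer than 2 rows")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9))) + 2
        raise FormatError(f"marker CSV {path}: uneven sampling near line {bad}")
    rate = 1.0 / float(dt[0])
    data = {lab: df[f"{lab}_z_mm"].to_numpy() for lab in MARKER_LABELS}
    return MarkerSet(data=data, rate=rate)


# --- strides ---------------------------------------------------------------


def write_strides_csv(path: str | Path, strides: StrideSeries) -> None:
    df = pd.DataFrame(
        {"cycle_index": np.arange(len(strides)), "stride_s": strides.strides}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_strides_csv(path: str | Path) -> StrideSeries:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse strides CSV {path}: {exc}") from exc
    if "stride_s" not in df.columns:
        raise FormatError(f"strides CSV {path} missing 'stride_s' column")
    return StrideSeries(df["stride_s"].to_numpy())


# --- processed signals -----------------------------------------------------


def write_qp_csv(path: str | Path, Q: UniformSignal, P: UniformSignal) -> None:
    df = pd.DataFrame({"time_s": Q.times, "Q_m": Q.values, "P_mps": P.values})
    df.to_csv(path, index=False, float_format="%.9f")


def read_qp_csv(path: str | Path) -> tuple[UniformSignal, UniformSignal]:
    df = pd.read_csv(path)
    for col in ("time_s", "Q_m", "P_mps"):
        if col not in df.columns:
            raise FormatError(f"Q/P CSV {path} missing column {col}")
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(t[1] - t[0])
    return (
        UniformSignal(df["Q_m"].to_numpy(), rate, float(t[0])),
        UniformSignal(df["P_mps"].to_numpy(), rate, float(t[0])),
    )


def write_cycles_csv(path: str | Path, table: GaitCycleTable) -> None:
    out = table.table.rename(columns={"ekbar_jkg": "Ekbar_Jkg"})
    out.insert(0, "cycle", np.arange(len(out)))
    out.to_csv(path, index=False, float_format="%.9g")


def write_attractor_csv(path: str | Path, attractor: Attractor) -> None:
    df = pd.DataFrame(
        {
            "bin": np.arange(attractor.mean_q.size),
            "mean_Q_m": attractor.mean_q,
            "sd_Q_m": attractor.sd_q,
            "mean_P_mps": attractor.mean_p,
            "sd_P_mps": attractor.sd_p,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
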