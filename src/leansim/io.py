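"""Trial and table file formats.

A trial is a CSV (``time_s,cop_ap_cm,cop_ml_cm``) plus a JSON sidecar of
the same stem holding ``target_onset_s``, ``sampling_hz``, ``target_id``
and free-form metadata.  Values are serialized with 9 significant digits;
on read the time axis is snapped back to the exact uniform grid (after a
gap check on the raw values), so a write -> read -> write cycle is
idempotent.  Feature/gain/stats tables are TSV with provenance header
comments (``# key=value``).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .trial import COPTrial

_SIDEcar_KEYS = ("target_onset_s", "sampling_hz", "target_id")


def _paths(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".csv":
        return p, p.with_suffix(".json")
    return p.with_suffix(".csv"), p.with_suffix(".json")


def write_trial(trial: COPTrial, path) -> Path:
    """Write the CSV + JSON sidecar pair; returns the CSV path."""
    csv_path, json_path = _paths(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(csv_path, "w") as fh:
        fh.write("time_s,cop_ap_cm,cop_ml_cm\n")
        for t, a, m in zip(trial.time, trial.cop_ap, trial.cop_ml):
            # +0.0 normalizes negative zero so rewriting parsed values
            # is byte-identical
            fh.write(f"{t + 0.0:.9g},{a + 0.0:.9g},{m + 0.0:.9g}\n")
    sidecar = {
        "target_onset_s": trial.target_onset,
        "sampling_hz": trial.sampling_hz,
        "target_id": int(trial.target_id),
        "metadata": trial.metadata,
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path


def read_trial(path) -> COPTrial:
    """Read a trial pair back; raises :class:`FormatError` on any defect."""
    csv_path, json_path = _paths(path)
    if not json_path.exists():
        raise FormatError(f"missing sidecar file {json_path}")
    with open(json_path) as fh:
        sidecar = json.load(fh)
    for key in _SIDEcar_KEYS:
        if key not in sidecar:
            raise FormatError(f"sidecar {json_path} missing required key '{key}'")

    df = pd.read_csv(csv_path)
    expected = ["time_s", "cop_ap_cm", "cop_ml_cm"]
    if list(df.columns) != expected:
        raise FormatError(f"{csv_path}: header must be {','.join(expected)}")
    time = df["time_s"].to_numpy(float)
    fs = float(sidecar["sampling_hz"])
    dt = 1.0 / fs
    steps = np.diff(time)
    bad = np.nonzero(np.abs(steps - dt) > 1e-4 * dt)[0]
    if bad.size:
        raise FormatError(
            f"{csv_path}: non-uniform time grid at row index {int(bad[0]) + 1} "
            f"(step {steps[bad[0]]:.6g} s, expected {dt:.6g} s)"
        )
    # snap to the exact grid the writer discretized
    time = time[0] + np.arange(time.size) / fs
    try:
        return COPTrial(
            time=time,
            cop_ap=df["cop_ap_cm"].to_numpy(float),
            cop_ml=df["cop_ml_cm"].to_numpy(float),
            target_onset=float(sidecar["target_onset_s"]),
            target_id=int(sidecar["target_id"]),
            sampling_hz=fs,
            metadata=sidecar.get("metadata", {}),
        )
    except ValidationError as exc:
        raise FormatError(f"{csv_path}: {exc}") from exc


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """TSV with ``# key=value`` provenance header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for key, value in (provenance or {}).items():
        buf.write(f"# {key}={value}\n")
    df.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())
    return path


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a provenance-TSV back into (frame, provenance dict)."""
    path = Path(path)
    prov = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("# ") and "=" in line:
            key, _, value = line[2:].strip().partition("=")
            prov[key] = value
        else:
            body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t")
    return df, prov
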