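"""Plain-text signal and cohort I/O.

Signals are two-column CSV files (time_s, pressure_mmHg) with a JSON sidecar
(`<name>.json`) carrying patient id, channel, sampling rate, site, and a
ground-truth block when the signal is synthetic. A cohort is a directory of
such pairs plus a manifest CSV with one row per patient.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import PressureWaveform

MANIFEST_COLUMNS = ("patient_id", "invasive_path", "cuff_path",
                    "flush_path", "site")


def write_signal(path, waveform: PressureWaveform, meta: dict | None = None):
    """Write a waveform as CSV plus its JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": waveform.times,
                       "pressure_mmHg": waveform.samples})
    df.to_csv(path, index=False, float_format="%.6g")
    sidecar = {"channel": waveform.channel,
               "sampling_rate_hz": waveform.sampling_rate,
               "t0_s": waveform.t0}
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_signal(path):
    """Read a waveform written by :func:`write_signal`.

    Returns ``(waveform, sidecar)``; a malformed file raises ValueError
    with the path in the message.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        wf = PressureWaveform(df["pressure_mmHg"].to_numpy(),
                              float(sidecar["sampling_rate_hz"]),
                              channel=sidecar.get("channel", "invasive"),
                              t0=float(sidecar.get("t0_s", 0.0)))
    except (KeyError, ValueError, OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed signal file {path}: {exc}") from exc
    return wf, sidecar


def write_cohort(out_dir, patients) -> Path:
    """Write a synthetic cohort as signal pairs plus a manifest CSV.

    Sidecars carry the generator's ground-truth block (true central and
    brachial pressures, the device estimate, and the condition label).
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        truth = {"synthetic": True,
                 "condition": p.condition,
                 "true_central": list(p.true_central),
                 "true_brachial": list(p.true_brachial)}
        if p.device_estimate is not None:
            truth["device_estimate"] = list(p.device_estimate)
        row = {"patient_id": p.patient_id, "site": p.site,
               "invasive_path": "", "cuff_path": "", "flush_path": ""}
        if p.invasive is not None:
            f = out_dir / f"{p.patient_id}_invasive.csv"
            write_signal(f, p.invasive,
                         {"patient_id": p.patient_id, "site": p.site,
                          "ground_truth": truth})
            row["invasive_path"] = f.name
        if p.cuff is not None:
            f = out_dir / f"{p.patient_id}_cuff.csv"
            write_signal(f, p.cuff,
                         {"patient_id": p.patient_id, "site": p.site,
                          "ground_truth": truth})
            row["cuff_path"] = f.name
        if p.flush is not None:
            f = out_dir / f"{p.patient_id}_flush.csv"
            write_signal(f, p.flush,
                         {"patient_id": p.patient_id, "site": p.site,
                          "ground_truth": p.flush_truth})
            row["flush_path"] = f.name
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest, index=False)
    return manifest


def read_manifest(manifest_path):
    """Load a manifest into per-patient records of loaded waveforms.

    Returns a list of dicts with keys patient_id, site, invasive, cuff,
    flush (waveforms or None), sidecars, and load_errors (list of str).
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str).fillna("")
    base = manifest_path.parent
    records = []
    for row in df.itertuples():
        rec = {"patient_id": row.patient_id, "site": row.site,
               "invasive": None, "cuff": None, "flush": None,
               "sidecars": {}, "load_errors": []}
        for chan in ("invasive", "cuff", "flush"):
            rel = getattr(row, f"{chan}_path", "")
            if not rel:
                continue
            try:
                wf, sidecar = read_signal(base / rel)
                rec[chan] = wf
                rec["sidecars"][chan] = sidecar
            except ValueError as exc:
                rec["load_errors"].append(str(exc))
        records.append(rec)
    return records
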