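"""Reading and writing recordings and cohort artifacts.

Native on-disk format: one CSV matrix (channels x samples, one row per
channel) plus a JSON sidecar holding sampling rate, channel labels, subject
metadata and epoch boundaries.  EDF files are read through MNE when it is
installed; EDF export is not provided (no writer library is part of the
package's dependency set).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Recording

__all__ = ["write_recording", "read_recording", "write_cohort", "read_cohort"]


def write_recording(recording: Recording, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.csv`` (samples) and ``<path>.json`` (metadata)."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    np.savetxt(csv_path, recording.samples, delimiter=",", fmt="%.8g")
    meta = {
        "fs": recording.fs,
        "ch_names": recording.ch_names,
        "subject_id": recording.subject_id,
        "group": recording.group,
        "age": recording.age,
        "sex": recording.sex,
        "epochs": [[int(a), int(b)] for a, b in recording.epochs],
    }
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path


def _read_csv_pair(csv_path: Path) -> Recording:
    json_path = csv_path.with_suffix(".json")
    if not json_path.exists():
        raise FileNotFoundError(f"metadata sidecar {json_path} missing")
    meta = json.loads(json_path.read_text())
    samples = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    if samples.shape[0] != len(meta["ch_names"]):
        raise ValueError(
            f"{csv_path}: {samples.shape[0]} rows but "
            f"{len(meta['ch_names'])} channel labels (truncated file?)"
        )
    return Recording(
        samples=samples,
        fs=float(meta["fs"]),
        ch_names=list(meta["ch_names"]),
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
        age=float(meta["age"]),
        sex=str(meta["sex"]),
        epochs=[tuple(e) for e in meta.get("epochs", [])],
    )


def _read_edf(path: Path, meta: dict | None = None) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sidecar = path.with_suffix(".json")
    meta = meta or (json.loads(sidecar.read_text()) if sidecar.exists() else {})
    if "fs" in meta and abs(float(meta["fs"]) - raw.info["sfreq"]) > 1e-6:
        raise ValueError(
            f"{path}: sidecar fs {meta['fs']} does not match EDF header "
            f"{raw.info['sfreq']}"
        )
    return Recording(
        samples=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        subject_id=str(meta.get("subject_id", path.stem)),
        group=str(meta.get("group", "HC")),
        age=float(meta.get("age", np.nan)),
        sex=str(meta.get("sex", "female")),
        epochs=[tuple(e) for e in meta.get("epochs", [])],
    )


def read_recording(path: str | Path) -> Recording:
    """Load a recording from a CSV+JSON pair or an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix == "":
        path = path.with_suffix(".csv")
    if path.suffix == ".csv":
        return _read_csv_pair(path)
    raise ValueError(f"unsupported recording format: {path.suffix}")


def write_cohort(
    recordings: list[Recording], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write every recording plus ``manifest.csv`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out / rec.subject_id)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def read_cohort(in_dir: str | Path) -> tuple[list[Recording], pd.DataFrame]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    recs = [read_recording(in_dir / sid) for sid in manifest["subject_id"]]
    return recs, manifest
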