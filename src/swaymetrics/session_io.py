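"""On-disk session layout and result tables.

A session directory holds one CSV per modality plus JSON metadata::

    <session_dir>/
        meta.json    subject_id, group, per-modality rates and units
        cop.csv      header "ML,AP"; millimetres at 90 Hz
        emg.csv      header "L_TA,...,R_S"; millivolts at 1600 Hz
        eeg.csv      64 montage labels; microvolts at 4096 Hz
        hr.csv       header "HR"; bpm at 1 Hz

``eeg.csv`` may be replaced by an EDF file ``eeg.edf`` (read through
:mod:`mne` when installed), in which case the EDF header rate takes
precedence over ``meta.json``.  CSV values are written with 10
significant digits, so a read-back session matches the written one to
better than 1e-9 relative.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .group_stats import ComparisonRecord
from .session import Session, TimeSeries, ValidationError

__all__ = ["read_session", "write_session", "write_comparison_table"]

_MODALITY_FILES = {
    "cop": "cop.csv",
    "emg": "emg.csv",
    "eeg": "eeg.csv",
    "hr": "hr.csv",
}

_FLOAT_FMT = "%.10g"


class SessionIOError(IOError):
    """A session directory is missing files or cannot be written."""


def write_session(session: Session, session_dir) -> Path:
    """Write ``session`` in the canonical layout; refuses invalid data."""
    session.validate()
    out = Path(session_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": session.subject_id,
        "group": session.group,
        "rates": {},
        "units": {},
        "metadata": _jsonable(session.metadata),
    }
    for name, fname in _MODALITY_FILES.items():
        ts = session.modality(name)
        meta["rates"][name] = ts.rate
        meta["units"][name] = ts.units
        df = pd.DataFrame(np.asarray(ts.values, dtype=np.float64),
                          columns=ts.channel_labels)
        df.to_csv(out / fname, index=False, float_format=_FLOAT_FMT)
    (out / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out


def read_session(session_dir) -> Session:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`SessionIOError` naming any missing file and
    :class:`~swaymetrics.session.ValidationError` on rate mismatches or
    unknown group labels.
    """
    src = Path(session_dir)
    meta_path = src / "meta.json"
    if not meta_path.exists():
        raise SessionIOError(f"missing metadata file: {meta_path}")
    meta = json.loads(meta_path.read_text())

    parts: dict[str, TimeSeries] = {}
    for name, fname in _MODALITY_FILES.items():
        rate = float(meta["rates"][name])
        units = meta.get("units", {}).get(name, "")
        if name == "eeg" and not (src / fname).exists() and (src / "eeg.edf").exists():
            parts[name] = _read_edf(src / "eeg.edf", units)
            continue
        path = src / fname
        if not path.exists():
            raise SessionIOError(f"missing modality file: {fname}")
        df = pd.read_csv(path)
        parts[name] = TimeSeries(df.to_numpy(dtype=float), rate,
                                 list(df.columns), units)

    session = Session(
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
        cop=parts["cop"],
        emg=parts["emg"],
        eeg=parts["eeg"],
        hr=parts["hr"],
        metadata=meta.get("metadata", {}),
    )
    session.validate()
    return session


def _read_edf(path: Path, units: str) -> TimeSeries:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise SessionIOError(
            "eeg.edf present but the optional 'mne' dependency is not "
            "installed; install swaymetrics[edf]"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # EDF stores volts for EEG channel kinds; canonical units are microvolts.
    data = raw.get_data().T * 1e6
    return TimeSeries(data, float(raw.info["sfreq"]), list(raw.ch_names),
                      units or "uV")


def write_comparison_table(records: list[ComparisonRecord], path) -> Path:
    """Write comparison records as CSV, sorted feature-major then phase.

    Columns: feature, phase, test, p_value, p_adjusted, cliff_delta,
    magnitude, significant, flags.
    """
    if not records:
        raise ValueError("no comparison records to write")
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    df["flags"] = df["flags"].map(lambda f: ";".join(f))
    df = df[["feature", "phase", "test", "p_value", "p_adjusted",
             "cliff_delta", "magnitude", "significant", "flags"]]
    df = df.sort_values(["feature", "phase"], kind="mergesort").reset_index(drop=True)
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False, float_format=_FLOAT_FMT)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
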