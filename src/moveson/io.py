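"""Readers and writers for the delimited-text and event formats.

Trajectories and record tables are plain delimited text with a
provenance header (comment lines starting ``#`` carrying a JSON object
with the seed and a config hash), so every artefact can be traced to
the run that produced it.  Event streams are written as JSON lines
(optionally preceded by a provenance line) or as a type-0 Standard MIDI
File via a small built-in writer.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import RECORD_COLUMNS
from .simulate.trajectory import Trajectory
from .sonification import EventStream, GM_PROGRAMS

__all__ = ["read_trajectory", "write_trajectory", "write_events",
           "read_events", "write_records", "read_records", "make_provenance"]

TRAJ_COLUMNS = ["t_s", "x_cm", "y_cm", "z_cm", "valid_flag"]


def make_provenance(config: dict | None = None, seed: int | None = None) -> dict:
    """Provenance stamp: config hash + seed + package version."""
    from . import __version__
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {"config_hash": hashlib.sha1(blob).hexdigest()[:12],
            "seed": seed, "moveson": __version__}


def _header_lines(provenance: dict | None) -> str:
    if provenance is None:
        return ""
    return "# moveson-provenance: " + json.dumps(provenance, sort_keys=True) + "\n"


def write_trajectory(traj: Trajectory, path: str | Path,
                     provenance: dict | None = None) -> None:
    path = Path(path)
    prov = provenance or make_provenance(
        {"source_id": traj.source_id, **traj.meta},
        traj.meta.get("seed"))
    lines = [_header_lines(prov).rstrip("\n"),
             f"# rate_hz: {traj.rate_hz}",
             ",".join(TRAJ_COLUMNS)]
    for i in range(len(traj)):
        lines.append(f"{traj.t[i]:.6f},{traj.x[i]:.6f},{traj.y[i]:.6f},"
                     f"{traj.z[i]:.6f},{int(traj.valid[i])}")
    path.write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    text = path.read_text().splitlines()
    if not any(line.strip() and not line.startswith("#") for line in text):
        raise ValueError(f"{path}: empty trajectory file")
    rate = 60.0
    meta: dict = {}
    rows = []
    header_seen = False
    for lineno, line in enumerate(text, start=1):
        if line.startswith("#"):
            if "rate_hz:" in line:
                rate = float(line.split("rate_hz:")[1])
            if "moveson-provenance:" in line:
                meta["provenance"] = json.loads(
                    line.split("moveson-provenance:")[1])
            continue
        if not line.strip():
            continue
        if not header_seen:
            if line.split(",") != TRAJ_COLUMNS:
                raise ValueError(f"{path}:{lineno}: unexpected header "
                                 f"{line!r}")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != len(TRAJ_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected "
                             f"{len(TRAJ_COLUMNS)} fields, got {len(parts)}")
        try:
            rows.append([float(v) for v in parts])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: {e}") from None
    arr = np.asarray(rows)
    return Trajectory(t=arr[:, 0], x=arr[:, 1], y=arr[:, 2], z=arr[:, 3],
                      valid=arr[:, 4].astype(bool), rate_hz=rate,
                      source_id=path.stem, meta=meta)


# ---------------------------------------------------------------- events
def write_events(stream: EventStream, path: str | Path,
                 fmt: str | None = None,
                 provenance: dict | None = None) -> None:
    """Write an event stream as JSON lines or a Standard MIDI File."""
    path = Path(path)
    if fmt is None:
        fmt = "midi" if path.suffix.lower() in (".mid", ".midi") else "jsonl"
    if fmt == "jsonl":
        head = ""
        if provenance is not None:
            head = json.dumps({"_provenance": provenance},
                              sort_keys=True) + "\n"
        path.write_text(head + stream.to_jsonl())
    elif fmt == "midi":
        path.write_bytes(_smf_bytes(stream))
    else:
        raise ValueError(f"unknown event format {fmt!r}")


def read_events(path: str | Path) -> list[dict]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        if "_provenance" in obj:
            continue
        out.append(obj)
    return out


def _vlq(value: int) -> bytes:
    """MIDI variable-length quantity."""
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _freq_to_midi(freq: float) -> int:
    return int(np.clip(round(69 + 12 * np.log2(freq / 440.0)), 0, 127))


def _smf_bytes(stream: EventStream, ppq: int = 480,
               tempo_us: int = 500_000) -> bytes:
    """Minimal type-0 Standard MIDI File: one track, one channel.

    Frequency maps to the nearest MIDI note, loudness (dB attenuation)
    to velocity, timbre zone to a General-MIDI program.
    """
    ticks_per_s = ppq * 1_000_000 / tempo_us
    track = bytearray()
    track += _vlq(0) + b"\xff\x51\x03" + struct.pack(">I", tempo_us)[1:]
    cursor = 0
    program = None
    for ev in stream.events:
        p = ev.params
        prog = GM_PROGRAMS[p.timbre_zone]
        note = _freq_to_midi(p.frequency)
        vel = max(1, min(127, round(127 * 10 ** (p.loudness_db / 20.0))))
        on = int(round(ev.onset_s * ticks_per_s))
        off = int(round(ev.offset_s * ticks_per_s))
        if prog != program:
            track += _vlq(max(on - cursor, 0)) + bytes([0xC0, prog])
            cursor = max(on, cursor)
            program = prog
        track += _vlq(max(on - cursor, 0)) + bytes([0x90, note, vel])
        cursor = max(on, cursor)
        track += _vlq(max(off - cursor, 0)) + bytes([0x80, note, 0])
        cursor = max(off, cursor)
    track += _vlq(0) + b"\xff\x2f\x00"
    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, ppq)
    return header + b"MTrk" + struct.pack(">I", len(track)) + bytes(track)


# ---------------------------------------------------------------- tables
def write_records(records: pd.DataFrame, path: str | Path,
                  provenance: dict | None = None) -> None:
    """Write a smoothness-record table (fixed leading column order)."""
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_lines(provenance))
        records[cols].to_csv(fh, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------- ephys
def write_ephys(rec, path: str | Path, provenance: dict | None = None) -> None:
    """Write a recording as an .npz array container + JSON sidecar manifest."""
    from .neurophys.recording import EphysRecording  # noqa: F401 (doc link)
    path = Path(path)
    np.savez_compressed(path, eeg=rec.eeg, emg=rec.emg, events=rec.events)
    manifest = {
        "eeg_channels": list(rec.eeg_channels),
        "emg_channels": list(rec.emg_channels),
        "rate_hz": rec.rate_hz,
        "lesioned_hemisphere": rec.lesioned_hemisphere,
        "trained_arm": rec.trained_arm,
        "provenance": provenance or make_provenance(rec.meta.get("design"),
                                                    None),
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(manifest, indent=1, default=str))


def read_ephys(path: str | Path):
    from .neurophys.recording import EphysRecording
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_ephys_edf(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        eeg, emg, events = data["eeg"], data["emg"], data["events"]
    manifest = json.loads(path.with_suffix(".json").read_text())
    return EphysRecording(
        eeg=eeg, emg=emg, events=events,
        eeg_channels=manifest["eeg_channels"],
        emg_channels=manifest["emg_channels"],
        rate_hz=manifest["rate_hz"],
        lesioned_hemisphere=manifest.get("lesioned_hemisphere"),
        trained_arm=manifest.get("trained_arm"),
        meta={"provenance": manifest.get("provenance")},
    )


def read_ephys_edf(path: str | Path, emg_channels: tuple[str, ...] = ("DELT",)):
    """Ingest a real EDF recording (EEG + EMG channels by name).

    Channels whose names match ``emg_channels`` (case-insensitive) become
    EMG; everything else is treated as EEG.  Values are converted from
    volts to microvolts.  Event markers are not read from EDF
    annotations; detect them from the EMG with
    :func:`moveson.neurophys.detect_onsets`.
    """
    import mne

    from .neurophys.recording import EphysRecording
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = raw.ch_names
    emg_set = {c.lower() for c in emg_channels}
    emg_idx = [i for i, c in enumerate(names) if c.lower() in emg_set]
    eeg_idx = [i for i, c in enumerate(names) if c.lower() not in emg_set]
    data = raw.get_data() * 1e6  # V -> uV
    return EphysRecording(
        eeg=data[eeg_idx], emg=data[emg_idx] if emg_idx else
        np.zeros((1, data.shape[1])),
        eeg_channels=[names[i] for i in eeg_idx],
        emg_channels=[names[i] for i in emg_idx] or ["EMG"],
        rate_hz=float(raw.info["sfreq"]),
        meta={"source": str(path)},
    )
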