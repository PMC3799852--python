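"""File formats: EDF continuous recordings with a sidecar events TSV, and a
compressed array container for epoch sets.

Recordings are written as plain EDF (16-bit, one-second data records,
microvolt physical dimension) with a tab-separated events file holding
0-based sample indices: columns ``onset_sample``, ``duration_samples``,
``code``, ``row``, ``col``, ``is_target``.  Reading goes through MNE.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .recording import ContinuousRecording, EpochSet, Event

EVENT_COLUMNS = ("onset_sample", "duration_samples", "code", "row", "col",
                 "is_target")


def _fixed(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii", "replace")
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, rec: ContinuousRecording) -> Path:
    """Write a recording as plain EDF (16-bit), one-second data records.

    The sampling rate must be an integer (samples per one-second record).
    The last record is zero-padded; the true sample count is recoverable from
    the events sidecar or by trimming trailing padding.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidArgumentError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))

    data = np.zeros((n_ch, n_records * spr))
    data[:, :rec.n_samples] = rec.data

    phys_max = max(1.0, float(np.abs(data).max()) * 1.000001)
    # write the limit at the precision the 8-char header field carries and
    # scale with the written value, so reader and writer agree exactly
    pm_str = f"{phys_max:.6g}"
    phys_max = float(pm_str)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    gain = (phys_max - phys_min) / (dig_max - dig_min)

    header = b""
    header += _fixed("0", 8)                      # version
    header += _fixed("X X X X", 80)               # patient id
    header += _fixed("Startdate X X X X", 80)     # recording id
    header += _fixed("01.01.00", 8)               # start date
    header += _fixed("00.00.00", 8)               # start time
    header += _fixed(str(256 * (n_ch + 1)), 8)    # header bytes
    header += _fixed("", 44)                      # reserved
    header += _fixed(str(n_records), 8)
    header += _fixed("1", 8)                      # record duration (s)
    header += _fixed(str(n_ch), 4)

    header += b"".join(_fixed(lbl, 16) for lbl in rec.channel_labels)
    header += b"".join(_fixed("AgAgCl electrode", 80) for _ in range(n_ch))
    header += b"".join(_fixed("uV", 8) for _ in range(n_ch))
    header += b"".join(_fixed(f"-{pm_str}", 8) for _ in range(n_ch))
    header += b"".join(_fixed(pm_str, 8) for _ in range(n_ch))
    header += b"".join(_fixed(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(_fixed(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_fixed("", 80) for _ in range(n_ch))
    header += b"".join(_fixed(str(spr), 8) for _ in range(n_ch))
    header += b"".join(_fixed("", 32) for _ in range(n_ch))

    digital = np.clip(np.round((data - phys_min) / gain) + dig_min,
                      dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def write_events_tsv(path: str | Path, events: list[Event]) -> Path:
    path = Path(path)
    df = pd.DataFrame([{
        "onset_sample": ev.sample,
        "duration_samples": ev.duration_samples,
        "code": ev.code,
        "row": ev.row,
        "col": ev.col,
        "is_target": int(ev.is_target),
    } for ev in events], columns=list(EVENT_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, sep="\t")
    return [Event(sample=int(r.onset_sample), code=str(r.code),
                  row=int(r.row), col=int(r.col),
                  is_target=bool(r.is_target),
                  duration_samples=int(r.duration_samples))
            for r in df.itertuples()]


def write_recording(basepath: str | Path, rec: ContinuousRecording,
                    ) -> tuple[Path, Path]:
    """Write ``<base>.edf`` plus ``<base>_events.tsv``."""
    basepath = Path(basepath)
    edf = write_edf(basepath.with_suffix(".edf"), rec)
    tsv = write_events_tsv(basepath.parent / f"{basepath.stem}_events.tsv",
                           rec.events)
    return edf, tsv


def read_recording(edf_path: str | Path,
                   events_path: str | Path | None = None,
                   ) -> ContinuousRecording:
    """Read an EDF recording (via MNE) and its sidecar events TSV."""
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    events: list[Event] = []
    if events_path is None:
        cand = Path(edf_path).parent / f"{Path(edf_path).stem}_events.tsv"
        events_path = cand if cand.exists() else None
    if events_path is not None:
        events = read_events_tsv(events_path)
    return ContinuousRecording(
        data=data_uv, fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names), events=events,
        provenance=[f"read from {Path(edf_path).name}"])


def save_epochs(path: str | Path, epochs: EpochSet) -> Path:
    """Compressed array container (npz) with a JSON header."""
    path = Path(path)
    header = {
        "fs": epochs.fs,
        "channel_labels": list(epochs.channel_labels),
        "baseline_window": list(epochs.baseline_window)
        if epochs.baseline_window else None,
        "reference": epochs.reference,
        "provenance": list(epochs.provenance),
        "events": [[ev.sample, ev.code, ev.row, ev.col, int(ev.is_target),
                    ev.duration_samples] for ev in epochs.events],
    }
    np.savez_compressed(path, data=epochs.data, time=epochs.time,
                        labels=epochs.labels.astype(str),
                        header=np.array(json.dumps(header)))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_epochs(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        events = [Event(sample=int(s), code=c, row=int(r), col=int(co),
                        is_target=bool(t), duration_samples=int(d))
                  for s, c, r, co, t, d in header["events"]]
        return EpochSet(
            data=z["data"], time=z["time"], labels=z["labels"],
            fs=float(header["fs"]),
            channel_labels=tuple(header["channel_labels"]),
            baseline_window=tuple(header["baseline_window"])
            if header["baseline_window"] else None,
            reference=header["reference"],
            provenance=list(header["provenance"]),
            events=events)
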