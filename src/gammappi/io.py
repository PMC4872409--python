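"""Session readers and writers.

Formats
-------
``native-hdf5``
    One HDF5 container holding the signal plus metadata attributes, with two
    tidy CSV sidecars (``<base>.events.csv``, ``<base>.trials.csv``).
    Lossless: ``read_session(write_session(s)) == s``.
``csv-pair``
    Plain-text alternative: signal as a CSV matrix (one column per channel)
    with the same event/trial sidecars. Lossy only through decimal printing.
``edf``
    European Data Format, read-only, for interoperability with acquisition
    software. Signal and sampling rate come from the EDF header; events and
    trials come from the CSV sidecars when present.

Event CSV columns: ``onset_s, kind, level_db, duration_ms``.
Trial CSV columns: ``index, kind, pulse_onset_s, startle_amp``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .session import Event, Recording, Session, SessionValidationError, TrialRecord

FORMATS = ("native-hdf5", "csv-pair", "edf")


def _base(path) -> Path:
    p = Path(path)
    return p.parent / p.stem


def _events_csv(path) -> Path:
    return Path(str(_base(path)) + ".events.csv")


def _trials_csv(path) -> Path:
    return Path(str(_base(path)) + ".trials.csv")


def _write_sidecars(session: Session, path) -> None:
    ev = pd.DataFrame(
        {
            "onset_s": [e.onset for e in session.events],
            "kind": [e.kind for e in session.events],
            "level_db": [e.params.get("level_db", np.nan) for e in session.events],
            "duration_ms": [e.params.get("duration_ms", np.nan) for e in session.events],
        }
    )
    ev.to_csv(_events_csv(path), index=False)
    tr = pd.DataFrame(
        {
            "index": [t.index for t in session.trials],
            "kind": [t.kind for t in session.trials],
            "pulse_onset_s": [t.pulse_onset for t in session.trials],
            "startle_amp": [t.startle_amp for t in session.trials],
        }
    )
    tr.to_csv(_trials_csv(path), index=False)


def _read_sidecars(path) -> tuple[list[Event], list[TrialRecord]]:
    events: list[Event] = []
    trials: list[TrialRecord] = []
    epath, tpath = _events_csv(path), _trials_csv(path)
    if epath.exists():
        for row in pd.read_csv(epath).itertuples(index=False):
            params = {}
            if np.isfinite(row.level_db):
                params["level_db"] = float(row.level_db)
            if np.isfinite(row.duration_ms):
                params["duration_ms"] = float(row.duration_ms)
            events.append(Event(onset=float(row.onset_s), kind=str(row.kind), params=params))
    if tpath.exists():
        df = pd.read_csv(tpath)
        for row in df.itertuples(index=False):
            trials.append(
                TrialRecord(
                    index=int(row.index),
                    kind=str(row.kind),
                    pulse_onset=float(row.pulse_onset_s),
                    startle_amp=float(row.startle_amp),
                )
            )
    return events, trials


def write_session(session: Session, path, format: str = "native-hdf5") -> None:
    """Write a validated session to disk; see module docstring for layouts."""
    if format == "native-hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("signal", data=session.recording.samples)
            dset.attrs["units"] = "uV"
            f.attrs["fs"] = session.recording.fs
            f.attrs["start_time"] = session.recording.start_time
            f.attrs["channel_ids"] = np.array(
                [str(c) for c in session.recording.channel_ids], dtype=h5py.string_dtype()
            )
            f.attrs["subject_id"] = str(session.subject_id)
            f.attrs["condition_id"] = str(session.condition_id)
            f.attrs["session_order"] = int(session.session_order)
        _write_sidecars(session, path)
    elif format == "csv-pair":
        df = pd.DataFrame(session.recording.samples.T, columns=session.recording.channel_ids)
        with open(path, "w") as fh:
            fh.write(
                f"# fs={session.recording.fs} subject={session.subject_id} "
                f"condition={session.condition_id} order={session.session_order}\n"
            )
            df.to_csv(fh, index=False)
        _write_sidecars(session, path)
    elif format == "edf":
        raise ValueError("EDF is supported read-only; use native-hdf5 or csv-pair")
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def read_session(path, format: str = "native-hdf5") -> Session:
    """Read and validate a session written by :func:`write_session` (or an EDF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native-hdf5":
        with h5py.File(path, "r") as f:
            samples = np.asarray(f["signal"])
            rec = Recording(
                samples=samples,
                fs=float(f.attrs["fs"]),
                channel_ids=[
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in f.attrs["channel_ids"]
                ],
                start_time=float(f.attrs["start_time"]),
            )
            meta = dict(
                subject_id=str(f.attrs["subject_id"]),
                condition_id=str(f.attrs["condition_id"]),
                session_order=int(f.attrs["session_order"]),
            )
        events, trials = _read_sidecars(path)
        return Session(recording=rec, events=events, trials=trials, **meta)
    if format == "csv-pair":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise SessionValidationError(f"{path}: missing metadata header line")
            meta = dict(kv.split("=") for kv in header[1:].split())
            df = pd.read_csv(fh)
        rec = Recording(samples=df.to_numpy().T, fs=float(meta["fs"]), channel_ids=list(df.columns))
        events, trials = _read_sidecars(path)
        return Session(
            recording=rec,
            events=events,
            trials=trials,
            subject_id=meta.get("subject", "s0"),
            condition_id=meta.get("condition", "unknown"),
            session_order=int(meta.get("order", 0)),
        )
    if format == "edf":
        rec = read_edf(path)
        events, trials = _read_sidecars(path)
        return Session(recording=rec, events=events, trials=trials)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


# ---------------------------------------------------------------------------
# Minimal EDF (European Data Format) support. EDF stores an ASCII header and
# int16 little-endian data records with per-signal physical/digital scaling.
# Only equal-rate continuous signals are handled (sufficient for 2-channel
# ECoG interchange); annotations channels are ignored.
# ---------------------------------------------------------------------------


def read_edf(path) -> Recording:
    """Read a (possibly minimal) EDF file into a :class:`Recording`."""
    with open(path, "rb") as f:
        hdr = f.read(256)
        if len(hdr) < 256:
            raise SessionValidationError(f"{path}: truncated EDF header")
        n_records = int(hdr[236:244].decode("ascii").strip())
        record_dur = float(hdr[244:252].decode("ascii").strip())
        ns = int(hdr[252:256].decode("ascii").strip())
        sig_hdr = f.read(ns * 256)

        # signal-header field widths: label 16, transducer 80, dim 8, phys_min 8,
        # phys_max 8, dig_min 8, dig_max 8, prefilter 80, n_samp 8, reserved 32
        off = {}
        pos = 0
        for name, w in [
            ("label", 16),
            ("transducer", 80),
            ("dim", 8),
            ("phys_min", 8),
            ("phys_max", 8),
            ("dig_min", 8),
            ("dig_max", 8),
            ("prefilter", 80),
            ("n_samp", 8),
        ]:
            off[name] = (pos, w)
            pos += w

        def col(name, conv=str):
            p, w = off[name]
            start = p * ns
            return [
                conv(sig_hdr[start + i * w : start + (i + 1) * w].decode("ascii").strip())
                for i in range(ns)
            ]

        labels = col("label")
        phys_min = col("phys_min", float)
        phys_max = col("phys_max", float)
        dig_min = col("dig_min", float)
        dig_max = col("dig_max", float)
        n_samp = col("n_samp", int)

        keep = [i for i, lab in enumerate(labels) if "annotation" not in lab.lower()]
        if not keep:
            raise SessionValidationError(f"{path}: no signal channels in EDF")
        rates = {n_samp[i] / record_dur for i in keep}
        if len(rates) != 1:
            raise SessionValidationError(f"{path}: mixed sampling rates not supported")
        fs = rates.pop()

        per_rec = sum(n_samp)
        raw = np.fromfile(f, dtype="<i2", count=n_records * per_rec)
    if raw.size != n_records * per_rec:
        raise SessionValidationError(f"{path}: EDF data shorter than header declares")
    raw = raw.reshape(n_records, per_rec)
    bounds = np.cumsum([0] + n_samp)
    chans = []
    for i in keep:
        dig = raw[:, bounds[i] : bounds[i + 1]].reshape(-1).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        chans.append(phys_min[i] + gain * (dig - dig_min[i]))
    return Recording(samples=np.vstack(chans), fs=fs, channel_ids=[labels[i] for i in keep])


def _write_edf(recording: Recording, path) -> None:
    """Write a minimal EDF file (synthetic fixture helper for tests)."""
    fs = recording.fs
    if fs != int(fs):
        raise ValueError("EDF fixture writer needs an integer sampling rate")
    ns = recording.n_channels
    record_dur = 1.0
    spr = int(fs)
    n_records = recording.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s EDF record")
    x = recording.samples[:, : n_records * spr]
    pmin, pmax = float(np.floor(x.min() - 1)), float(np.ceil(x.max() + 1))
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    dig = np.round((x - pmin) / gain + dmin).astype("<i2")

    def pad(s, w):
        b = str(s)[:w].encode("ascii")
        return b + b" " * (w - len(b))

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X", 80),
            pad("X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 * (1 + ns), 8),
            pad("", 44),
            pad(n_records, 8),
            pad("%g" % record_dur, 8),
            pad(ns, 4),
        ]
    )
    sig = b"".join(pad(c, 16) for c in recording.channel_ids)
    sig += b"".join(pad("", 80) for _ in range(ns))
    sig += b"".join(pad("uV", 8) for _ in range(ns))
    sig += b"".join(pad("%g" % pmin, 8) for _ in range(ns))
    sig += b"".join(pad("%g" % pmax, 8) for _ in range(ns))
    sig += b"".join(pad(dmin, 8) for _ in range(ns))
    sig += b"".join(pad(dmax, 8) for _ in range(ns))
    sig += b"".join(pad("", 80) for _ in range(ns))
    sig += b"".join(pad(spr, 8) for _ in range(ns))
    sig += b"".join(pad("", 32) for _ in range(ns))
    with open(path, "wb") as f:
        f.write(hdr + sig)
        for r in range(n_records):
            for c in range(ns):
                f.write(dig[c, r * spr : (r + 1) * spr].tobytes())
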