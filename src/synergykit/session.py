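"""Session data model and on-disk container.

A session is one visit: a multi-channel surface-EMG recording with the cued
trial windows (start/end sample per movement x trial x condition) and the
participant metadata.  The on-disk container is an open HDF5 layout::

    /emg        float64 dataset, channels x samples
    /events     structured dataset (movement_id, trial_index, condition,
                start_sample, end_sample), 0-based half-open [start, end)
    attrs       fs, participant_id, session_index, group, channel_names

A plain-text import path (wide CSV of samples + JSON sidecar of events and
metadata) is provided for interoperability and for text-only fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import CHANNEL_NAMES, CONDITIONS, ChannelLayout
from .errors import SchemaError

GROUPS = ("SCI", "control")


@dataclass(frozen=True)
class TrialEvent:
    """One cued trial: half-open sample window [start_sample, end_sample)."""

    movement_id: str
    trial_index: int
    condition: str
    start_sample: int
    end_sample: int


@dataclass
class SessionRecord:
    """Raw EMG plus events and metadata for one visit."""

    emg: np.ndarray                      # channels x samples, float
    fs: float = 600.0
    events: list[TrialEvent] = field(default_factory=list)
    participant_id: str = "P0"
    session_index: int = 1
    group: str = "control"
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    def events_for(self, movement_id: str | None = None,
                   condition: str | None = None) -> list[TrialEvent]:
        out = self.events
        if movement_id is not None:
            out = [e for e in out if e.movement_id == movement_id]
        if condition is not None:
            out = [e for e in out if e.condition == condition]
        return out

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.condition, None)
        return tuple(seen)


def validate_session(record: SessionRecord,
                     layout: ChannelLayout | None = None) -> None:
    """Raise :class:`SchemaError` if the record violates its invariants."""
    layout = layout or ChannelLayout()
    names = tuple(record.channel_names)
    missing = set(layout.names) - set(names)
    if missing:
        raise SchemaError(f"missing channel(s): {sorted(missing)}")
    extra = set(names) - set(layout.names)
    if extra:
        raise SchemaError(f"unknown channel(s): {sorted(extra)}")
    if record.emg.ndim != 2 or record.emg.shape[0] != len(names):
        raise SchemaError(
            f"emg shape {record.emg.shape} does not match {len(names)} channels")
    if record.fs <= 0:
        raise SchemaError("fs must be positive")
    if record.session_index < 1:
        raise SchemaError("session_index must be >= 1")
    if record.group not in GROUPS:
        raise SchemaError(f"unknown group {record.group!r}")
    n = record.n_samples
    per_condition: dict[str, list[TrialEvent]] = {}
    for e in record.events:
        if e.condition not in CONDITIONS:
            raise SchemaError(f"unknown condition label {e.condition!r}")
        if not (0 <= e.start_sample < e.end_sample <= n):
            raise SchemaError(
                f"event {e.movement_id}/{e.trial_index}/{e.condition}: "
                f"invalid window [{e.start_sample}, {e.end_sample}) for {n} samples")
        per_condition.setdefault(e.condition, []).append(e)
    for cond, evs in per_condition.items():
        evs = sorted(evs, key=lambda e: e.start_sample)
        for a, b in zip(evs, evs[1:]):
            if b.start_sample < a.end_sample:
                raise SchemaError(
                    f"overlapping events in condition {cond!r}: "
                    f"{a.movement_id}/{a.trial_index} and {b.movement_id}/{b.trial_index}")


def canonicalize_channels(record: SessionRecord,
                          layout: ChannelLayout | None = None) -> SessionRecord:
    """Reorder channels (and the signal matrix) into the canonical layout."""
    layout = layout or ChannelLayout()
    names = tuple(record.channel_names)
    if names == layout.names:
        return record
    perm = [names.index(c) for c in layout.names]
    return replace(record, emg=record.emg[perm], channel_names=layout.names)


# ---------------------------------------------------------------------------
# HDF5 container

_EVENT_DTYPE = np.dtype([
    ("movement_id", "S16"),
    ("trial_index", "i8"),
    ("condition", "S16"),
    ("start_sample", "i8"),
    ("end_sample", "i8"),
])


def write_session(record: SessionRecord, path: str | Path) -> None:
    """Write a validated session to the HDF5 container.

    Datasets are written with ``track_times=False`` so two writes of the same
    record produce byte-identical files.
    """
    validate_session(record)
    ev = np.array(
        [(e.movement_id.encode(), e.trial_index, e.condition.encode(),
          e.start_sample, e.end_sample) for e in record.events],
        dtype=_EVENT_DTYPE,
    )
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("emg", data=np.asarray(record.emg, dtype=np.float64),
                         track_times=False)
        f.create_dataset("events", data=ev, track_times=False)
        f.attrs["fs"] = float(record.fs)
        f.attrs["participant_id"] = record.participant_id
        f.attrs["session_index"] = int(record.session_index)
        f.attrs["group"] = record.group
        f.attrs["channel_names"] = [c for c in record.channel_names]


def read_session(path: str | Path,
                 layout: ChannelLayout | None = None) -> SessionRecord:
    """Read, validate and canonicalize a session from the HDF5 container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for key in ("emg", "events"):
            if key not in f:
                raise SchemaError(f"container missing dataset '/{key}'")
        emg = f["emg"][()]
        ev = f["events"][()]
        try:
            record = SessionRecord(
                emg=emg,
                fs=float(f.attrs["fs"]),
                events=[
                    TrialEvent(
                        movement_id=row["movement_id"].decode(),
                        trial_index=int(row["trial_index"]),
                        condition=row["condition"].decode(),
                        start_sample=int(row["start_sample"]),
                        end_sample=int(row["end_sample"]),
                    )
                    for row in ev
                ],
                participant_id=str(f.attrs["participant_id"]),
                session_index=int(f.attrs["session_index"]),
                group=str(f.attrs["group"]),
                channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            )
        except KeyError as exc:
            raise SchemaError(f"container missing attribute {exc}") from exc
    validate_session(record, layout)
    return canonicalize_channels(record, layout)


# ---------------------------------------------------------------------------
# Plain-text import (CSV of samples + JSON sidecar)

def read_session_csv(csv_path: str | Path, sidecar_path: str | Path,
                     layout: ChannelLayout | None = None) -> SessionRecord:
    """Import a session from a wide CSV (columns = channels, rows = samples)
    plus a JSON sidecar holding fs, events and participant metadata."""
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(sidecar_path).read_text())
    record = SessionRecord(
        emg=df.to_numpy(dtype=np.float64).T,
        fs=float(meta["fs"]),
        events=[TrialEvent(**e) for e in meta["events"]],
        participant_id=str(meta.get("participant_id", "P0")),
        session_index=int(meta.get("session_index", 1)),
        group=str(meta.get("group", "control")),
        channel_names=tuple(df.columns),
    )
    validate_session(record, layout)
    return canonicalize_channels(record, layout)


def write_session_csv(record: SessionRecord, csv_path: str | Path,
                      sidecar_path: str | Path) -> None:
    validate_session(record)
    pd.DataFrame(record.emg.T, columns=list(record.channel_names)).to_csv(
        csv_path, index=False)
    meta = {
        "fs": record.fs,
        "participant_id": record.participant_id,
        "session_index": record.session_index,
        "group": record.group,
        "events": [vars(e) for e in record.events],
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))
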