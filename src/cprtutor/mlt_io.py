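"""Reading, writing and time-aligning MLT session archives.

An MLT session is a folder (or zip) of JSON documents, one per recording,
plus a ``session.json`` manifest.  Sensor recordings hold timestamped
frames; annotation recordings hold time *intervals* carrying per-compression
manikin measurements and/or class labels.  All timers are relative to the
session start (t0 = 0); an absolute ``recording_datetime`` distinguishes
sessions from each other.
"""

from __future__ import annotations

import json
import re
import zipfile
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "MLTFormatError",
    "SensorFrame",
    "SensorRecording",
    "AnnotationInterval",
    "AnnotationRecording",
    "MLTSession",
    "MEASUREMENT_KEYS",
    "LABEL_KEYS",
    "parse_timestamp",
    "format_timestamp",
    "read_session",
    "write_session",
    "apply_offset",
]

#: Per-compression manikin measurement attributes.
MEASUREMENT_KEYS = frozenset({"compDepth", "compMeanRate", "compRelease"})
#: Per-compression class-label attributes.
LABEL_KEYS = frozenset(
    {"classRate", "classDepth", "classRelease", "armsLocked", "bodyWeight"}
)

_MANIFEST_NAME = "session.json"

# Accepts both timestamp dialects: "HH:MM:SS.fffffff" and "MM:SS.fffffff"
# (the hour field is optional on input); fractional part optional.
_TS_RE = re.compile(r"^(?:(\d+):)?([0-5]?\d):([0-5]?\d(?:\.\d+)?)$")

_TICKS_PER_SECOND = 10**7  # 100 ns resolution of the frameStamp format


class MLTFormatError(ValueError):
    """Raised when an archive or recording violates the MLT dialect."""


def parse_timestamp(text: str) -> float:
    """Parse a relative timer string to seconds.

    Both ``"HH:MM:SS.fffffff"`` and ``"MM:SS.fffffff"`` are accepted;
    resolution is preserved to 100 ns (the 7-digit fractional field).

    >>> parse_timestamp("00:00:02.0160129")
    2.0160129
    >>> parse_timestamp("00:02.0282288")
    2.0282288
    """
    if isinstance(text, (int, float)):  # tolerate already-numeric stamps
        return float(text)
    m = _TS_RE.match(text.strip())
    if m is None:
        raise MLTFormatError(f"unparseable timestamp: {text!r}")
    hours = int(m.group(1)) if m.group(1) is not None else 0
    minutes = int(m.group(2))
    seconds = float(m.group(3))
    return hours * 3600.0 + minutes * 60.0 + seconds


def format_timestamp(seconds: float) -> str:
    """Format seconds as the full ``"HH:MM:SS.fffffff"`` dialect.

    ``parse_timestamp(format_timestamp(t))`` reproduces ``t`` to 1e-7 s.
    """
    if seconds < 0:
        raise ValueError(f"negative timestamp: {seconds!r}")
    ticks = round(seconds * _TICKS_PER_SECOND)
    whole, frac = divmod(ticks, _TICKS_PER_SECOND)
    hours, whole = divmod(whole, 3600)
    minutes, secs = divmod(whole, 60)
    return f"{hours:02d}:{minutes:02d}:{secs:02d}.{frac:07d}"


@dataclass(frozen=True)
class SensorFrame:
    """One sensor update: a relative timestamp plus attribute values."""

    timestamp: float
    attributes: Mapping[str, float]

    def __post_init__(self) -> None:
        # t >= 0 is enforced at the serialisation boundary (format_timestamp)
        # so that apply_offset may pass through transiently negative times.
        for name in self.attributes:
            if not name:
                raise ValueError("empty attribute name in frame")


@dataclass
class SensorRecording:
    """A named stream of time-ordered :class:`SensorFrame` objects."""

    application_id: str
    application_name: str
    frames: list[SensorFrame] = field(default_factory=list)
    time_offset: float = 0.0

    def sort_frames(self) -> None:
        """Stable-sort frames by timestamp (preserves source order on ties)."""
        self.frames.sort(key=lambda f: f.timestamp)

    @property
    def time_span(self) -> tuple[float, float]:
        if not self.frames:
            return (0.0, 0.0)
        return (self.frames[0].timestamp, self.frames[-1].timestamp)


@dataclass
class AnnotationInterval:
    """One chest compression: a half-open time interval with payload.

    ``measurements`` may carry compDepth (mm), compMeanRate
    (compressions/min) and compRelease (mm); ``labels`` may carry
    classRate/classDepth/classRelease/armsLocked/bodyWeight in {0, 1, 2}.
    """

    start: float
    end: float
    measurements: dict[str, float] = field(default_factory=dict)
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(
                f"interval end ({self.end}) must exceed start ({self.start})"
            )
        for key, value in self.labels.items():
            if value not in (0, 1, 2):
                raise ValueError(f"label {key}={value!r} outside {{0,1,2}}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AnnotationRecording:
    """A named stream of :class:`AnnotationInterval` objects."""

    application_id: str
    application_name: str
    intervals: list[AnnotationInterval] = field(default_factory=list)
    time_offset: float = 0.0


@dataclass
class MLTSession:
    """One recorded activity: sensor + annotation recordings sharing t0 = 0."""

    session_id: str
    recording_datetime: datetime
    sensor_recordings: list[SensorRecording] = field(default_factory=list)
    annotation_recordings: list[AnnotationRecording] = field(default_factory=list)
    videos: list[str] = field(default_factory=list)

    def recording(self, application_name: str) -> Union[SensorRecording, AnnotationRecording]:
        for rec in (*self.sensor_recordings, *self.annotation_recordings):
            if rec.application_name == application_name:
                return rec
        raise KeyError(application_name)


# ---------------------------------------------------------------------------
# serialisation


def _frame_to_json(frame: SensorFrame) -> dict:
    doc = {"frameStamp": format_timestamp(frame.timestamp)}
    doc.update(frame.attributes)
    return doc


def _interval_to_json(interval: AnnotationInterval) -> dict:
    doc = {
        "start": format_timestamp(interval.start),
        "end": format_timestamp(interval.end),
    }
    doc.update(interval.labels)
    doc.update(interval.measurements)
    return doc


def _frame_from_json(doc: dict, index: int, source: str) -> SensorFrame:
    if "frameStamp" not in doc:
        raise MLTFormatError(f"{source}: frame {index} missing 'frameStamp'")
    attrs = {k: float(v) for k, v in doc.items() if k != "frameStamp"}
    return SensorFrame(timestamp=parse_timestamp(doc["frameStamp"]), attributes=attrs)


def _interval_from_json(doc: dict, index: int, source: str) -> AnnotationInterval:
    try:
        start = parse_timestamp(doc["start"])
        end = parse_timestamp(doc["end"])
    except KeyError as exc:
        raise MLTFormatError(f"{source}: interval {index} missing {exc}") from None
    labels: dict[str, int] = {}
    measurements: dict[str, float] = {}
    for key, value in doc.items():
        if key in ("start", "end"):
            continue
        if key in LABEL_KEYS:
            labels[key] = int(value)
        else:
            measurements[key] = float(value)
    return AnnotationInterval(start=start, end=end, measurements=measurements, labels=labels)


def _is_annotation_doc(doc: dict) -> bool:
    frames = doc.get("frames", [])
    return bool(frames) and "start" in frames[0] and "end" in frames[0]


def _recording_from_json(doc: dict, source: str):
    if "frames" not in doc:
        raise MLTFormatError(f"{source}: missing 'frames' list")
    app_id = str(doc.get("applicationId", ""))
    app_name = str(doc.get("applicationName", Path(source).stem))
    offset = float(doc.get("timeOffset", 0.0))
    if _is_annotation_doc(doc):
        intervals = [
            _interval_from_json(f, i, source) for i, f in enumerate(doc["frames"])
        ]
        return AnnotationRecording(app_id, app_name, intervals, time_offset=offset)
    frames = [_frame_from_json(f, i, source) for i, f in enumerate(doc["frames"])]
    rec = SensorRecording(app_id, app_name, frames, time_offset=offset)
    rec.sort_frames()
    return rec


def _recording_to_json(rec: Union[SensorRecording, AnnotationRecording]) -> dict:
    doc = {
        "applicationId": rec.application_id,
        "applicationName": rec.application_name,
        "timeOffset": rec.time_offset,
    }
    if isinstance(rec, AnnotationRecording):
        doc["frames"] = [_interval_to_json(iv) for iv in rec.intervals]
    else:
        doc["frames"] = [_frame_to_json(f) for f in rec.frames]
    return doc


def _load_json(text: str, source: str) -> dict:
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise MLTFormatError(f"{source}: invalid JSON ({exc})") from exc


def read_session(path: Union[str, Path]) -> MLTSession:
    """Read an MLT session archive from a directory or ``.zip`` file.

    Recordings are discovered through the ``session.json`` manifest when
    present, otherwise every ``*.json`` file is treated as a recording.
    Video entries are listed but never parsed.
    """
    path = Path(path)
    if zipfile.is_zipfile(path):
        documents = _read_zip(path)
    elif path.is_dir():
        documents = {
            p.name: p.read_text() for p in sorted(path.glob("*.json"))
        }
    else:
        raise MLTFormatError(f"not an MLT archive (dir or zip): {path}")

    manifest = None
    if _MANIFEST_NAME in documents:
        manifest = _load_json(documents.pop(_MANIFEST_NAME), _MANIFEST_NAME)

    session_id = "session"
    rec_dt = datetime.fromtimestamp(0)
    videos: list[str] = []
    names: Iterable[str]
    if manifest is not None:
        session_id = manifest.get("sessionId", session_id)
        if "recordingDatetime" in manifest:
            rec_dt = datetime.fromisoformat(manifest["recordingDatetime"])
        videos = list(manifest.get("videos", []))
        names = [entry["file"] for entry in manifest.get("recordings", [])]
    else:
        names = sorted(documents)

    session = MLTSession(session_id, rec_dt, videos=videos)
    for name in names:
        if name not in documents:
            raise MLTFormatError(f"manifest references missing file: {name}")
        rec = _recording_from_json(_load_json(documents[name], name), name)
        if isinstance(rec, AnnotationRecording):
            session.annotation_recordings.append(rec)
        else:
            session.sensor_recordings.append(rec)
    return session


def _read_zip(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with zipfile.ZipFile(path) as zf:
        for info in zf.infolist():
            name = Path(info.filename).name
            if name.endswith(".json"):
                out[name] = zf.read(info).decode("utf-8")
    return out


def write_session(session: MLTSession, path: Union[str, Path]) -> Path:
    """Write ``session`` as a directory archive; returns its path.

    Serialisation is deterministic: fixed key order, fixed separators and
    the full ``HH:MM:SS.fffffff`` timestamp dialect, so rewriting the same
    session yields byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    recordings = []
    for rec in (*session.sensor_recordings, *session.annotation_recordings):
        filename = f"{rec.application_name}.json"
        kind = "annotation" if isinstance(rec, AnnotationRecording) else "sensor"
        recordings.append(
            {
                "file": filename,
                "applicationId": rec.application_id,
                "applicationName": rec.application_name,
                "type": kind,
            }
        )
        _dump_json(_recording_to_json(rec), path / filename)
    manifest = {
        "sessionId": session.session_id,
        "recordingDatetime": session.recording_datetime.isoformat(),
        "recordings": recordings,
        "videos": list(session.videos),
    }
    _dump_json(manifest, path / _MANIFEST_NAME)
    return path


def _dump_json(doc: dict, path: Path) -> None:
    try:
        path.write_text(json.dumps(doc, indent=1, separators=(",", ": ")) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def apply_offset(recording, offset_seconds: float, *, allow_negative: bool = True):
    """Return a copy of ``recording`` with all times shifted by ``offset_seconds``.

    Works on both sensor and annotation recordings; the original is left
    unmodified and ordering is preserved.  With ``allow_negative=False`` a
    shift that would produce a negative start raises ``ValueError``.
    """
    if isinstance(recording, AnnotationRecording):
        intervals = [
            AnnotationInterval(
                start=iv.start + offset_seconds,
                end=iv.end + offset_seconds,
                measurements=dict(iv.measurements),
                labels=dict(iv.labels),
            )
            for iv in recording.intervals
        ]
        if not allow_negative and any(iv.start < 0 for iv in intervals):
            raise ValueError(f"offset {offset_seconds} produces negative interval start")
        return replace(recording, intervals=intervals)
    frames = [
        SensorFrame(timestamp=f.timestamp + offset_seconds, attributes=dict(f.attributes))
        for f in recording.frames
    ]
    if not allow_negative and any(f.timestamp < 0 for f in frames):
        raise ValueError(f"offset {offset_seconds} produces negative timestamp")
    return replace(recording, frames=frames)
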