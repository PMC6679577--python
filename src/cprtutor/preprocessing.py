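"""Interval table, attribute table, masking, resampling and tensor assembly.

The routine turns annotation intervals and raw sensor streams into a fixed
shape feature tensor of N compressions x S time bins x Q attributes:

1. stack all compression intervals into one interval table (with duration
   and an absolute session offset);
2. consolidate all sensor streams into one time-indexed attribute table
   (sanitised names, deduplicated timestamps, uninformative and excluded
   columns dropped);
3. mask the attribute table with each half-open interval [start, end);
4. resample each masked slice to S equal-duration bins (bin mean, with
   linear interpolation across empty bins);
5. stack to N x S x Q and min-max scale each attribute to [0, 1].

Missing updates are represented as absent (NaN), never as zeros, until the
bin means are taken -- zeros from non-updates would corrupt the means.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence, Union

import json

import numpy as np
import pandas as pd

from .mlt_io import LABEL_KEYS, MEASUREMENT_KEYS, AnnotationRecording

__all__ = [
    "PreprocessingError",
    "MaskedSeries",
    "FeatureTensor",
    "DEFAULT_EXCLUDED_JOINTS",
    "sanitize_name",
    "build_interval_table",
    "build_attribute_table",
    "mask_by_intervals",
    "resample_to_bins",
    "assemble_tensor",
]

#: Joints excluded a priori: rescuers kneel (hips/ankles static) and head
#: movement does not influence compression quality.
DEFAULT_EXCLUDED_JOINTS = ("Ankle", "Hip", "Head")

_SANITIZE_RE = re.compile(r"[^0-9A-Za-z]+")


class PreprocessingError(ValueError):
    pass


def sanitize_name(name: str) -> str:
    """Strip underscores and other special characters from attribute names."""
    return _SANITIZE_RE.sub("", name)


@dataclass
class MaskedSeries:
    """One compression's raw per-attribute updates within [start, end)."""

    start: float
    end: float
    frame: pd.DataFrame  # time-indexed, columns = attributes, NaN = no update

    @property
    def is_empty(self) -> bool:
        return self.frame.shape[0] == 0 or bool(self.frame.isna().all().all())


@dataclass
class FeatureTensor:
    """N x S x Q tensor plus attribute names and the min-max scaling used."""

    values: np.ndarray
    attribute_names: list[str]
    scale_min: np.ndarray
    scale_max: np.ndarray

    def __post_init__(self) -> None:
        n, s, q = self.values.shape
        if q != len(self.attribute_names):
            raise ValueError(
                f"tensor has {q} attributes but {len(self.attribute_names)} names"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def save(self, path: Union[str, Path]) -> None:
        """Write ``<path>.npy`` + ``<path>.meta.json`` (both byte-stable)."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        meta = {
            "attribute_names": self.attribute_names,
            "scale_min": self.scale_min.tolist(),
            "scale_max": self.scale_max.tolist(),
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "FeatureTensor":
        path = Path(path)
        values = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        return cls(
            values=values,
            attribute_names=list(meta["attribute_names"]),
            scale_min=np.asarray(meta["scale_min"], dtype=float),
            scale_max=np.asarray(meta["scale_max"], dtype=float),
        )


def _session_offset(value) -> float:
    if isinstance(value, datetime):
        return value.timestamp()
    return float(value)


def build_interval_table(
    annotation_recordings: Iterable[
        Union[AnnotationRecording, tuple[AnnotationRecording, object]]
    ],
) -> pd.DataFrame:
    """Stack compression intervals from one or more sessions into one table.

    Each element is either an :class:`AnnotationRecording` (session offset
    0) or a ``(recording, session_datetime_or_offset_seconds)`` pair; the
    session offset is added to the relative times (``abs_start`` /
    ``abs_end`` columns) so rows from different sessions stay distinct.
    Label and measurement attributes become target columns.
    """
    rows = []
    for item in annotation_recordings:
        if isinstance(item, tuple):
            recording, offset = item
            offset = _session_offset(offset)
        else:
            recording, offset = item, 0.0
        for i, iv in enumerate(recording.intervals):
            if not iv.end > iv.start:  # defensive; the type enforces it too
                raise PreprocessingError(
                    f"{recording.application_name} interval {i}: end <= start"
                )
            row = {
                "start": iv.start,
                "end": iv.end,
                "duration": iv.end - iv.start,
                "session_offset": offset,
                "abs_start": offset + iv.start,
                "abs_end": offset + iv.end,
            }
            row.update(iv.labels)
            row.update(iv.measurements)
            rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["start", "end", "duration", "session_offset", "abs_start", "abs_end"]
        )
    table = pd.DataFrame(rows)
    return table.sort_values(["session_offset", "start"], kind="stable").reset_index(
        drop=True
    )


def build_attribute_table(
    sensor_recordings: Iterable,
    excluded_joint_names: Sequence[str] = DEFAULT_EXCLUDED_JOINTS,
) -> pd.DataFrame:
    """Consolidate sensor streams into one sparse time-indexed table.

    Per recording: attribute names are sanitised, the recording's time
    offset is applied, duplicate timestamps are dropped keeping the first
    occurrence, columns whose running total equals zero are discarded, and
    columns naming an excluded joint are dropped.  The surviving streams
    are concatenated into a single time-ordered frame where NaN means "no
    update from this sensor at this time".
    """
    pieces = []
    for recording in sensor_recordings:
        if not recording.frames:
            continue
        index = [f.timestamp + recording.time_offset for f in recording.frames]
        df = pd.DataFrame([f.attributes for f in recording.frames], index=index)
        df.columns = [sanitize_name(c) for c in df.columns]
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise PreprocessingError(
                f"{recording.application_name}: attribute names collide after "
                f"sanitisation: {dupes}"
            )
        df = df[~df.index.duplicated(keep="first")]
        df = df.loc[:, df.sum(axis=0) != 0.0]  # uninformative: running total == 0
        if excluded_joint_names:
            keep = [
                c
                for c in df.columns
                if not any(token in c for token in excluded_joint_names)
            ]
            df = df[keep]
        if df.shape[1]:
            pieces.append(df)
    if not pieces:
        raise PreprocessingError("no attributes survive pruning; nothing to learn from")
    table = pd.concat(pieces, axis=0, join="outer").sort_index(kind="stable")
    return table


def mask_by_intervals(
    attribute_table: pd.DataFrame,
    interval_table: pd.DataFrame,
    *,
    time_columns: tuple[str, str] = ("start", "end"),
) -> list[MaskedSeries]:
    """Slice the attribute table with each half-open interval [start, end).

    Returns one :class:`MaskedSeries` per interval row, in order.  Slices
    with zero updates are returned flagged (``is_empty``); dropping versus
    filling them is the caller's decision.
    """
    index = attribute_table.index.to_numpy()
    out = []
    start_col, end_col = time_columns
    for row in interval_table.itertuples(index=False):
        start = getattr(row, start_col)
        end = getattr(row, end_col)
        lo = np.searchsorted(index, start, side="left")
        hi = np.searchsorted(index, end, side="left")  # t == end excluded
        out.append(MaskedSeries(start=start, end=end, frame=attribute_table.iloc[lo:hi]))
    return out


def resample_to_bins(masked: MaskedSeries, n_bins: int = 8) -> np.ndarray:
    """Resample one masked slice to ``n_bins`` equal-duration bins.

    Each bin's value is the mean of the raw updates falling in it (NaN
    entries, i.e. no update from that sensor, are ignored).  Empty bins are
    filled by linear interpolation between the nearest non-empty bins, with
    nearest-value extension at the edges.  An attribute with no updates at
    all in the interval is filled with zeros after a warning; if *every*
    attribute is empty a :class:`PreprocessingError` is raised.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if masked.is_empty:
        raise PreprocessingError(
            f"interval [{masked.start}, {masked.end}) contains no sensor updates"
        )
    times = masked.frame.index.to_numpy(dtype=float)
    values = masked.frame.to_numpy(dtype=float)
    span = masked.end - masked.start
    bin_idx = np.minimum(
        ((times - masked.start) / span * n_bins).astype(int), n_bins - 1
    )
    valid = ~np.isnan(values)
    sums = np.zeros((n_bins, values.shape[1]))
    counts = np.zeros((n_bins, values.shape[1]))
    np.add.at(sums, bin_idx, np.where(valid, values, 0.0))
    np.add.at(counts, bin_idx, valid.astype(float))
    with np.errstate(invalid="ignore"):
        means = sums / counts  # NaN where a bin holds no update
    empty = counts == 0
    if empty.any():
        centers = np.arange(n_bins, dtype=float)
        for q in np.nonzero(empty.any(axis=0))[0]:
            filled = ~empty[:, q]
            if not filled.any():
                warnings.warn(
                    f"attribute {masked.frame.columns[q]!r} has no updates in "
                    f"[{masked.start}, {masked.end}); filling with 0",
                    stacklevel=2,
                )
                means[:, q] = 0.0
                continue
            # np.interp extends with the nearest value beyond the edges
            means[empty[:, q], q] = np.interp(
                centers[empty[:, q]], centers[filled], means[filled, q]
            )
    return means


def assemble_tensor(
    resampled: Sequence[np.ndarray],
    attribute_names: Sequence[str],
    *,
    scale: bool = True,
) -> FeatureTensor:
    """Stack per-compression S x Q arrays into a scaled N x S x Q tensor.

    Min-max scaling to [0, 1] is fitted per attribute over the whole
    tensor; zero-range attributes scale to 0 everywhere (keeps the tensor
    finite).  The fitted (min, max) pairs are stored for reuse.
    """
    if not resampled:
        raise PreprocessingError("no resampled compressions to assemble")
    shapes = {a.shape for a in resampled}
    if len(shapes) != 1:
        raise PreprocessingError(f"inconsistent S x Q shapes across compressions: {shapes}")
    (s, q) = next(iter(shapes))
    if q != len(attribute_names):
        raise PreprocessingError(
            f"arrays have {q} attributes but {len(attribute_names)} names given"
        )
    values = np.stack(resampled).astype(float)
    lo = values.min(axis=(0, 1))
    hi = values.max(axis=(0, 1))
    if scale:
        span = hi - lo
        nonzero = span > 0
        scaled = np.zeros_like(values)
        scaled[..., nonzero] = (values[..., nonzero] - lo[nonzero]) / span[nonzero]
        values = scaled
    return FeatureTensor(
        values=values,
        attribute_names=list(attribute_names),
        scale_min=lo,
        scale_max=hi,
    )
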