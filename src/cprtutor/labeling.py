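"""Map per-compression manikin measurements to mistake classes.

Each guideline indicator has an ideal interval; a measurement is classified
as below (0), within (1) or above (2) for the ternary indicators, and as
correct (1) / incorrect (0) for the binary release indicator.  Interval
bounds are inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .mlt_io import AnnotationInterval

__all__ = [
    "GuidelineThresholds",
    "LabelingError",
    "label_rate",
    "label_depth",
    "label_release",
    "label_compressions",
]

#: label name -> measurement it is derived from
DERIVED_LABELS = {
    "classRate": "compMeanRate",
    "classDepth": "compDepth",
    "classRelease": "compRelease",
}
#: labels with no measurement rule (human-annotated, validated & passed through)
MANUAL_LABELS = ("armsLocked", "bodyWeight")


class LabelingError(ValueError):
    """Raised on invalid measurements or missing fields."""


@dataclass(frozen=True)
class GuidelineThresholds:
    """Guideline intervals for compression quality, bounds inclusive.

    Defaults: rate 100-120 compressions/min, depth 50-60 mm, and a
    residual-release threshold of 5 mm (the conventional manikin value;
    configurable).
    """

    rate_interval: tuple[float, float] = (100.0, 120.0)
    depth_interval: tuple[float, float] = (50.0, 60.0)
    release_max: float = 5.0

    def __post_init__(self) -> None:
        for name in ("rate_interval", "depth_interval"):
            low, high = getattr(self, name)
            if not low <= high:
                raise ValueError(f"{name}: low ({low}) must not exceed high ({high})")
        if not self.release_max > 0:
            raise ValueError(f"release_max must be > 0, got {self.release_max}")


def _classify_interval(value: float, interval: Sequence[float]) -> int:
    low, high = interval
    if value < low:
        return 0
    if value > high:
        return 2
    return 1


def label_rate(comp_mean_rate: float, thresholds: GuidelineThresholds | None = None) -> int:
    """Classify a mean compression rate: 0 too slow, 1 on point, 2 too fast."""
    thresholds = thresholds or GuidelineThresholds()
    if not comp_mean_rate > 0:
        raise LabelingError(f"compMeanRate must be positive, got {comp_mean_rate}")
    return _classify_interval(comp_mean_rate, thresholds.rate_interval)


def label_depth(comp_depth_mm: float, thresholds: GuidelineThresholds | None = None) -> int:
    """Classify a compression depth: 0 too shallow, 1 on point, 2 too deep."""
    thresholds = thresholds or GuidelineThresholds()
    if comp_depth_mm < 0:
        raise LabelingError(f"compDepth must be >= 0, got {comp_depth_mm}")
    return _classify_interval(comp_depth_mm, thresholds.depth_interval)


def label_release(comp_release_mm: float, thresholds: GuidelineThresholds | None = None) -> int:
    """Classify a release residual: 1 fully released (<= threshold), else 0."""
    thresholds = thresholds or GuidelineThresholds()
    if comp_release_mm < 0:
        raise LabelingError(f"compRelease must be >= 0, got {comp_release_mm}")
    return 1 if comp_release_mm <= thresholds.release_max else 0


_LABELERS = {
    "classRate": label_rate,
    "classDepth": label_depth,
    "classRelease": label_release,
}


def label_compressions(
    intervals: Iterable[AnnotationInterval],
    thresholds: GuidelineThresholds | None = None,
    targets: Sequence[str] = ("classRate", "classDepth", "classRelease"),
) -> list[AnnotationInterval]:
    """Attach class labels to compression intervals.

    For each requested target in ``targets`` the corresponding measurement
    is classified and written into the interval's labels; existing labels
    (for example manual armsLocked / bodyWeight annotations) are passed
    through untouched.  A missing measurement raises :class:`LabelingError`
    naming the interval and field.
    """
    thresholds = thresholds or GuidelineThresholds()
    unknown = [t for t in targets if t not in _LABELERS]
    if unknown:
        raise LabelingError(f"no labeling rule for target(s): {unknown}")
    out: list[AnnotationInterval] = []
    for i, interval in enumerate(intervals):
        labels = dict(interval.labels)
        for target in targets:
            measurement = DERIVED_LABELS[target]
            if measurement not in interval.measurements:
                raise LabelingError(
                    f"interval {i} [{interval.start}, {interval.end}): "
                    f"missing measurement '{measurement}' required for '{target}'"
                )
            labels[target] = _LABELERS[target](
                interval.measurements[measurement], thresholds
            )
        out.append(
            AnnotationInterval(
                start=interval.start,
                end=interval.end,
                measurements=dict(interval.measurements),
                labels=labels,
            )
        )
    return out
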