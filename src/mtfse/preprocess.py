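"""RR-interval preprocessing: artifact removal, labeling, segmentation, resampling.

The heart-rate-variability (HRV) signal is the sequence of RR intervals (time
between successive heart beats). Raw RR series from automatic beat detection
contain ectopic/spurious intervals, are irregularly sampled, and come with
per-minute apnea annotations. This module cleans them with a running-median
filter, tiles records into labeled non-overlapping 5-minute windows, and
resamples each window onto a uniform 4 Hz tachogram by cubic-spline
interpolation, the standard preparation for parametric spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "RRSeries",
    "MinuteAnnotations",
    "RawWindow",
    "HRVSegment",
    "GROUP_LABELS",
    "SEGMENT_DURATION_S",
    "remove_artifacts",
    "segment_and_label",
    "interpolate_resample",
]

#: the three cohort groups: apneic 5-min windows of apnea patients, non-apneic
#: windows of apnea patients, and non-apneic windows of controls.
GROUP_LABELS = ("A-OSA", "A-N", "C-N")

SEGMENT_DURATION_S = 300.0
MINUTE_S = 60.0


@dataclass(frozen=True)
class RRSeries:
    """Beat times (s, strictly increasing) and the RR intervals (ms) between them.

    ``rr_intervals[i]`` is the interval ending at ``beat_times[i + 1]``, so the
    series holds one fewer interval than beats.
    """

    beat_times: np.ndarray
    rr_intervals: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.rr_intervals, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "rr_intervals", rr)
        if bt.ndim != 1 or rr.ndim != 1:
            raise ValueError("beat_times and rr_intervals must be 1-D")
        if len(rr) != len(bt) - 1:
            raise ValueError(
                f"expected {len(bt) - 1} RR intervals for {len(bt)} beats, got {len(rr)}"
            )
        if np.any(np.diff(bt) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(rr <= 0) or not np.all(np.isfinite(rr)):
            raise ValueError("all RR intervals must be finite and positive")
        if not np.allclose(np.diff(bt) * 1000.0, rr, rtol=1e-9, atol=0.01):
            raise ValueError("rr_intervals inconsistent with beat_times spacing")

    @classmethod
    def from_intervals(
        cls, first_beat_time: float, rr_ms: Sequence[float], record_id: str = ""
    ) -> "RRSeries":
        """Build a series from a first beat time and the intervals that follow it."""
        rr = np.asarray(rr_ms, dtype=float)
        beat_times = first_beat_time + np.concatenate(([0.0], np.cumsum(rr) / 1000.0))
        return cls(beat_times, rr, record_id)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    def __len__(self) -> int:
        return len(self.rr_intervals)


@dataclass(frozen=True)
class MinuteAnnotations:
    """Per-minute apnea/normal labels; minute ``m`` covers ``[60 m, 60 (m+1))`` s."""

    labels: tuple

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        bad = set(labels) - {"apnea", "normal"}
        if bad:
            raise ValueError(f"annotation labels must be 'apnea'/'normal', got {bad}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RawWindow:
    """One 5-minute RR window before resampling.

    ``knot_times``/``knot_rr`` carry the RR value (ms) at the time of the beat
    that *ends* each interval — the conventional tachogram sample points.
    """

    knot_times: np.ndarray
    knot_rr: np.ndarray
    group_label: str
    start_s: float
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "knot_times", np.asarray(self.knot_times, dtype=float))
        object.__setattr__(self, "knot_rr", np.asarray(self.knot_rr, dtype=float))
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group_label!r}")


@dataclass(frozen=True)
class HRVSegment:
    """A labeled 5-min HRV segment on a uniform grid (1200 samples at 4 Hz)."""

    tachogram: np.ndarray
    start_s: float
    group_label: str
    source: str = ""
    sample_rate: float = 4.0
    duration_s: float = SEGMENT_DURATION_S

    def __post_init__(self) -> None:
        tach = np.asarray(self.tachogram, dtype=float)
        object.__setattr__(self, "tachogram", tach)
        expected = int(round(self.duration_s * self.sample_rate))
        if len(tach) != expected:
            raise ValueError(f"tachogram must have {expected} samples, got {len(tach)}")
        if not np.all(np.isfinite(tach)) or np.any(tach <= 0):
            raise ValueError("tachogram values must be finite and positive")

    @property
    def n_samples(self) -> int:
        return len(self.tachogram)

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / self.sample_rate

    def relabel(self, group_label: str, source: str | None = None) -> "HRVSegment":
        seg = replace(self, group_label=group_label)
        if source is not None:
            seg = replace(seg, source=source)
        return seg


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with the window clipped at the series edges."""
    half = window // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def remove_artifacts(
    rr: RRSeries, window: int = 5, rel_threshold: float = 0.2
) -> RRSeries:
    """Replace ectopic-like RR outliers by the local running median.

    An interval deviating from the median of its ``window``-beat neighbourhood
    by more than ``rel_threshold`` times that median is considered an artifact
    (missed/false beat or ectopic) and replaced by the median. Beat times are
    rebuilt by cumulative summation from the first beat, so downstream windows
    stay consistent. Clean series pass through unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    if len(rr) < window:
        raise ValueError(
            f"series has {len(rr)} intervals, fewer than the filter window {window}"
        )
    med = _running_median(rr.rr_intervals, window)
    outlier = np.abs(rr.rr_intervals - med) > rel_threshold * med
    cleaned = np.where(outlier, med, rr.rr_intervals)
    return RRSeries.from_intervals(rr.beat_times[0], cleaned, rr.record_id)


def segment_and_label(
    rr: RRSeries, ann: MinuteAnnotations, record_class: str
) -> list[RawWindow]:
    """Tile a record into labeled, non-overlapping, minute-aligned 5-min windows.

    Labeling follows the per-minute apnea annotations: a window of an apnea
    patient (class ``A``) containing at least one apneic minute is ``A-OSA``,
    otherwise ``A-N``; a control (class ``C``) window with no apneic minute is
    ``C-N`` and control windows containing apnea are discarded. A trailing
    partial window is discarded.
    """
    if record_class not in ("A", "C"):
        raise ValueError("record_class must be 'A' or 'C'")
    if len(ann) == 0:
        raise ValueError("empty annotation sequence")
    minutes_per_window = int(SEGMENT_DURATION_S // MINUTE_S)
    n_windows = len(ann) // minutes_per_window
    knot_times = rr.beat_times[1:]
    knot_rr = rr.rr_intervals
    windows: list[RawWindow] = []
    for w in range(n_windows):
        start = w * SEGMENT_DURATION_S
        minute_labels = ann.labels[
            w * minutes_per_window : (w + 1) * minutes_per_window
        ]
        has_apnea = "apnea" in minute_labels
        if record_class == "A":
            label = "A-OSA" if has_apnea else "A-N"
        else:
            if has_apnea:
                continue
            label = "C-N"
        mask = (knot_times >= start) & (knot_times < start + SEGMENT_DURATION_S)
        windows.append(
            RawWindow(
                knot_times=knot_times[mask],
                knot_rr=knot_rr[mask],
                group_label=label,
                start_s=start,
                source=f"{rr.record_id}@{int(start // MINUTE_S)}min",
            )
        )
    return windows


def interpolate_resample(window: RawWindow, sample_rate: float = 4.0) -> HRVSegment:
    """Cubic-spline a raw RR window onto the uniform ``sample_rate`` grid.

    The spline passes exactly through the (beat time, RR) knots; the grid
    covers ``[start, start + 300)`` s. Windows with fewer than 4 beats cannot
    support a cubic spline and are rejected.
    """
    if len(window.knot_times) < 4:
        raise ValueError(
            f"window {window.source!r} has {len(window.knot_times)} beats; "
            "at least 4 are needed for cubic-spline resampling"
        )
    spline = CubicSpline(window.knot_times, window.knot_rr)
    n_samples = int(round(SEGMENT_DURATION_S * sample_rate))
    grid = window.start_s + np.arange(n_samples) / sample_rate
    tach = spline(grid)
    if not np.all(np.isfinite(tach)) or np.any(tach <= 0):
        raise ValueError(
            f"window {window.source!r}: spline resampling produced non-positive "
            "or non-finite tachogram values"
        )
    return HRVSegment(
        tachogram=tach,
        start_s=window.start_s,
        group_label=window.group_label,
        source=window.source,
        sample_rate=sample_rate,
    )
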