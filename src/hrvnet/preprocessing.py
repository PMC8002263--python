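"""RR-interval preprocessing: beat-annotation filtering, segmentation, padding.

Input is a per-subject tachogram: an ordered sequence of RR intervals
(seconds), each carrying the beat-type annotation of its terminating beat
('N' = normal sinus beat, anything else = ectopic/abnormal).  Cleaning
removes intervals ending on a non-'N' beat and intervals longer than 2 s
(peak-detection artefacts); the survivors are concatenated in order, cut
into consecutive non-overlapping windows of N intervals, and zero-padded on
the right to the smallest multiple of 2**L so an L-level encoder can halve
the length L times without remainder (500→512, 1000→1008, 2000→2000 for
L = 4).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

MAX_RR_SECONDS = 2.0
NORMAL_CODE = "N"


class CohortLabel(str, Enum):
    NSR = "NSR"
    CHF = "CHF"
    AF = "AF"

    @property
    def binary(self) -> int:
        """1 for congestive heart failure, 0 for any non-CHF rhythm."""
        return 1 if self is CohortLabel.CHF else 0


@dataclass(frozen=True)
class BeatAnnotatedRR:
    """A subject's raw RR series with per-interval beat annotations."""

    subject_id: str
    cohort_label: CohortLabel
    intervals: tuple[float, ...]
    annotations: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        object.__setattr__(self, "intervals", tuple(float(v) for v in self.intervals))
        object.__setattr__(self, "annotations", tuple(self.annotations))
        if len(self.intervals) != len(self.annotations):
            raise ValueError(
                f"{self.subject_id}: {len(self.intervals)} intervals vs "
                f"{len(self.annotations)} annotations"
            )
        if any(v <= 0 for v in self.intervals):
            raise ValueError(f"{self.subject_id}: non-positive RR interval")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class CleanRRSeries:
    """Surviving normal-beat intervals (≤ 2 s), order preserved."""

    subject_id: str
    cohort_label: CohortLabel
    intervals: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class RRSegment:
    """One fixed-length cleaned window, optionally right-zero-padded."""

    subject_id: str
    cohort_label: CohortLabel
    values: tuple[float, ...]
    padded_values: tuple[float, ...] | None = None

    @property
    def label(self) -> int:
        return self.cohort_label.binary

    @property
    def n(self) -> int:
        return len(self.values)


def remove_abnormal_intervals(series: BeatAnnotatedRR) -> BeatAnnotatedRR:
    """Drop every interval whose terminating beat is annotated non-'N'."""
    kept = [
        (v, a)
        for v, a in zip(series.intervals, series.annotations)
        if a == NORMAL_CODE
    ]
    return replace(
        series,
        intervals=tuple(v for v, _ in kept),
        annotations=tuple(a for _, a in kept),
    )


def remove_long_intervals(series: BeatAnnotatedRR) -> BeatAnnotatedRR:
    """Drop intervals strictly longer than 2 s (boundary value 2.0 s kept)."""
    kept = [
        (v, a)
        for v, a in zip(series.intervals, series.annotations)
        if v <= MAX_RR_SECONDS
    ]
    return replace(
        series,
        intervals=tuple(v for v, _ in kept),
        annotations=tuple(a for _, a in kept),
    )


def clean(series: BeatAnnotatedRR) -> CleanRRSeries:
    """Apply both filters; survivors are simply concatenated (no gap markers)."""
    filtered = remove_long_intervals(remove_abnormal_intervals(series))
    return CleanRRSeries(series.subject_id, series.cohort_label, filtered.intervals)


def segment_series(series: CleanRRSeries, n: int) -> list[RRSegment]:
    """Cut into consecutive non-overlapping n-interval windows.

    The trailing remainder of fewer than ``n`` intervals is dropped, so the
    segment count is ``floor(len(series) / n)``.
    """
    if n <= 0:
        raise ValueError(f"segment length must be positive, got {n}")
    count = len(series) // n
    return [
        RRSegment(
            series.subject_id,
            series.cohort_label,
            tuple(series.intervals[i * n:(i + 1) * n]),
        )
        for i in range(count)
    ]


def padded_length(n: int, depth: int) -> int:
    """Smallest multiple of 2**depth that is ≥ n."""
    block = 2 ** depth
    return ((n + block - 1) // block) * block


def pad_segment(segment: RRSegment, depth: int = 4) -> RRSegment:
    """Right-pad with zeros to the smallest multiple of 2**depth ≥ n."""
    if depth < 1:
        raise ValueError(f"encoder depth must be ≥ 1, got {depth}")
    m = padded_length(segment.n, depth)
    padded = segment.values + (0.0,) * (m - segment.n)
    return replace(segment, padded_values=padded)


@dataclass
class DatasetCounts:
    """Per-cohort segment counts at each stage of the filter cascade.

    Stages: 'none' (no filtering), 'long_removed' (> 2 s intervals removed),
    'abnormal_removed' (both filters — the segments actually used).
    """

    none: Counter = field(default_factory=Counter)
    long_removed: Counter = field(default_factory=Counter)
    abnormal_removed: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict[str, dict[str, int]]:
        return {
            "none": {k.value: v for k, v in sorted(self.none.items())},
            "long_removed": {k.value: v for k, v in sorted(self.long_removed.items())},
            "abnormal_removed": {
                k.value: v for k, v in sorted(self.abnormal_removed.items())
            },
        }


def build_dataset(
    cohort: Sequence[BeatAnnotatedRR], n: int, depth: int = 4
) -> tuple[list[RRSegment], DatasetCounts]:
    """Clean, segment and pad every subject; report the filter cascade counts.

    Counts mirror the usual preprocessing table: segments obtainable with no
    filtering, after removing > 2 s intervals only, and after the full
    cascade (the returned segments).
    """
    ids = [s.subject_id for s in cohort]
    if len(set(ids)) != len(ids):
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate subject ids: {dupes}")
    counts = DatasetCounts()
    segments: list[RRSegment] = []
    for subject in cohort:
        counts.none[subject.cohort_label] += len(subject) // n
        counts.long_removed[subject.cohort_label] += (
            len(remove_long_intervals(subject)) // n
        )
        cleaned = clean(subject)
        subject_segments = [
            pad_segment(seg, depth) for seg in segment_series(cleaned, n)
        ]
        counts.abnormal_removed[subject.cohort_label] += len(subject_segments)
        segments.extend(subject_segments)
    return segments, counts


def segments_to_arrays(
    segments: Iterable[RRSegment], zscore: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Stack padded segments into (n_segments, 1, M) inputs and a label vector.

    ``zscore`` standardises each segment's non-padded part to zero mean and
    unit variance (padding zeros untouched); off by default — the network
    consumes raw seconds.
    """
    segs = list(segments)
    if not segs:
        raise ValueError("no segments")
    if any(s.padded_values is None for s in segs):
        raise ValueError("segments must be padded first (pad_segment)")
    x = np.asarray([s.padded_values for s in segs])[:, None, :]
    if zscore:
        for row, seg in zip(x, segs):
            vals = row[0, :seg.n]
            sd = vals.std()
            row[0, :seg.n] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    y = np.asarray([s.label for s in segs], dtype=np.float64)
    return x, y
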