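"""Beat-interval ingestion: reading, artifact cleaning, and segmentation.

Recordings arrive as plain-text beat files (one beat per line: beat time in
seconds and the preceding RR interval in milliseconds). The pipeline starts
from these beat intervals; QRS detection from raw ECG is out of scope.

Cleaning flags beats whose RR interval deviates from a centered 11-beat
running median by more than a fractional threshold (default 20%), a simple
rule that catches the doubled/halved intervals typical of missed or spurious
beat detections. Recordings are then tiled into contiguous, non-overlapping
half-open windows (default 30 minutes); a window is kept only if enough of
its beats survive cleaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: beats in the centered running-median window used by :func:`clean_rr`
MEDIAN_WINDOW = 11

#: default fractional deviation from the running median that flags a beat
DEFAULT_DEVIATION_THRESHOLD = 0.20

#: default analysis window length in seconds (30 minutes)
DEFAULT_WINDOW_S = 1800.0

#: default minimum fraction of beats that must survive cleaning
DEFAULT_MIN_QUALITY = 0.80

#: default minimum number of clean beats per retained segment
DEFAULT_MIN_BEATS = 1000


@dataclass
class RRSeries:
    """A timestamped beat-interval sequence for one recording session.

    Parameters
    ----------
    patient_id : str
        Identifier of the infant.
    pma_weeks : float
        Post-menstrual age at the recording, in weeks.
    beat_times : ndarray
        Beat times in seconds, strictly increasing.
    rr_ms : ndarray
        RR interval (cardiac cycle length) preceding each beat, in ms.
    """

    patient_id: str
    pma_weeks: float
    beat_times: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.beat_times.shape != self.rr_ms.shape:
            raise ValueError(
                "beat_times and rr_ms must have equal length "
                f"({self.beat_times.size} != {self.rr_ms.size})"
            )
        if self.rr_ms.size and np.any(self.rr_ms <= 0):
            raise ValueError("rr_ms values must be strictly positive")
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")

    def __len__(self) -> int:
        return self.beat_times.size

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass
class Segment:
    """One analysis window of clean beats cut from a recording.

    ``quality`` is the fraction of the window's beats that survived artifact
    cleaning; ``beat_times``/``rr_ms`` hold only the surviving beats.
    Windows are half-open ``[start_s, end_s)`` and beats are assigned by
    beat time, so no beat belongs to two segments.
    """

    patient_id: str
    pma_weeks: float
    start_s: float
    end_s: float
    beat_times: np.ndarray = field(repr=False)
    rr_ms: np.ndarray = field(repr=False)
    quality: float
    n_total: int
    n_flagged: int

    def __len__(self) -> int:
        return self.beat_times.size


def read_rr(
    path: str | Path,
    patient_id: str | None = None,
    pma_weeks: float = float("nan"),
) -> RRSeries:
    """Read a two-column beat file (time_s, rr_ms) into an :class:`RRSeries`.

    Lines starting with ``#`` and blank lines are ignored. Raises
    ``ValueError`` naming the offending line on malformed rows,
    non-monotone beat times, or an empty file.
    """
    path = Path(path)
    times: list[float] = []
    rrs: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                t, rr = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
            if times and t <= times[-1]:
                raise ValueError(
                    f"{path}:{lineno}: beat time {t} not after previous {times[-1]}"
                )
            if rr <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive RR {rr}")
            times.append(t)
            rrs.append(rr)
    if not times:
        raise ValueError(f"{path}: no beats found")
    return RRSeries(
        patient_id=patient_id if patient_id is not None else path.stem,
        pma_weeks=pma_weeks,
        beat_times=np.array(times),
        rr_ms=np.array(rrs),
    )


def running_median_flags(
    rr_ms: np.ndarray, deviation_threshold: float = DEFAULT_DEVIATION_THRESHOLD
) -> np.ndarray:
    """Boolean mask of beats deviating from the centered 11-beat running median.

    Edge beats use shrinking (partial) windows. Series shorter than the
    median window are never flagged.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < MEDIAN_WINDOW:
        return np.zeros(rr.size, dtype=bool)
    med = (
        pd.Series(rr)
        .rolling(MEDIAN_WINDOW, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return np.abs(rr - med) > deviation_threshold * med


def clean_rr(
    series: RRSeries,
    deviation_threshold: float = DEFAULT_DEVIATION_THRESHOLD,
) -> tuple[RRSeries, np.ndarray]:
    """Remove artifact beats from a series.

    Returns the cleaned series together with the boolean flag mask over the
    *original* beats (``True`` = excluded). A series shorter than the
    running-median window is returned unchanged with a warning.
    """
    if len(series) < MEDIAN_WINDOW:
        warnings.warn(
            f"series of length {len(series)} shorter than the {MEDIAN_WINDOW}-beat "
            "median window; returned unchanged",
            stacklevel=2,
        )
        return series, np.zeros(len(series), dtype=bool)
    flags = running_median_flags(series.rr_ms, deviation_threshold)
    cleaned = RRSeries(
        patient_id=series.patient_id,
        pma_weeks=series.pma_weeks,
        beat_times=series.beat_times[~flags],
        rr_ms=series.rr_ms[~flags],
    )
    return cleaned, flags


def segment_series(
    series: RRSeries,
    window_s: float = DEFAULT_WINDOW_S,
    min_quality: float = DEFAULT_MIN_QUALITY,
    min_beats: int = DEFAULT_MIN_BEATS,
    deviation_threshold: float = DEFAULT_DEVIATION_THRESHOLD,
) -> list[Segment]:
    """Tile a recording into contiguous half-open windows of clean beats.

    Windows start at the first beat time; only complete windows (end within
    the recording) are formed. A window is retained when its clean-beat
    fraction is at least ``min_quality`` and it holds at least ``min_beats``
    clean beats. An empty list is a valid result.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if len(series) == 0:
        return []
    flags = running_median_flags(series.rr_ms, deviation_threshold)
    t0 = series.beat_times[0]
    t_last = series.beat_times[-1]
    n_windows = int(np.floor((t_last - t0) / window_s))
    segments: list[Segment] = []
    for k in range(n_windows):
        start, end = t0 + k * window_s, t0 + (k + 1) * window_s
        in_win = (series.beat_times >= start) & (series.beat_times < end)
        n_total = int(in_win.sum())
        if n_total == 0:
            continue
        keep = in_win & ~flags
        n_flagged = n_total - int(keep.sum())
        quality = 1.0 - n_flagged / n_total
        if quality < min_quality or int(keep.sum()) < min_beats:
            continue
        segments.append(
            Segment(
                patient_id=series.patient_id,
                pma_weeks=series.pma_weeks,
                start_s=float(start),
                end_s=float(end),
                beat_times=series.beat_times[keep],
                rr_ms=series.rr_ms[keep],
                quality=float(quality),
                n_total=n_total,
                n_flagged=n_flagged,
            )
        )
    return segments
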