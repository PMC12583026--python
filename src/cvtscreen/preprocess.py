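"""Beat-series preprocessing: missing-data estimation, rolling CVT,
edge exclusion, artifact excision, quality filtering, and the retention
rule, plus raw-data descriptives and best-recording selection.

Pipeline stage order is roll -> trim -> artifact excision -> quality
filter -> retention check.  Artifacts are detected on the raw
instantaneous-HR stream (they are raw-beat phenomena) and mapped onto
the surviving positions of the rolled-and-trimmed CVT series before
excision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import NightRecording

__all__ = [
    "ProcessingConfig",
    "ProcessedRecording",
    "RawQualityReport",
    "instantaneous_hr",
    "estimate_missing_fraction",
    "rolling_cvt",
    "trim_edges",
    "detect_artifacts",
    "excise_artifacts",
    "quality_filter",
    "process_recording",
    "summarize_raw",
    "select_best_recording",
]


@dataclass(frozen=True)
class ProcessingConfig:
    """Filtering thresholds.  Defaults are the clinical-standard constants."""

    roll_window: int = 10  # rolling-average width, beats
    edge_trim: int = 10  # points dropped at each end of the rolled series
    artifact_jump: float = 15.0  # bpm; strict > triggers the artifact rule
    excision_flank: int = 7  # points removed on each side of an artifact
    quality_min: int = 10  # beats with quality below this are removed
    retention_min: float = 0.70  # recordings below this fraction are excluded

    def __post_init__(self) -> None:
        if self.roll_window < 1 or self.edge_trim < 0 or self.excision_flank < 0:
            raise ValueError("window sizes must be positive")
        if self.artifact_jump <= 0:
            raise ValueError("artifact_jump must be positive")
        if not (0 < self.retention_min <= 1):
            raise ValueError("retention_min must be in (0, 1]")


@dataclass
class ProcessedRecording:
    """Output of the full preprocessing pipeline for one recording."""

    subject_id: str
    recording_index: int
    t: np.ndarray  # times of surviving CVT points
    cvt: np.ndarray  # surviving CVT values (LVS)
    n_raw: int  # raw beat count
    n_original: int  # rolled-and-trimmed length (retention denominator)
    n_retained: int
    retention: float
    missing_fraction: float
    accepted: bool
    removal_log: dict[str, int] = field(default_factory=dict)
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if self.n_retained > self.n_raw:
            raise ValueError("retained count exceeds raw count")
        if not (0.0 <= self.retention <= 1.0):
            raise ValueError("retention outside [0, 1]")


@dataclass
class RawQualityReport:
    """Raw-recording descriptives: n, length, points, missing %, high-quality %."""

    n_recordings: int
    length_s_mean: float
    length_s_sd: float
    points_mean: float
    points_sd: float
    missing_pct_mean: float
    missing_pct_sd: float
    high_quality_pct_mean: float
    high_quality_pct_sd: float
    quality_threshold: int = 13

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def instantaneous_hr(rr_ms: np.ndarray) -> np.ndarray:
    """Per-beat heart rate in bpm from RR intervals in milliseconds."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    if np.any(rr_ms <= 0):
        raise ValueError("rr intervals must be > 0")
    return 60000.0 / rr_ms


def estimate_missing_fraction(rec: NightRecording) -> float:
    """Fraction of the session without data, from the average heart rate.

    At mean HR >= 60 bpm the device is expected to see at least one beat
    per second, so the expected count is the session duration in seconds;
    below 60 bpm the expectation is scaled by meanHR/60.
    """
    if rec.n_beats < 2:
        raise ValueError("insufficient beats to estimate missing fraction (need >= 2)")
    duration = rec.session_end - rec.session_start
    mean_hr = float(np.mean(instantaneous_hr(rec.rr)))
    expected = duration if mean_hr >= 60.0 else duration * mean_hr / 60.0
    if expected <= 0:
        raise ValueError("non-positive expected beat count")
    return max(0.0, 1.0 - rec.n_beats / expected)


def rolling_cvt(raw: np.ndarray, window: int = 10) -> np.ndarray:
    """Rolling average of ``window`` points (current beat included).

    Emitted only where a full window exists, so the output has length
    ``n - window + 1``; shorter inputs yield an empty array.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(raw, kernel, mode="valid")


def trim_edges(series: np.ndarray, n_trim: int = 10) -> np.ndarray:
    """Drop exactly the first and last ``n_trim`` points (edge artifacts)."""
    series = np.asarray(series)
    if len(series) <= 2 * n_trim:
        return series[:0]
    return series[n_trim : len(series) - n_trim]


def detect_artifacts(hr: np.ndarray, jump: float = 15.0) -> np.ndarray:
    """Indices i (i >= 1) where hr[i] - hr[i-1] strictly exceeds ``jump`` bpm.

    Decreases are never flagged; compensatory pauses are handled by the
    excision window around each flagged beat.
    """
    hr = np.asarray(hr, dtype=float)
    if len(hr) < 2:
        return np.empty(0, dtype=int)
    return np.flatnonzero(np.diff(hr) > jump) + 1


def excise_artifacts(series: np.ndarray, artifact_indices, flank: int = 7) -> np.ndarray:
    """Remove each artifact with ``flank`` points on both sides.

    Overlapping windows are unioned; windows are truncated at the series
    bounds; surviving order is preserved.
    """
    series = np.asarray(series)
    keep = excision_mask(len(series), artifact_indices, flank)
    return series[keep]


def excision_mask(n: int, artifact_indices, flank: int = 7) -> np.ndarray:
    """Boolean keep-mask implementing the +/-flank excision windows."""
    keep = np.ones(n, dtype=bool)
    for i in np.asarray(artifact_indices, dtype=int):
        if i < -flank or i >= n + flank:
            continue
        keep[max(0, i - flank) : min(n, i + flank + 1)] = False
    return keep


def quality_filter(values: np.ndarray, quality: np.ndarray, threshold: int = 10) -> np.ndarray:
    """Keep exactly the values whose quality score is >= ``threshold``."""
    values = np.asarray(values)
    quality = np.asarray(quality)
    if len(values) != len(quality):
        raise ValueError("values and quality must be the same length")
    return values[quality >= threshold]


def process_recording(
    rec: NightRecording, config: ProcessingConfig | None = None
) -> ProcessedRecording:
    """Run the full preprocessing pipeline on one recording.

    Returns a :class:`ProcessedRecording`; recordings too short to roll
    and trim are rejected (``accepted=False``) with a reason rather than
    raising.  The removal log satisfies
    ``n_raw - sum(removal_log.values()) == n_retained``.
    """
    cfg = config or ProcessingConfig()
    w, e = cfg.roll_window, cfg.edge_trim
    n_raw = rec.n_beats
    offset = (w - 1) + e  # trimmed index k <-> raw beat index k + offset

    def rejected(reason: str, log: dict[str, int]) -> ProcessedRecording:
        log = dict(log)
        removed = sum(log.values())
        log["short"] = n_raw - removed  # account for untreatable remainder
        try:
            missing = estimate_missing_fraction(rec)
        except ValueError:
            missing = float("nan")
        return ProcessedRecording(
            subject_id=rec.subject_id,
            recording_index=rec.recording_index,
            t=np.empty(0),
            cvt=np.empty(0),
            n_raw=n_raw,
            n_original=0,
            n_retained=0,
            retention=0.0,
            missing_fraction=missing,
            accepted=False,
            removal_log=log,
            reject_reason=reason,
        )

    if n_raw < w:
        return rejected(f"too short to roll (needs >= {w} beats, got {n_raw})", {})
    rolled = rolling_cvt(rec.raw_lvs, w)
    log = {"rolling": n_raw - len(rolled)}

    trimmed = trim_edges(rolled, e)
    if len(trimmed) == 0:
        return rejected(
            f"too short after edge trim (needs > {2 * e} rolled points)", log
        )
    log["edge_trim"] = len(rolled) - len(trimmed)
    n_original = len(trimmed)
    trimmed_t = rec.t[offset : offset + n_original]
    trimmed_quality = rec.quality[offset : offset + n_original]

    # artifact rule on the raw HR stream, mapped onto trimmed positions
    hr = instantaneous_hr(rec.rr)
    raw_artifacts = detect_artifacts(hr, cfg.artifact_jump)
    mapped = raw_artifacts - offset
    keep = excision_mask(n_original, mapped, cfg.excision_flank)
    log["artifact"] = int(n_original - keep.sum())

    surv_cvt = trimmed[keep]
    surv_t = trimmed_t[keep]
    surv_quality = trimmed_quality[keep]

    qmask = surv_quality >= cfg.quality_min
    log["quality"] = int(len(surv_cvt) - qmask.sum())
    final_cvt = surv_cvt[qmask]
    final_t = surv_t[qmask]

    n_retained = len(final_cvt)
    retention = n_retained / n_original
    try:
        missing = estimate_missing_fraction(rec)
    except ValueError:
        missing = float("nan")
    return ProcessedRecording(
        subject_id=rec.subject_id,
        recording_index=rec.recording_index,
        t=final_t,
        cvt=final_cvt,
        n_raw=n_raw,
        n_original=n_original,
        n_retained=n_retained,
        retention=retention,
        missing_fraction=missing,
        accepted=retention >= cfg.retention_min,
        removal_log=log,
    )


def summarize_raw(
    recordings: list[NightRecording], high_quality_threshold: int = 13
) -> RawQualityReport:
    """Descriptives of raw recordings before any filtering."""
    if not recordings:
        raise ValueError("no recordings to summarize")

    def mean_sd(x: list[float]) -> tuple[float, float]:
        arr = np.asarray(x, dtype=float)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        return float(np.mean(arr)), sd

    lengths = [r.session_end - r.session_start for r in recordings]
    points = [float(r.n_beats) for r in recordings]
    missing = [100.0 * estimate_missing_fraction(r) for r in recordings]
    highq = [
        100.0 * float(np.mean(r.quality >= high_quality_threshold)) if r.n_beats else 0.0
        for r in recordings
    ]
    l_m, l_s = mean_sd(lengths)
    p_m, p_s = mean_sd(points)
    m_m, m_s = mean_sd(missing)
    q_m, q_s = mean_sd(highq)
    return RawQualityReport(
        n_recordings=len(recordings),
        length_s_mean=l_m,
        length_s_sd=l_s,
        points_mean=p_m,
        points_sd=p_s,
        missing_pct_mean=m_m,
        missing_pct_sd=m_s,
        high_quality_pct_mean=q_m,
        high_quality_pct_sd=q_s,
        quality_threshold=high_quality_threshold,
    )


def select_best_recording(processed: list[ProcessedRecording]) -> ProcessedRecording:
    """Deterministic proxy for representative-recording selection.

    Highest retention wins; ties go to the longer retained series, then
    to the lowest recording index.
    """
    accepted = [p for p in processed if p.accepted]
    if not accepted:
        raise ValueError("no usable recording: none passed the retention rule")
    return min(accepted, key=lambda p: (-p.retention, -p.n_retained, p.recording_index))
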