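"""Reading and writing beat-level recordings and cohort metadata.

The beat-series dialect is a plain UTF-8 CSV with LF line endings: a
``#key=value`` comment preamble carrying session metadata, followed by a
header line ``t_s,rr_ms,raw_lvs,quality`` and one row per heartbeat.
Times are seconds from session start (0-based), never wall clock, so
files stay anonymizable.  Declared precision: ``t_s`` milliseconds (3
decimals), ``rr_ms`` 0.1 ms (1 decimal), ``raw_lvs`` 3 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

BEAT_COLUMNS = ("t_s", "rr_ms", "raw_lvs", "quality")

METADATA_COLUMNS = (
    "subject_id",
    "group",
    "can_stage",
    "cart_postural",
    "cart_breathing",
    "cart_valsalva",
)

QUALITY_MAX = 15


class RecordingValidationError(ValueError):
    """Raised when a recording violates the dialect or a type invariant.

    ``line`` is the 1-based line number in the source file when the error
    was detected while parsing, otherwise ``None``.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class BeatRecord:
    """One heartbeat: time, RR interval, raw vagal tone, signal quality."""

    t: float  # seconds from session start
    rr: float  # milliseconds
    raw_lvs: float  # linear vagal scale units
    quality: int  # 0-15, higher is better

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise RecordingValidationError(f"rr must be > 0, got {self.rr}")
        if not (0 <= self.quality <= QUALITY_MAX):
            raise RecordingValidationError(
                f"quality must be in [0, {QUALITY_MAX}], got {self.quality}"
            )
        if self.raw_lvs < 0:
            raise RecordingValidationError(f"raw_lvs must be >= 0, got {self.raw_lvs}")


@dataclass
class NightRecording:
    """Ordered beat series for one subject-session plus metadata.

    Beat columns are stored as parallel numpy arrays for speed; the
    ``beats`` property yields :class:`BeatRecord` views.
    """

    subject_id: str
    recording_index: int
    session_start: float
    session_end: float
    t: np.ndarray = field(default_factory=lambda: np.empty(0))
    rr: np.ndarray = field(default_factory=lambda: np.empty(0))
    raw_lvs: np.ndarray = field(default_factory=lambda: np.empty(0))
    quality: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    device_id: str = "sim"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.raw_lvs = np.asarray(self.raw_lvs, dtype=float)
        self.quality = np.asarray(self.quality, dtype=int)
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        if not (len(self.rr) == len(self.raw_lvs) == len(self.quality) == n):
            raise RecordingValidationError("beat columns have unequal lengths")
        if self.session_end < self.session_start:
            raise RecordingValidationError("session_end precedes session_start")
        if n == 0:
            return
        if np.any(np.diff(self.t) <= 0):
            i = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise RecordingValidationError(f"timestamps not strictly increasing at beat {i}")
        if self.t[0] < self.session_start or self.t[-1] > self.session_end:
            raise RecordingValidationError("beat times outside declared session bounds")
        if np.any(self.rr <= 0):
            raise RecordingValidationError("rr values must be > 0")
        if np.any(self.raw_lvs < 0):
            raise RecordingValidationError("raw_lvs values must be >= 0")
        if np.any((self.quality < 0) | (self.quality > QUALITY_MAX)):
            raise RecordingValidationError(f"quality values outside [0, {QUALITY_MAX}]")

    @property
    def n_beats(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Declared session duration in seconds."""
        return self.session_end - self.session_start

    @property
    def beats(self) -> Iterator[BeatRecord]:
        for t, rr, lvs, q in zip(self.t, self.rr, self.raw_lvs, self.quality):
            yield BeatRecord(float(t), float(rr), float(lvs), int(q))

    def equals(self, other: "NightRecording") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.recording_index == other.recording_index
            and self.device_id == other.device_id
            and math.isclose(self.session_start, other.session_start, abs_tol=5e-4)
            and math.isclose(self.session_end, other.session_end, abs_tol=5e-4)
            and self.n_beats == other.n_beats
            and np.allclose(self.t, other.t, atol=5e-4)
            and np.allclose(self.rr, other.rr, atol=5e-2)
            and np.allclose(self.raw_lvs, other.raw_lvs, atol=5e-4)
            and np.array_equal(self.quality, other.quality)
        )


def write_recording(rec: NightRecording, path: str | Path) -> None:
    """Write a recording in the beat-series dialect (deterministic bytes)."""
    path = Path(path)
    lines = [
        f"#subject_id={rec.subject_id}",
        f"#recording_index={rec.recording_index}",
        f"#session_start={rec.session_start:.3f}",
        f"#session_end={rec.session_end:.3f}",
        f"#device_id={rec.device_id}",
        ",".join(BEAT_COLUMNS),
    ]
    for t, rr, lvs, q in zip(rec.t, rec.rr, rec.raw_lvs, rec.quality):
        lines.append(f"{t:.3f},{rr:.1f},{lvs:.3f},{q:d}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_recording(path: str | Path) -> NightRecording:
    """Parse a beat-series file, reporting malformed rows by line number."""
    path = Path(path)
    meta: dict[str, str] = {}
    t, rr, lvs, quality = [], [], [], []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if header_seen:
                    raise RecordingValidationError("comment after header", lineno)
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if tuple(line.split(",")) != BEAT_COLUMNS:
                    raise RecordingValidationError(
                        f"expected header {','.join(BEAT_COLUMNS)!r}, got {line!r}", lineno
                    )
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != len(BEAT_COLUMNS):
                raise RecordingValidationError(
                    f"expected {len(BEAT_COLUMNS)} fields, got {len(fields)}", lineno
                )
            try:
                ti, rri, li = float(fields[0]), float(fields[1]), float(fields[2])
                qi = int(fields[3])
            except ValueError as exc:
                raise RecordingValidationError(f"unparsable value ({exc})", lineno) from exc
            if rri <= 0:
                raise RecordingValidationError(f"rr must be > 0, got {rri}", lineno)
            if not (0 <= qi <= QUALITY_MAX):
                raise RecordingValidationError(
                    f"quality must be in [0, {QUALITY_MAX}], got {qi}", lineno
                )
            if li < 0:
                raise RecordingValidationError(f"raw_lvs must be >= 0, got {li}", lineno)
            if t and ti <= t[-1]:
                raise RecordingValidationError(
                    f"time {ti} not greater than previous {t[-1]}", lineno
                )
            t.append(ti)
            rr.append(rri)
            lvs.append(li)
            quality.append(qi)
    if not header_seen:
        raise RecordingValidationError(f"no header line found in {path}")
    for key in ("subject_id", "session_start", "session_end"):
        if key not in meta:
            raise RecordingValidationError(f"missing metadata key {key!r} in preamble")
    return NightRecording(
        subject_id=meta["subject_id"],
        recording_index=int(meta.get("recording_index", 0)),
        session_start=float(meta["session_start"]),
        session_end=float(meta["session_end"]),
        t=np.array(t),
        rr=np.array(rr),
        raw_lvs=np.array(lvs),
        quality=np.array(quality, dtype=int),
        device_id=meta.get("device_id", "unknown"),
    )


def write_metadata(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort metadata table (one row per subject)."""
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    cols = list(METADATA_COLUMNS) + [c for c in table.columns if c not in METADATA_COLUMNS]
    table[cols].to_csv(path, index=False, lineterminator="\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    return table


def write_cvt_series(t: Sequence[float], cvt: Sequence[float], path: str | Path) -> None:
    """Write a processed CVT series as ``t_s,cvt_lvs``."""
    lines = ["t_s,cvt_lvs"]
    lines += [f"{ti:.3f},{vi:.3f}" for ti, vi in zip(t, cvt)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
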