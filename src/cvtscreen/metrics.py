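"""Per-recording CVT summaries: mean, SD and vagal 'capacity'."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CAPACITY_MIN_POINTS = 20
_N_EXTREMES = 10  # per tail


@dataclass(frozen=True)
class CVTSummary:
    mean_cvt: float
    sd_cvt: float
    capacity: float | None  # None when the series is too short (< 20 points)
    n_points: int
    source: str  # "short_term" | "long_term"

    def __post_init__(self) -> None:
        if self.sd_cvt < 0:
            raise ValueError("sd_cvt must be >= 0")
        if self.capacity is not None and self.capacity < -1e-12:
            raise ValueError("capacity must be >= 0")


def cvt_capacity(cvt: np.ndarray) -> float:
    """Average absolute deviation from the series mean of the 20 most
    extreme values: the 10 largest and the 10 smallest.

    Ties at the tail boundaries are broken by earliest time index (stable
    sort), and the two tails are disjoint index sets.
    """
    cvt = np.asarray(cvt, dtype=float)
    n = len(cvt)
    if n < CAPACITY_MIN_POINTS:
        raise ValueError(f"capacity undefined: needs >= {CAPACITY_MIN_POINTS} points, got {n}")
    order = np.argsort(cvt, kind="stable")
    lowest = order[:_N_EXTREMES]
    highest = order[n - _N_EXTREMES :]
    m = float(np.mean(cvt))
    extremes = cvt[np.concatenate([lowest, highest])]
    return float(np.mean(np.abs(extremes - m)))


def summarize(cvt: np.ndarray, source: str) -> CVTSummary:
    """Arithmetic mean, sample SD (n-1) and capacity for one CVT series."""
    cvt = np.asarray(cvt, dtype=float)
    if len(cvt) == 0:
        raise ValueError("empty CVT series")
    if source not in ("short_term", "long_term"):
        raise ValueError(f"unknown source {source!r}")
    mean = float(np.mean(cvt))
    sd = float(np.std(cvt, ddof=1)) if len(cvt) > 1 else 0.0
    capacity = cvt_capacity(cvt) if len(cvt) >= CAPACITY_MIN_POINTS else None
    return CVTSummary(mean_cvt=mean, sd_cvt=sd, capacity=capacity, n_points=len(cvt), source=source)
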