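"""Synthetic cohorts of overnight vagal-tone recordings.

Subjects carry a latent vagal-tone level drawn from group x stage means;
nights add a night-level offset, a square-wave sleep architecture
(non-REM baseline, REM dips, optional brief wake bouts), per-beat noise,
RR intervals coupled inversely to vagal tone, injected HR-spike
artifacts, contiguous dropout gaps, and device-like quality scores.
Ground-truth labels for every corruption are returned alongside so the
preprocessing stages can be tested against known answers.

Default level parameters are calibrated to published group medians but
are configuration, not fact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import NightRecording, write_metadata, write_recording
from .screening import stage_can

GROUPS = ("control", "t2d")
STAGES = ("none", "early", "manifest")


def _default_stage_probs() -> dict[str, dict[str, float]]:
    return {
        "control": {"none": 0.80, "early": 0.15, "manifest": 0.05},
        "t2d": {"none": 0.475, "early": 0.25, "manifest": 0.275},
    }


def _default_group_means() -> dict[str, dict[str, float]]:
    return {
        "control": {"none": 8.0, "early": 6.0, "manifest": 4.5},
        "t2d": {"none": 7.0, "early": 5.5, "manifest": 4.0},
    }


@dataclass
class SimulationConfig:
    n_control: int = 20
    n_t2d: int = 40
    stage_probs: dict = field(default_factory=_default_stage_probs)
    group_mean_cvt: dict = field(default_factory=_default_group_means)
    between_sd: float = 2.0  # subject-level SD of the latent level (LVS)
    within_night_sd: float = 0.6  # night-level offset SD (LVS)
    beat_noise_sd: float = 1.0  # per-beat noise SD (LVS)
    sleep_cycle_minutes: float = 90.0
    rem_fraction: float = 0.25  # tail share of each cycle spent in REM
    rem_cvt_reduction: float = 2.0  # LVS dip during REM, floored at 0
    wake_cvt_elevation: float = 3.0  # LVS rise during wake bouts
    wake_bout_minutes: float = 2.0
    wake_bout_prob: float = 0.5  # chance of a wake bout at each cycle start
    base_hr: float = 60.0  # bpm at the reference vagal-tone level
    hr_cvt_slope: float = 1.0  # bpm decrease per LVS above reference
    hr_cvt_ref: float = 7.0
    artifact_rate: float = 0.002  # per-beat probability of an HR spike
    dropout_rate: float = 0.208  # expected fraction of session in gaps
    quality_high_frac: float = 0.937  # fraction of beats scoring >= 13
    session_length_minutes: float = 434.0
    nights_per_subject: int = 3
    night_missing_prob: float = 0.05  # chance a scheduled night never records
    short_term_minutes: float = 5.0
    short_term_offset: float = -3.0  # awake level relative to sleep baseline
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "between_sd", "within_night_sd", "beat_noise_sd", "rem_cvt_reduction",
            "wake_cvt_elevation", "artifact_rate", "dropout_rate",
            "quality_high_frac", "night_missing_prob",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("artifact_rate", "dropout_rate", "quality_high_frac",
                     "rem_fraction", "night_missing_prob", "wake_bout_prob"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_control < 0 or self.n_t2d < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.base_hr <= 0 or self.sleep_cycle_minutes <= 0:
            raise ValueError("base_hr and sleep_cycle_minutes must be positive")
        for group in GROUPS:
            probs = self.stage_probs[group]
            if any(probs[s] < 0 for s in STAGES):
                raise ValueError("stage probabilities must be >= 0")
            if abs(sum(probs[s] for s in STAGES) - 1.0) > 1e-9:
                raise ValueError(f"stage_probs for {group!r} must sum to 1")
            if any(self.group_mean_cvt[group][s] < 0 for s in STAGES):
                raise ValueError("group_mean_cvt values must be >= 0 (absolute zero scale)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str
    can_stage: str
    cart_abnormal: tuple[bool, bool, bool]  # postural, deep breathing, Valsalva
    subject_intercept: float  # latent sleep-baseline vagal tone (LVS)
    assigned_mean_cvt: float  # group x stage mean the intercept was drawn from

    def __post_init__(self) -> None:
        if stage_can(self.cart_abnormal) != self.can_stage:
            raise ValueError("can_stage inconsistent with abnormal test count")


@dataclass
class NightGroundTruth:
    """Corruption labels for one simulated night, for test oracles."""

    artifact_indices: list[int]  # indices into the delivered beat arrays
    artifact_times: list[float]
    n_artifacts_injected: int  # includes any later lost to dropout
    dropout_spans: list[tuple[float, float]]
    stage_track: list[tuple[float, float, str]]  # (start_s, end_s, stage)
    night_level: float  # subject + night baseline (LVS)

    def to_dict(self) -> dict:
        return {
            "artifact_indices": self.artifact_indices,
            "artifact_times": self.artifact_times,
            "n_artifacts_injected": self.n_artifacts_injected,
            "dropout_spans": self.dropout_spans,
            "stage_track": self.stage_track,
            "night_level": self.night_level,
        }


def generate_subject(
    config: SimulationConfig, group: str, rng: np.random.Generator, subject_id: str = "S000"
) -> SubjectProfile:
    """Draw one subject: stage, reflex-test pattern and latent level."""
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")
    probs = [config.stage_probs[group][s] for s in STAGES]
    stage = STAGES[int(rng.choice(len(STAGES), p=probs))]
    mean = config.group_mean_cvt[group][stage]
    intercept = max(0.0, float(rng.normal(mean, config.between_sd)))
    if stage == "none":
        n_abnormal = 0
    elif stage == "early":
        n_abnormal = 1
    else:
        n_abnormal = int(rng.choice([2, 3]))
    which = rng.choice(3, size=n_abnormal, replace=False)
    cart = tuple(i in which for i in range(3))
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        can_stage=stage,
        cart_abnormal=cart,
        subject_intercept=intercept,
        assigned_mean_cvt=mean,
    )


def _stage_track(
    duration_s: float, config: SimulationConfig, wake_flags: np.ndarray
) -> list[tuple[float, float, str]]:
    """Deterministic alternating sleep-architecture template."""
    cycle = config.sleep_cycle_minutes * 60.0
    wake_len = config.wake_bout_minutes * 60.0
    rem_start_frac = 1.0 - config.rem_fraction
    track: list[tuple[float, float, str]] = []
    start = 0.0
    c = 0
    while start < duration_s:
        end = min(start + cycle, duration_s)
        rem_at = start + rem_start_frac * cycle
        cursor = start
        if c < len(wake_flags) and wake_flags[c] and wake_len > 0:
            w_end = min(start + wake_len, end)
            track.append((cursor, w_end, "wake"))
            cursor = w_end
        if rem_at > cursor:
            track.append((cursor, min(rem_at, end), "nonrem"))
            cursor = min(rem_at, end)
        if end > cursor:
            track.append((cursor, end, "rem"))
        start = end
        c += 1
    return track


def _levels_at(times: np.ndarray, track, level: float, config: SimulationConfig) -> np.ndarray:
    starts = np.array([s for s, _, _ in track])
    stage_level = {
        "nonrem": level,
        "rem": max(0.0, level - config.rem_cvt_reduction),
        "wake": level + config.wake_cvt_elevation,
    }
    seg_levels = np.array([stage_level[name] for _, _, name in track])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(track) - 1)
    return seg_levels[idx]


def _draw_quality(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Mostly high scores (13-15) with low-quality bursts covering
    roughly 1 - quality_high_frac of beats."""
    quality = rng.integers(13, 16, size=n)
    n_low = int(round((1.0 - config.quality_high_frac) * n))
    assigned = 0
    guard = 0
    while assigned < n_low and guard < 10 * n_low + 100:
        guard += 1
        start = int(rng.integers(0, n))
        length = min(int(rng.geometric(1.0 / 15.0)), n_low - assigned, n - start)
        if length <= 0:
            continue
        seg = slice(start, start + length)
        fresh = np.sum(quality[seg] >= 13)
        quality[seg] = rng.integers(0, 13, size=length)
        assigned += int(fresh)
    return quality


def _dropout_spans(
    duration_s: float, rate: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    if rate <= 0:
        return []
    total = rate * duration_s
    k = int(rng.integers(1, 4))
    shares = rng.dirichlet(np.ones(k))
    durations = shares * total
    free = duration_s - total
    cuts = np.sort(rng.uniform(0, free, size=k))
    spans = []
    consumed = 0.0
    for cut, d in zip(cuts, durations):
        start = cut + consumed
        spans.append((float(start), float(start + d)))
        consumed += d
    return spans


def generate_night(
    subject: SubjectProfile,
    config: SimulationConfig,
    night_index: int,
    rng: np.random.Generator,
) -> tuple[NightRecording, NightGroundTruth]:
    """Simulate one overnight recording plus ground-truth labels."""
    if night_index < 1:
        raise ValueError("night_index must be >= 1")
    if config.session_length_minutes < config.sleep_cycle_minutes:
        raise ValueError(
            "session shorter than one sleep cycle "
            f"({config.session_length_minutes} < {config.sleep_cycle_minutes} min)"
        )
    duration = config.session_length_minutes * 60.0
    level = max(0.0, subject.subject_intercept + rng.normal(0.0, config.within_night_sd))

    n_cycles = int(np.ceil(config.session_length_minutes / config.sleep_cycle_minutes)) + 1
    wake_flags = (
        rng.random(n_cycles) < config.wake_bout_prob
        if config.wake_bout_prob > 0 and config.wake_cvt_elevation > 0
        else np.zeros(n_cycles, dtype=bool)
    )
    track = _stage_track(duration, config, wake_flags)

    hr_max = config.base_hr + config.hr_cvt_slope * config.hr_cvt_ref + 1.0
    n_max = int(np.ceil(duration * hr_max / 60.0)) + 16
    # provisional evenly spaced times locate each beat's sleep stage;
    # final times come from the cumulative RR series
    t_prov = np.arange(n_max) * (60.0 / config.base_hr)
    lvl = _levels_at(t_prov, track, level, config)
    cvt = np.maximum(0.0, lvl + rng.normal(0.0, config.beat_noise_sd, size=n_max))
    hr = config.base_hr - config.hr_cvt_slope * (cvt - config.hr_cvt_ref)
    hr = np.clip(hr, 30.0, 180.0)
    rr = 60000.0 / hr

    artifact_mask = rng.random(n_max) < config.artifact_rate
    artifact_mask[0] = False
    artifact_idx = np.flatnonzero(artifact_mask)
    for i in artifact_idx:  # sequential so consecutive artifacts chain correctly
        hr_prev = 60000.0 / rr[i - 1]
        rr[i] = 60000.0 / (hr_prev + rng.uniform(16.0, 30.0))

    t = np.cumsum(rr) / 1000.0
    keep = t <= duration
    t, rr, cvt = t[keep], rr[keep], cvt[keep]
    artifact_flags = artifact_mask[keep]
    n_injected = int(artifact_flags.sum())

    spans = _dropout_spans(duration, config.dropout_rate, rng)
    if spans:
        in_gap = np.zeros(len(t), dtype=bool)
        for s, e in spans:
            in_gap |= (t >= s) & (t < e)
        t, rr, cvt = t[~in_gap], rr[~in_gap], cvt[~in_gap]
        artifact_flags = artifact_flags[~in_gap]

    quality = _draw_quality(len(t), config, rng)
    rec = NightRecording(
        subject_id=subject.subject_id,
        recording_index=night_index,
        session_start=0.0,
        session_end=duration,
        t=t,
        rr=rr,
        raw_lvs=cvt,
        quality=quality,
        device_id="smartsheet-sim",
    )
    observed_artifacts = np.flatnonzero(artifact_flags)
    truth = NightGroundTruth(
        artifact_indices=[int(i) for i in observed_artifacts],
        artifact_times=[float(t[i]) for i in observed_artifacts],
        n_artifacts_injected=n_injected,
        dropout_spans=[(float(s), float(e)) for s, e in spans],
        stage_track=[(float(s), float(e), name) for s, e, name in track],
        night_level=level,
    )
    return rec, truth


def generate_short_term(
    subject: SubjectProfile, config: SimulationConfig, rng: np.random.Generator
) -> NightRecording:
    """5-minute awake resting recording: flat architecture, clean signal."""
    duration = config.short_term_minutes * 60.0
    level = max(0.0, subject.subject_intercept + config.short_term_offset)
    hr_max = config.base_hr + config.hr_cvt_slope * config.hr_cvt_ref + 1.0
    n_max = int(np.ceil(duration * hr_max / 60.0)) + 16
    cvt = np.maximum(0.0, level + rng.normal(0.0, config.beat_noise_sd, size=n_max))
    hr = np.clip(config.base_hr - config.hr_cvt_slope * (cvt - config.hr_cvt_ref), 30.0, 180.0)
    rr = 60000.0 / hr
    t = np.cumsum(rr) / 1000.0
    keep = t <= duration
    t, rr, cvt = t[keep], rr[keep], cvt[keep]
    quality = rng.integers(13, 16, size=len(t))
    return NightRecording(
        subject_id=subject.subject_id,
        recording_index=0,
        session_start=0.0,
        session_end=duration,
        t=t,
        rr=rr,
        raw_lvs=cvt,
        quality=quality,
        device_id="shortterm-sim",
    )


@dataclass
class Cohort:
    config: SimulationConfig
    subjects: list[SubjectProfile]
    nights: dict  # (subject_id, night_index) -> (NightRecording, NightGroundTruth)
    short_term: dict  # subject_id -> NightRecording

    def metadata(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "can_stage": s.can_stage,
                    "cart_postural": s.cart_abnormal[0],
                    "cart_breathing": s.cart_abnormal[1],
                    "cart_valsalva": s.cart_abnormal[2],
                }
            )
        return pd.DataFrame(rows)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Deterministic cohort: subjects, up to ``nights_per_subject`` nights
    and one short-term recording each, all from one master seed."""
    master = np.random.SeedSequence(config.seed)
    n_total = config.n_control + config.n_t2d
    children = master.spawn(n_total)
    subjects: list[SubjectProfile] = []
    nights: dict = {}
    short: dict = {}
    groups = ["control"] * config.n_control + ["t2d"] * config.n_t2d
    for i, (group, child) in enumerate(zip(groups, children)):
        sid = f"S{i:03d}"
        streams = child.spawn(config.nights_per_subject + 2)
        subj_rng = np.random.default_rng(streams[0])
        subject = generate_subject(config, group, subj_rng, subject_id=sid)
        subjects.append(subject)
        short[sid] = generate_short_term(subject, config, np.random.default_rng(streams[1]))
        for night in range(1, config.nights_per_subject + 1):
            night_rng = np.random.default_rng(streams[1 + night])
            if night_rng.random() < config.night_missing_prob:
                continue
            nights[(sid, night)] = generate_night(subject, config, night, night_rng)
    return Cohort(config=config, subjects=subjects, nights=nights, short_term=short)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Write recordings, ground-truth sidecars, metadata and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(exist_ok=True)
    files = []
    for (sid, night), (rec, truth) in sorted(cohort.nights.items()):
        rec_path = rec_dir / f"{sid}_night{night}.csv"
        write_recording(rec, rec_path)
        truth_path = rec_dir / f"{sid}_night{night}.truth.json"
        truth_path.write_text(json.dumps(truth.to_dict()), encoding="utf-8")
        files += [rec_path.name, truth_path.name]
    for sid, rec in sorted(cohort.short_term.items()):
        p = rec_dir / f"{sid}_short.csv"
        write_recording(rec, p)
        files.append(p.name)
    write_metadata(cohort.metadata(), outdir / "metadata.csv")
    manifest = {
        "seed": cohort.config.seed,
        "n_subjects": len(cohort.subjects),
        "n_night_recordings": len(cohort.nights),
        "n_short_term": len(cohort.short_term),
        "files": sorted(files),
        "config": cohort.config.to_dict(),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
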