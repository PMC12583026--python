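"""End-to-end orchestration: simulate a cohort, process recordings,
summarize, and produce the reliability and diagnostic reports.

Every report echoes the thresholds it was produced with so runs are
auditable; the same config and seed always yield the same numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .metrics import summarize
from .preprocess import (
    ProcessedRecording,
    ProcessingConfig,
    process_recording,
    select_best_recording,
    summarize_raw,
)
from .reliability import fit_random_intercept
from .screening import OUTCOMES, evaluate_biomarkers, results_table
from .simulate import Cohort, SimulationConfig, generate_cohort, write_cohort

log = logging.getLogger("cvtscreen")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    outcomes: tuple[str, ...] = OUTCOMES
    output_dir: str = "cvtscreen_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "processing": dict(self.processing.__dict__),
            "outcomes": list(self.outcomes),
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            simulation=SimulationConfig.from_dict(d.get("simulation", {})),
            processing=ProcessingConfig(**d.get("processing", {})),
            outcomes=tuple(d.get("outcomes", OUTCOMES)),
            output_dir=d.get("output_dir", "cvtscreen_out"),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")


def run_simulate(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate a cohort and write it to ``outdir``; returns the manifest."""
    cohort = generate_cohort(config.simulation)
    manifest = write_cohort(cohort, outdir)
    log.info(
        "simulated %d subjects, %d night recordings",
        manifest["n_subjects"],
        manifest["n_night_recordings"],
    )
    return manifest


def load_cohort_dir(input_dir: str | Path):
    """Read a written cohort back: metadata, night and short recordings."""
    input_dir = Path(input_dir)
    metadata = rio.read_metadata(input_dir / "metadata.csv")
    rec_dir = input_dir / "recordings"
    nights, short = {}, {}
    for path in sorted(rec_dir.glob("*.csv")):
        rec = rio.read_recording(path)
        if path.stem.endswith("_short"):
            short[rec.subject_id] = rec
        else:
            nights[(rec.subject_id, rec.recording_index)] = rec
    return metadata, nights, short


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default, allow_nan=True),
        encoding="utf-8",
    )


def analyze_cohort(
    metadata: pd.DataFrame,
    nights: dict,
    short: dict,
    config: RunConfig,
) -> dict:
    """Full analysis on in-memory recordings; returns all report objects.

    Produces the raw-quality report, per-recording summaries (with
    best-night selection), the night-to-night ICC, group descriptives
    and the diagnostic-performance table.
    """
    pcfg = config.processing
    night_recs = list(nights.values())
    if not night_recs:
        raise ValueError("no night recordings found")
    raw_report = summarize_raw(night_recs)

    processed: dict[str, list[ProcessedRecording]] = {}
    reject_reasons: list[str] = []
    for (sid, _), rec in sorted(nights.items()):
        p = process_recording(rec, pcfg)
        processed.setdefault(sid, []).append(p)
        if not p.accepted:
            reject_reasons.append(
                f"{sid}#{p.recording_index}: "
                f"{p.reject_reason or f'retention {p.retention:.2f} < {pcfg.retention_min}'}"
            )
    n_accepted = sum(p.accepted for ps in processed.values() for p in ps)
    if n_accepted == 0:
        raise ValueError(
            "no accepted recordings; rejections: " + "; ".join(reject_reasons[:10])
        )

    # per-recording mean CVT observations feed the reliability model
    obs_rows = []
    summary_rows = []
    for sid, plist in processed.items():
        for p in plist:
            if p.accepted and p.n_retained >= 2:
                s = summarize(p.cvt, "long_term")
                obs_rows.append(
                    {"subject_id": sid, "recording_number": p.recording_index,
                     "mean_cvt": s.mean_cvt}
                )
    icc_result = None
    icc_error = None
    try:
        icc_result = fit_random_intercept(pd.DataFrame(obs_rows))
    except (ValueError, RuntimeError) as exc:
        icc_error = str(exc)

    # best night per subject -> long-term biomarkers; short-term separately
    biomarker_rows = {}
    for sid, plist in processed.items():
        row = {"short_term_mean": np.nan, "long_term_mean": np.nan,
               "long_term_capacity": np.nan}
        try:
            best = select_best_recording(plist)
        except ValueError:
            best = None
        if best is not None and best.n_retained >= 2:
            s = summarize(best.cvt, "long_term")
            row["long_term_mean"] = s.mean_cvt
            row["long_term_sd"] = s.sd_cvt
            if s.capacity is not None:
                row["long_term_capacity"] = s.capacity
            row["best_recording_index"] = best.recording_index
            row["best_retention"] = best.retention
            summary_rows.append(
                {"subject_id": sid, "recording_index": best.recording_index,
                 "source": "long_term", "mean_cvt": s.mean_cvt, "sd_cvt": s.sd_cvt,
                 "capacity": s.capacity, "n_points": s.n_points}
            )
        biomarker_rows[sid] = row
    for sid, rec in short.items():
        p = process_recording(rec, pcfg)
        if p.accepted and p.n_retained >= 2:
            s = summarize(p.cvt, "short_term")
            biomarker_rows.setdefault(
                sid, {"short_term_mean": np.nan, "long_term_mean": np.nan,
                      "long_term_capacity": np.nan}
            )["short_term_mean"] = s.mean_cvt
            summary_rows.append(
                {"subject_id": sid, "recording_index": 0, "source": "short_term",
                 "mean_cvt": s.mean_cvt, "sd_cvt": s.sd_cvt,
                 "capacity": s.capacity, "n_points": s.n_points}
            )
    biomarkers = pd.DataFrame.from_dict(biomarker_rows, orient="index")
    biomarkers.index.name = "subject_id"
    summaries = pd.DataFrame(summary_rows)

    stages = metadata.set_index("subject_id")["can_stage"]
    stages = stages.reindex(biomarkers.index)
    diagnostics = evaluate_biomarkers(
        biomarkers, stages, outcomes=config.outcomes
    )

    # group descriptives: median (IQR) of each biomarker by group and stage
    merged = biomarkers.join(metadata.set_index("subject_id")[["group", "can_stage"]])
    desc_rows = []
    for by in ("group", "can_stage"):
        for key, sub in merged.groupby(by):
            for col in ("short_term_mean", "long_term_mean", "long_term_capacity"):
                vals = sub[col].dropna()
                if len(vals) == 0:
                    continue
                desc_rows.append(
                    {"stratum": by, "level": key, "biomarker": col, "n": len(vals),
                     "median": float(vals.median()),
                     "q1": float(vals.quantile(0.25)),
                     "q3": float(vals.quantile(0.75))}
                )
    descriptives = pd.DataFrame(desc_rows)

    return {
        "raw_quality": raw_report.to_dict(),
        "summaries": summaries,
        "reliability": (icc_result.to_dict() if icc_result else {"error": icc_error}),
        "descriptives": descriptives,
        "diagnostics": diagnostics,
        "thresholds": dict(pcfg.__dict__),
        "n_recordings_accepted": int(n_accepted),
        "rejections": reject_reasons,
    }


def run_analyze(input_dir: str | Path, config: RunConfig, outdir: str | Path) -> dict:
    """Analyze a cohort directory and write the report files."""
    metadata, nights, short = load_cohort_dir(input_dir)
    report = analyze_cohort(metadata, nights, short, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _dump({"raw_quality": report["raw_quality"], "thresholds": report["thresholds"]},
          outdir / "raw_quality.json")
    report["summaries"].to_csv(outdir / "summaries.csv", index=False, lineterminator="\n")
    _dump({**report["reliability"], "thresholds": report["thresholds"]},
          outdir / "reliability.json")
    report["descriptives"].to_csv(outdir / "descriptives.csv", index=False, lineterminator="\n")
    diag = results_table(report["diagnostics"])
    diag.to_csv(outdir / "diagnostics.csv", index=False, lineterminator="\n")
    _dump({"results": [r.to_dict() for r in report["diagnostics"]],
           "thresholds": report["thresholds"]}, outdir / "diagnostics.json")
    log.info("reports written to %s", outdir)
    return report


def run_end_to_end(config: RunConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Simulate then analyze in one invocation under a single seed."""
    if seed is not None:
        config.simulation.seed = seed
        config.simulation.validate()
    outdir = Path(outdir)
    sim_dir = outdir / "cohort"
    run_simulate(config, sim_dir)
    return run_analyze(sim_dir, config, outdir / "reports")
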