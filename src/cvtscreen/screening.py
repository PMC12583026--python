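"""Clinical rule classifiers and diagnostic-performance evaluation.

Covers autonomic-neuropathy staging from reflex-test results, orthostatic
and nocturnal blood-pressure rules, and ROC machinery: empirical curves,
Mann-Whitney AUC, DeLong confidence intervals, Youden cut-offs and
confusion-matrix summaries.  Vagal-tone biomarkers use a lower-is-positive
orientation (disease lowers vagal tone), exposed as a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CAN_STAGES",
    "DiagnosticResult",
    "stage_can",
    "classify_orthostatic",
    "is_reverse_dipper",
    "roc_points",
    "auc",
    "auc_trapezoid",
    "delong_variance",
    "delong_ci",
    "youden_cutoff",
    "confusion_at_cutoff",
    "evaluate_biomarkers",
]

CAN_STAGES = ("none", "early", "manifest")

OUTCOMES = ("any_can", "early_can", "manifest_can")

BIOMARKERS = ("short_term_mean", "long_term_mean", "long_term_capacity")


def stage_can(cart_abnormal: Sequence[bool]) -> str:
    """Stage from the three reflex-test results: 0 abnormal -> none,
    1 -> early, 2 or more -> manifest."""
    if len(cart_abnormal) != 3:
        raise ValueError(f"expected three test results, got {len(cart_abnormal)}")
    n_abnormal = sum(bool(x) for x in cart_abnormal)
    if n_abnormal == 0:
        return "none"
    if n_abnormal == 1:
        return "early"
    return "manifest"


def classify_orthostatic(
    baseline_bp: tuple[float, float],
    readings: Sequence[tuple[float, float, float]],
) -> str:
    """Orthostatic-intolerance category from a 10-minute standing test.

    A drop of >= 20 mmHg systolic or >= 10 mmHg diastolic versus baseline
    counts; the first qualifying reading sets the category: within the
    first minute -> initial, first to third minute -> classic, fourth to
    tenth -> delayed.  Returns ``"none"`` if the criterion is never met.
    """
    if not readings:
        raise ValueError("empty readings")
    base_sys, base_dia = baseline_bp
    for minute, sys_bp, dia_bp in sorted(readings, key=lambda r: r[0]):
        if not (0 <= minute <= 10):
            raise ValueError(f"reading at minute {minute} outside the 10-minute window")
        if (base_sys - sys_bp) >= 20 or (base_dia - dia_bp) >= 10:
            if minute < 1:
                return "initial"
            if minute <= 3:
                return "classic"
            return "delayed"
    return "none"


def is_reverse_dipper(
    day_mean: tuple[float, float], night_mean: tuple[float, float]
) -> bool:
    """Nocturnal pressure rises >= 10% above daytime on either component."""
    day_sys, day_dia = day_mean
    night_sys, night_dia = night_mean
    if min(day_sys, day_dia, night_sys, night_dia) <= 0:
        raise ValueError("blood pressures must be positive")
    # n >= 1.1*d written as 10n >= 11d to keep the 10% boundary exact
    return night_sys * 10.0 >= day_sys * 11.0 or night_dia * 10.0 >= day_dia * 11.0


class RocPoint(NamedTuple):
    fpr: float
    tpr: float
    threshold: float


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must be the same length")
    cases, controls = scores[labels], scores[~labels]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need at least one case and one control")
    return cases, controls


def roc_points(scores, labels, lower_is_positive: bool = True) -> list[RocPoint]:
    """Empirical ROC curve over the observed thresholds plus sentinels.

    With the lower-is-positive orientation a subject is classified
    positive iff score <= threshold; points are monotone in both rates.
    """
    cases, controls = _split(scores, labels)
    thresholds = np.unique(np.concatenate([cases, controls]))
    if not lower_is_positive:
        thresholds = thresholds[::-1]
    pts = [RocPoint(0.0, 0.0, -math.inf if lower_is_positive else math.inf)]
    for thr in thresholds:
        if lower_is_positive:
            tpr = float(np.mean(cases <= thr))
            fpr = float(np.mean(controls <= thr))
        else:
            tpr = float(np.mean(cases >= thr))
            fpr = float(np.mean(controls >= thr))
        pts.append(RocPoint(fpr, tpr, float(thr)))
    return pts


def auc(scores, labels, lower_is_positive: bool = True) -> float:
    """AUC as the Mann-Whitney statistic: probability a random case is
    more extreme than a random control, counting ties as one half."""
    cases, controls = _split(scores, labels)
    x = np.concatenate([cases, controls])
    if lower_is_positive:
        x = -x
    ranks = stats.rankdata(x)
    m = len(cases)
    n = len(controls)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def auc_trapezoid(points: Iterable[RocPoint]) -> float:
    """Trapezoidal area under an empirical ROC curve."""
    pts = sorted(points, key=lambda p: (p.fpr, p.tpr))
    area = 0.0
    for (f0, t0, _), (f1, t1, _) in zip(pts, pts[1:]):
        area += (f1 - f0) * (t0 + t1) / 2.0
    return area


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components via midranks (higher-is-positive)."""
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    rank_all = stats.rankdata(combined)
    rank_cases = stats.rankdata(cases)
    rank_controls = stats.rankdata(controls)
    v10 = (rank_all[:m] - rank_cases) / n  # per-case placement
    v01 = 1.0 - (rank_all[m:] - rank_controls) / m  # per-control placement
    return v10, v01


def delong_variance(scores, labels, lower_is_positive: bool = True) -> float:
    """DeLong sampling variance of the empirical AUC."""
    cases, controls = _split(scores, labels)
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("DeLong variance needs >= 2 cases and >= 2 controls")
    if lower_is_positive:
        cases, controls = -cases, -controls
    v10, v01 = _placements(cases, controls)
    s10 = float(np.var(v10, ddof=1))
    s01 = float(np.var(v01, ddof=1))
    return s10 / len(cases) + s01 / len(controls)


def delong_ci(
    scores, labels, level: float = 0.95, lower_is_positive: bool = True
) -> tuple[float, float]:
    """Normal-approximation AUC confidence interval, clipped to [0, 1]."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    a = auc(scores, labels, lower_is_positive)
    var = delong_variance(scores, labels, lower_is_positive)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(0.0, var))
    return (max(0.0, a - half), min(1.0, a + half))


class YoudenResult(NamedTuple):
    cutoff: float
    sensitivity: float
    specificity: float
    tied_cutoffs: tuple[float, ...]  # all observed cutoffs attaining max J


def youden_cutoff(scores, labels, lower_is_positive: bool = True) -> YoudenResult:
    """Observed score maximizing J = sensitivity + specificity - 1.

    Ties in J are broken toward higher specificity, then lower cutoff;
    all tied cutoffs are reported alongside the chosen one.
    """
    cases, controls = _split(scores, labels)
    candidates = np.unique(np.concatenate([cases, controls]))
    best = None
    rows = []
    for thr in candidates:
        if lower_is_positive:
            sens = float(np.mean(cases <= thr))
            spec = float(np.mean(controls > thr))
        else:
            sens = float(np.mean(cases >= thr))
            spec = float(np.mean(controls < thr))
        j = sens + spec - 1.0
        rows.append((j, spec, float(thr), sens))
        key = (-j, -spec, thr)
        if best is None or key < best[0]:
            best = (key, float(thr), sens, spec, j)
    _, cutoff, sens, spec, jmax = best
    ties = tuple(thr for j, _, thr, _ in rows if abs(j - jmax) < 1e-12)
    return YoudenResult(cutoff, sens, spec, ties)


class Confusion(NamedTuple):
    sensitivity: float
    specificity: float
    fpr: float
    tpr: float
    ppv: float  # nan when no subject is predicted positive
    npv: float  # nan when no subject is predicted negative


def confusion_at_cutoff(
    scores, labels, cutoff: float, lower_is_positive: bool = True
) -> Confusion:
    """2x2-table rates at a fixed cutoff; predictive values use sample
    prevalence and are reported as nan (undefined) on empty margins."""
    cases, controls = _split(scores, labels)
    if lower_is_positive:
        tp = int(np.sum(cases <= cutoff))
        fp = int(np.sum(controls <= cutoff))
    else:
        tp = int(np.sum(cases >= cutoff))
        fp = int(np.sum(controls >= cutoff))
    fn = len(cases) - tp
    tn = len(controls) - fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return Confusion(sens, spec, 1.0 - spec, sens, ppv, npv)


@dataclass
class DiagnosticResult:
    """ROC summary for one biomarker x outcome contrast."""

    biomarker: str
    outcome: str
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    fpr: float
    tpr: float
    ppv: float
    npv: float
    n_cases: int
    n_controls: int
    reliable: bool = True
    tied_cutoffs: tuple[float, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["auc_ci_low"], d["auc_ci_high"] = d.pop("auc_ci")
        d["tied_cutoffs"] = list(d["tied_cutoffs"])
        return d


def _outcome_frame(stages: pd.Series, outcome: str) -> pd.Series:
    """Case/control labels for one contrast; manifest subjects are
    excluded from the early contrast and vice versa."""
    if outcome == "any_can":
        keep = stages.isin(CAN_STAGES)
        labels = stages[keep].isin(["early", "manifest"])
    elif outcome == "early_can":
        keep = stages.isin(["none", "early"])
        labels = stages[keep] == "early"
    elif outcome == "manifest_can":
        keep = stages.isin(["none", "manifest"])
        labels = stages[keep] == "manifest"
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return labels


def evaluate_biomarkers(
    summaries: pd.DataFrame,
    stages: pd.Series,
    biomarkers: Sequence[str] = BIOMARKERS,
    outcomes: Sequence[str] = OUTCOMES,
    lower_is_positive: bool = True,
    ci_level: float = 0.95,
) -> list[DiagnosticResult]:
    """One :class:`DiagnosticResult` per biomarker x outcome.

    ``summaries`` is indexed by subject with one column per biomarker;
    ``stages`` maps subject -> CAN stage.  Missing biomarker values are
    dropped pairwise per contrast.  Contrasts with fewer than two cases
    or controls are flagged ``reliable=False`` rather than dropped.
    """
    results = []
    for outcome in outcomes:
        labels = _outcome_frame(stages, outcome)
        for biomarker in biomarkers:
            if biomarker not in summaries.columns:
                raise ValueError(f"biomarker column {biomarker!r} missing")
            values = summaries[biomarker].reindex(labels.index)
            ok = values.notna()
            v = values[ok].to_numpy(dtype=float)
            y = labels[ok].to_numpy(dtype=bool)
            n_cases, n_controls = int(y.sum()), int((~y).sum())
            reliable = n_cases >= 2 and n_controls >= 2
            if n_cases == 0 or n_controls == 0:
                results.append(
                    DiagnosticResult(
                        biomarker, outcome, float("nan"), (float("nan"), float("nan")),
                        float("nan"), float("nan"), float("nan"), float("nan"),
                        float("nan"), float("nan"), float("nan"),
                        n_cases, n_controls, reliable=False,
                    )
                )
                continue
            a = auc(v, y, lower_is_positive)
            ci = (
                delong_ci(v, y, ci_level, lower_is_positive)
                if reliable
                else (float("nan"), float("nan"))
            )
            yr = youden_cutoff(v, y, lower_is_positive)
            conf = confusion_at_cutoff(v, y, yr.cutoff, lower_is_positive)
            results.append(
                DiagnosticResult(
                    biomarker=biomarker,
                    outcome=outcome,
                    auc=a,
                    auc_ci=ci,
                    cutoff=yr.cutoff,
                    sensitivity=conf.sensitivity,
                    specificity=conf.specificity,
                    fpr=conf.fpr,
                    tpr=conf.tpr,
                    ppv=conf.ppv,
                    npv=conf.npv,
                    n_cases=n_cases,
                    n_controls=n_controls,
                    reliable=reliable,
                    tied_cutoffs=yr.tied_cutoffs,
                )
            )
    return results


def results_table(results: Sequence[DiagnosticResult]) -> pd.DataFrame:
    """Flat table of diagnostic results (one row per biomarker x outcome)."""
    return pd.DataFrame([r.to_dict() for r in results])
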