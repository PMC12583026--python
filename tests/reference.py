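"""Naive single-pass reference implementations used as test oracles.

Deliberately written with plain Python loops, independent of the package
internals, directly from the stated filtering rules.
"""

from __future__ import annotations


def reference_process(
    rec,
    roll_window: int = 10,
    edge_trim: int = 10,
    artifact_jump: float = 15.0,
    excision_flank: int = 7,
    quality_min: int = 10,
    retention_min: float = 0.70,
):
    """Return (cvt_values, n_original, n_retained, retention, accepted)
    or None when the recording is too short to roll and trim."""
    lvs = [float(x) for x in rec.raw_lvs]
    rr = [float(x) for x in rec.rr]
    quality = [int(q) for q in rec.quality]
    n = len(lvs)
    w, e = roll_window, edge_trim
    if n < w:
        return None
    rolled = [sum(lvs[i - w + 1 : i + 1]) / w for i in range(w - 1, n)]
    raw_of_rolled = list(range(w - 1, n))
    if len(rolled) <= 2 * e:
        return None
    trimmed = rolled[e : len(rolled) - e]
    raw_of_trimmed = raw_of_rolled[e : len(rolled) - e]

    hr = [60000.0 / x for x in rr]
    artifacts = [i for i in range(1, n) if hr[i] - hr[i - 1] > artifact_jump]
    removed: set[int] = set()
    for a in artifacts:
        pos = a - (w - 1) - e
        for k in range(pos - excision_flank, pos + excision_flank + 1):
            if 0 <= k < len(trimmed):
                removed.add(k)
    survivors = [k for k in range(len(trimmed)) if k not in removed]
    final = [trimmed[k] for k in survivors if quality[raw_of_trimmed[k]] >= quality_min]
    n_original = len(trimmed)
    n_retained = len(final)
    retention = n_retained / n_original
    return final, n_original, n_retained, retention, retention >= retention_min


def reference_auc_paircount(scores, labels, lower_is_positive=True):
    """AUC by exhaustive case/control pair counting, ties count one half."""
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for c in cases:
        for k in controls:
            if c == k:
                total += 0.5
            elif (c < k) if lower_is_positive else (c > k):
                total += 1.0
    return total / (len(cases) * len(controls))


def reference_delong_variance(scores, labels, lower_is_positive=True):
    """DeLong variance via explicit double loops over the kernel."""
    sign = -1.0 if lower_is_positive else 1.0
    cases = [sign * s for s, y in zip(scores, labels) if y]
    controls = [sign * s for s, y in zip(scores, labels) if not y]
    m, n = len(cases), len(controls)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    v10 = [sum(psi(c, k) for k in controls) / n for c in cases]
    v01 = [sum(psi(c, k) for c in cases) / m for k in controls]
    a = sum(v10) / m
    s10 = sum((v - a) ** 2 for v in v10) / (m - 1)
    s01 = sum((v - a) ** 2 for v in v01) / (n - 1)
    return s10 / m + s01 / n


def reference_youden(scores, labels, lower_is_positive=True):
    """Maximal J over an exhaustive scan of all observed thresholds."""
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    best_j = -2.0
    for thr in sorted(set(scores)):
        if lower_is_positive:
            sens = sum(c <= thr for c in cases) / len(cases)
            spec = sum(k > thr for k in controls) / len(controls)
        else:
            sens = sum(c >= thr for c in cases) / len(cases)
            spec = sum(k < thr for k in controls) / len(controls)
        best_j = max(best_j, sens + spec - 1.0)
    return best_j


def reference_anova_components(values_by_subject):
    """Balanced one-way ANOVA method-of-moments variance components.

    ``values_by_subject`` is a list of equal-length lists.
    """
    k = len(values_by_subject[0])
    a = len(values_by_subject)
    grand = sum(sum(v) for v in values_by_subject) / (a * k)
    subject_means = [sum(v) / k for v in values_by_subject]
    msb = k * sum((m - grand) ** 2 for m in subject_means) / (a - 1)
    msw = sum(
        (x - m) ** 2 for v, m in zip(values_by_subject, subject_means) for x in v
    ) / (a * (k - 1))
    var_within = msw
    var_between = max(0.0, (msb - msw) / k)
    return var_between, var_within
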