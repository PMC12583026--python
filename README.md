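# cvtscreen

Processing and screening analysis for overnight cardiac vagal tone (CVT)
recordings, aimed at detecting cardiovascular autonomic neuropathy (CAN)
in type 2 diabetes. The package covers the whole workflow:

- **`cvtscreen.simulate`** — synthetic cohorts of per-beat overnight and
  short-term recordings with a hierarchical latent structure: group × CAN-stage
  vagal-tone levels, night-to-night variation, square-wave sleep architecture
  (non-REM baseline, REM dips, wake bouts), HR–CVT coupling, injected HR-spike
  artifacts, contiguous dropout gaps, and device-like 0–15 quality scores.
  Ground-truth corruption labels are returned for testing.
- **`cvtscreen.io`** — a plain-text beat-series CSV dialect
  (`#key=value` preamble, `t_s,rr_ms,raw_lvs,quality` columns) and a cohort
  metadata table, with line-level validation and lossless round-trips.
- **`cvtscreen.preprocess`** — missing-data estimation from mean heart rate,
  10-point rolling CVT, 10+10 edge exclusion, artifact detection
  (beat-to-beat HR increase >15 bpm) with ±7-point excision windows,
  quality filtering (score <10 removed), the 70% retention rule, raw-data
  descriptives and deterministic best-recording selection.
- **`cvtscreen.metrics`** — per-recording mean, SD and "CVT capacity"
  (mean absolute deviation from the whole-series mean of the 10 highest and
  10 lowest values).
- **`cvtscreen.reliability`** — profiled-REML variance components for the
  random-intercept model (recording number as fixed effect) and the
  intraclass correlation coefficient.
- **`cvtscreen.screening`** — CAN staging from reflex-test results,
  orthostatic-intolerance and reverse-dipper rules, and ROC machinery:
  empirical curves, Mann–Whitney AUC, DeLong confidence intervals, Youden
  cut-offs and confusion-matrix summaries, assembled into a diagnostic
  table per biomarker × outcome.
- **`cvtscreen.pipeline` / `cvtscreen.cli`** — end-to-end orchestration with
  YAML configuration and report generation.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence against naive reference implementations, rule boundaries,
DeLong CI coverage, ICC parameter recovery, end-to-end binormal effect
recovery, bookkeeping conservation).

## CLI

```sh
# simulate a cohort
cvtscreen simulate --config config.yaml --seed 1 --out cohort/

# preprocess one recording
cvtscreen process --input cohort/recordings/S000_night1.csv --out processed/

# summary metrics for one recording
cvtscreen metrics --input cohort/recordings/S000_night1.csv

# ICC from a per-recording mean-CVT table
cvtscreen reliability --input observations.csv --out reports/

# ROC evaluation of biomarker columns against CAN stages
cvtscreen evaluate --summaries biomarkers.csv --metadata cohort/metadata.csv --out reports/

# simulate + analyze end to end
cvtscreen run --seed 1 --out run1/
```

`cvtscreen run` writes a cohort under `<out>/cohort/` and reports under
`<out>/reports/`: `raw_quality.json`, `summaries.csv`, `reliability.json`,
`descriptives.csv`, `diagnostics.csv`/`.json`. Every report echoes the
processing thresholds used. The same config and seed always reproduce the
same bytes.

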