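# perisim

In-silico static automated perimetry: simulate visual-field testing on
synthetic observers with known ground truth, compare thresholding
strategies across instruments with different dynamic ranges, and run the
full agreement/severity statistical battery on the results.

## What it models

* **Test grids** (`perisim.geometry`) — the 76-point central-30° pattern
  ("30-2") and the 66-point subset ("SPARK66", top/bottom rows and
  blind-spot pair removed), eye transposition, location matching and a
  six-sector functional partition with one seed point per sector.
* **Decibel scales** (`perisim.scales`) — `dB = k − 10·log10(ΔL)` style
  attenuation scales with instrument constants k = 40 (10,000 asb maximum)
  and k = 30 (1,000 asb maximum), cross-scale conversion (0 dB on k=30 ≡
  10 dB on k=40) and floor clipping — the *plateau effect* that truncates
  deep defects on the short-range instrument.
* **Synthetic observers** (`perisim.observer_sim`) — hill-of-vision normals,
  focal (glaucoma-like) bundle defects, diffuse (cataract-like) loss, and a
  frequency-of-seeing response model (cumulative Gaussian with
  sensitivity-dependent spread, false-positive/negative/fixation-loss
  rates). Ground truth is stored on the k=40 reference scale.
* **Strategies** (`perisim.strategies`) — a four-phase interpolation
  strategy (6 directly bracketed seeds + regression/interpolation, then
  three 21-point refinement phases, final median-of-4 combine that discards
  the most extreme estimate) and a classic 4-2 staircase stand-in for
  per-location Bayesian strategies, plus catch trials and a test-time
  proxy.
* **Indices** (`perisim.indices`) — simulated normative databases, MS, total
  and pattern deviation, MD, PSD, NAPDP.
* **AGIS scoring** (`perisim.agis`) — 0–20 severity score from a
  total-deviation map (nasal 0–2, each hemifield 0–9), categories
  none/mild/moderate/severe/end-stage, criteria in one editable JSON table.
* **Agreement statistics** (`perisim.agreement`) — Bland–Altman bias and 95%
  limits of agreement, proportional-bias regression, Spearman rank
  correlation and the Wilcoxon signed-rank test (implemented from their
  definitions; verified against SciPy), pointwise bias maps.
* **Study pipeline** (`perisim.pipeline`) — cohorts → both strategies on
  both instruments → reliability filtering (FP > 20%, FN > 20%, FL > 30%;
  FN not assessed by the four-phase strategy) → indices/AGIS → agreement
  battery → CSV/JSON report with a config-hash manifest. Fully
  deterministic from one seed.

## CLI

```sh
perisim simulate-cohort --group glaucoma --n 39 --seed 1 --out cohort.json
perisim run-strategy --strategy spark4 --observers cohort.json --seed 1 --out outcomes/
perisim build-normative --strategy staircase42 --n 60 --seed 1 --out normdb.json
perisim score-agis --td td_map.csv
perisim agree --a values_a.csv --b values_b.csv
perisim run-study --seed 1 --out report/          # full in-silico study
```

`run-study` accepts a YAML/JSON config (`--config`); see
`perisim.pipeline.StudyConfig` for the keys and defaults (39 glaucoma + 31
cataract observers, four-phase strategy on the k=30 instrument vs staircase
on the k=40 instrument).

## Notes

* The 4-2 staircase is a declared stand-in for proprietary per-location
  strategies; only its per-location independence matters for the
  comparisons made here.
* The k=30 instrument is modelled with a 1,000 asb maximum stimulus
  (0–30 dB range); thresholds it reports can therefore never fall below
  10 dB when re-expressed on the k=40 scale, which is the mechanism that
  makes deep focal loss look shallower on that instrument.
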