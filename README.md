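# mmn-rubberband

Synthetic auditory-oddball ERP simulation and mismatch-negativity (MMN)
difference-wave analysis: nine-parameter waveform characterization with
threshold-based fake-MMN rejection, electrode-wise Spearman correlation
counting, and region-of-interest (ROI) amplitude-vs-slope analysis.

The package ships its own data source: an oddball cohort generator with
known ground truth and a controllable amplitude–slope coupling mode —
`rubberband` (fixed return-to-baseline window, so the descent rate grows
with amplitude) versus `null` (descent rate independent of amplitude).
Every downstream stage is testable against that ground truth.

## Layout

| module | role |
|---|---|
| `mmn_rubberband.synth` | stimulus sequences, ground-truth draws, deflection components, epoch synthesis |
| `mmn_rubberband.waveforms` | baseline correction, zero-phase 25 Hz low-pass, condition averaging, difference waves, ROI averaging |
| `mmn_rubberband.extraction` | the nine parameters (amplitude, ampavg, onset, offset, peak latency, duration, area, upslope, downslope) + threshold/validity |
| `mmn_rubberband.correlations` | Spearman stage, all-pairs grid, significance-count table, ROI table, normality logging |
| `mmn_rubberband.pipeline` / `cli` / `config` | orchestration, YAML/JSON config, reporting, CLI |

## CLI

```sh
# full pipeline: simulate → average → extract → correlate → report
mmn-rubberband all --out out/ --seed 1 --mode rubberband

# stage by stage (keep trial counts small for the epochs CSV)
mmn-rubberband simulate --mode rubberband --subjects 6 --seed 1 --out sim/ \
    --n-deviant-trials 8 --n-standard-trials 16
mmn-rubberband extract --epochs sim/ --out ext/
mmn-rubberband correlate --parameters ext/parameters.csv \
    --roi-parameters ext/roi_parameters.csv --out cor/
mmn-rubberband report --tables cor/ --out report.md
```

`all` writes `ground_truth.csv`, `waves.csv`, `parameters.csv`,
`roi_parameters.csv`, `correlations.csv`, `table2_counts.csv`,
`table3_roi.csv`, `normality.csv`, `recovery.csv`, `report.md` and a
`config.json` provenance sidecar. Raw epochs are streamed, not persisted,
by `all`; use `simulate` for an epochs CSV. Hyperparameters come from a
YAML/JSON config (`--config cfg.yaml`); exit code 2 flags config errors,
3 data errors.

## Defaults

22 subjects, 13 electrodes (FPZ FZ FCZ CZ CPZ F1 F3 F2 F4 FT7 FT8 T7 T8),
ISIs 1.5/3/4.5/6 s, 150-stimulus blocks (120 standard + 30 deviant,
deviants separated by ≥2 standards, first five standard), epochs −400 to
+798 ms at 500 Hz, baseline −200..0 ms, peak window 100–300 ms, ampavg
±20 ms, significance counting at p < 0.1 (strict p < 0.05 in
parentheses), ROIs frontal/central/left-temporal/right-temporal.

A wave's rejection threshold is baseline mean − baseline SD; waves never
dipping strictly below it inside the peak window are "fake" and excluded.

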