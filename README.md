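# pwvloop

Local pulse wave velocity (PWV) in the ascending aorta from sequentially
acquired ultrasound recordings, using the ln(D)U-loop technique.

The package implements the full offline analysis chain:

1. **image_io** — read cine recordings (text sidecar dialect: ASCII PGM
   frames + `recording.yaml`; DICOM optionally via `pydicom`), concatenate
   frames into one continuous image, extract pixel calibrations.
2. **ecg** — extract the embedded ECG strip and detect R-wave peaks by
   threshold crossing at 0.8 of the ECG height.
3. **tracing** — threshold-based wall tracing in user ROIs (inner edge to
   inner edge diameter, cm) and maximum Doppler envelope extraction (m/s),
   with artefact exclusion and smoothing-spline gap filling (parameter 0.001).
4. **beats** — R-to-R beat segmentation, systolic upstroke-onset detection
   by backward linear regression (r² threshold 0.985), six-beat moving-window
   groups, and cycle-length-based group matching across modalities.
5. **loop** — onset-aligned, tail-truncated (lnD, U) pairs; forward-growing
   early-systolic linear fit while r² > 0.98; PWV = ½ · dU/dlnD.
6. **ensemble** — all beat pairings across runs (3 × 6 D beats × 3 × 6 U
   beats = 324 loops), 10% trimmed mean with within-subject SD, cohort
   summaries.
7. **synthetic** — ground-truth generator: physiologic diameter/velocity
   waveform pairs with known wave speed, beat-to-beat variability, delayed
   reflections, and renderers producing M-mode-like and Doppler-like images
   with an embedded ECG strip — so every stage is testable without data.
8. **cli** — end-to-end orchestration with YAML config and JSON-lines logs.

## Usage

Generate a synthetic subject (3 diameter + 3 velocity image runs, ground
truth, and a ready-to-run pipeline config):

```bash
synth subject --seed 1 --c-true 4.1 --pixel-noise 6 --out subj1
pwv from-images --config subj1/config.yaml --out subj1/out
```

Or work at the waveform level (CSV `time_ms,value` with R-peak sidecars):

```bash
synth waveforms --seed 1 --c-true 4.1 --out subj1w
pwv from-waveforms --config subj1w/config.yaml --out subj1w/out
```

Outputs: per-run waveform CSVs, `loops.csv` (slope, r², n_fit, PWV and QC
flags per pairing), `subject.json` (trimmed-mean PWV ± wsd), and
`log.jsonl` with every per-beat decision.

Key config defaults (YAML sections): `ecg.threshold_fraction` 0.8,
`ecg.refractory_ms` 200, `tracing.smoothing_parameter` 0.001,
`beats.group_size` 6, `beats.upstroke_r2` 0.985, `loop.dt_ms` 1.0,
`loop.fit_r2` 0.98, `ensemble.trim_fraction` 0.10.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a
20-subject image-to-report parameter-recovery study (±10% of the true wave
speed) and exact-equivalence checks against independent brute-force oracles.

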