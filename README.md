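# tasteeg

Taste-response EEG classification pipeline: synthetic 2-channel EEG
generation, artifact screening, zero-phase bandpass filtering,
fractional-stride windowing, a three-branch 1-D convolutional classifier
(pure NumPy), and one-vs-rest evaluation metrics.

The pipeline mirrors a gustatory-cortex EEG study design: 2-channel
(C3/C4) recordings sampled at 512 Hz, 16 s per trial, labeled with one of
four stimuli (water, sucrose, aspartame, sucralose). A synthetic generator
with controllable class separability (`effect_size`) makes every stage
testable without any external recordings.

## Layout

| module | purpose |
| --- | --- |
| `tasteeg.synth` | 1/f-background synthetic EEG with class-specific band oscillations, onset envelope, artifact injection, CSV dataset I/O |
| `tasteeg.preprocess` | amplitude/flatline screening, 4th-order Butterworth 8–40 Hz zero-phase bandpass, 1,028-sample windows with 0.1-s (51.2-sample) fractional stride, per-window z-scoring, segment/group-level stratified splits |
| `tasteeg.nn` | minimal NumPy NN engine (Conv1D via im2col, max-pool, dropout, dense, Adam) |
| `tasteeg.model` | the three-branch convolutional classifier, training/prediction, FFT band-power baseline, checkpointing |
| `tasteeg.evaluation` | confusion matrices, one-vs-rest accuracy/precision/recall/F1 with macro averages, the reconstructed 682-window reference matrix, grand-average traces |
| `tasteeg.screening` | participant eligibility from 9-cm VAS sweetness ratings |
| `tasteeg.pipeline` / `tasteeg.cli` | end-to-end orchestration with deterministic seeding and run directories |

## Notable conventions

- **Windowing**: window `k` starts at sample `floor(k × stride_s × fs)`.
  At 512 Hz with a 0.1-s stride this is an accumulated fractional stride of
  51.2 samples, giving exactly 140 windows per 16-s recording and 9,520
  across 68 recordings. Window length defaults to 1,028 samples (1,024 is
  available via config).
- **Per-class accuracy** is one-vs-rest binary accuracy `(TP+TN)/total`,
  not `trace/total`; the micro accuracy is exposed separately
  (`ConfusionMatrix.micro_accuracy`).
- **Group-level splitting** (all windows of a recording on one side) is
  the default: 0.1-s-stride windows overlap ~95 %, so a segment-level
  split leaks training data into the test set. Segment-level splitting is
  available for comparison.
- The reference confusion matrix completes three unprinted cells by
  reconciling the reference row percentages with the reference precision
  values; the narrated water→sucralose count of 4 is arithmetically
  incompatible with the reference sucrose precision (0.8857) and is
  treated as an erratum (water→sucrose = 4, water→sucralose = 12).

## CLI

```sh
tasteeg simulate --seed 1 --out runs/sim              # synthetic dataset + manifest
tasteeg screen vas_responses.csv                      # VAS participant screening
tasteeg preprocess runs/sim/manifest.csv              # screen/filter/window/normalize
tasteeg run-all --config config.yaml --seed 1 --out runs/exp1
tasteeg report runs/exp1                              # per-class metric table
```

A YAML config mirrors `PipelineConfig` (sections `synth`, `preprocess`,
`model`, `train` plus top-level `mode`, `seed`, `split_fraction`,
`split_mode`); see `tests/test_pipeline.py` for a complete example.

## Determinism

One integer seed drives dataset generation (per-recording seeds are keyed
SHA-256 hashes, so any single trial is reproducible in isolation), split
assignment, weight initialization, batch shuffling and dropout. Data-level
artifacts are bit-reproducible; training reproducibility is statistical
(BLAS reduction order may vary across platforms).
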