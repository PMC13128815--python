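# gaitmoment

Hip joint moment regression from surface EMG and joint-angle time series.

The package implements a desk-scale pipeline that predicts hip
flexion/extension (`hip_fe`) and abduction/adduction (`hip_aa`) moments from
four sEMG channels (gluteus medius, semitendinosus, biceps femoris, rectus
femoris) and two hip joint angles:

1. **signal_io** — CSV recording ingestion, NaN-row dropping, pure
   sample-dropping decimation (e.g. 1000 Hz → 200 Hz with a 5 ms step),
   predictor/target alignment, and a loader for nested
   `subject/date/mode/sensor` table directories.
2. **preprocessing** — overlapping sliding windows (default 60 samples =
   300 ms at 200 Hz, stride 1), per-channel z-scoring fitted on training
   data, and the full two-sided DFT magnitude per window/channel (feature
   length = window length).
3. **autoencoder** — a shared 4-layer MLP encoder/decoder
   (`input_dim → input_dim/2 → input_dim/4 → input_dim/2 → input_dim`,
   affine + ReLU with the bias inside the activation) applied per channel,
   plus a single same-length 1-D convolution over the latent axis that
   blurs transient "local features".
4. **model** — the gated recurrence (input/forget/output gates + candidate
   cell, no bias terms in the reference form), a dot-product softmax
   attention head pooling the hidden-state sequence, and a variant factory
   for the ablation ladder:

   | Variant | Components |
   |---------|-----------|
   | I   | LSTM on raw time windows |
   | II  | I + attention |
   | III | FFT magnitudes + autoencoder + LSTM |
   | IV  | III + attention |
   | V   | IV + conv refiner (full model) |

5. **training_eval** — minibatch Adam on MSE (lr 0.001, batch 60, 30
   epochs, dropout 0.2 on the context vector, optional auxiliary spectral
   reconstruction term), trial-level and chronological 80/20 split
   protocols, and the RMSE / R² / VAF metrics with mean ± std aggregation.
   Also BMI with the printed band classification.
6. **synthetic** — a gait-signal generator with a known delayed, mildly
   nonlinear mapping from activations and angles to moments, plus
   injectable band-limited high-frequency noise and spike artifacts, so
   the whole pipeline trains and evaluates with no external data.

Neural components run on a small built-in reverse-mode autodiff engine
(`gaitmoment.autodiff`, float64 numpy); no deep-learning framework is
required. Every trainable computation has a plain-numpy reference twin
(`lstm_step`, `attention`, `encode`/`decode`, `conv_refine`,
`forward_reference`) and the test suite checks the two routes against each
other.

### Interpretation note

For variants III–V the LSTM iterates over the **latent-feature axis**
(length `window_len/4`, channels as per-step features), so attention
weights frequency-derived steps and each window yields one prediction.
Variants I–II iterate over the raw time axis. The wiring between the
spectral stage, autoencoder, conv module and LSTM is an interpretation
choice; it is isolated in `MomentModel.forward_batch` /
`forward_reference`.

## CLI

```sh
gaitmoment simulate -c config.yaml            # write synthetic CSV fixtures
gaitmoment train    -c config.yaml            # train one variant, save checkpoint
gaitmoment evaluate -c config.yaml            # score the checkpoint, write report
gaitmoment ablate   -c config.yaml --seeds 1,2,3   # Models I–V comparison table
gaitmoment report   -r runs/out/report.json   # pretty-print a report
```

Minimal config:

```yaml
seed: 1
out_dir: runs/demo
model:
  variant: V
  hidden: 32
synthetic:
  duration_s: 12.0
  noise_sigma: 0.5
  spike_rate: 2.0
```

`--seed`, `--out` and `--variant` override file keys. Unknown keys are
rejected. Re-running `simulate` with the same config and seed produces
byte-identical CSVs.

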