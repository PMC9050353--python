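# tfrinfo

Which time-frequency representation (TFR) of a neural signal is *better*?
Resolution alone cannot answer this on real EEG/LFP data, where the true
time-frequency content is unknown and noise acts as a distractor.
`tfrinfo` implements an objective alternative: score a TFR by how much
information about the experimental condition it retains, measured as the
accuracy of classifiers trained on it, and then localize *which*
time-frequency components carry that information.

It is aimed at neurophysiologists comparing spectral estimators (and their
parameters) on trial-segmented single-channel EEG or LFP recordings, and
ships a seeded synthetic-data generator so the whole pipeline is testable
without recorded data.

## What it computes

1. **Four TFR estimators** on each trial `x(t)`:
   spectrogram (STFT, Blackman window, zero-padded DFT); Morlet continuous
   wavelet transform `CWT(t,f) = 2|(ψ_{f,c} ∗ x)(t)|²` with bandwidth
   `B_c = c/(5f)`; the superlet transform
   `SLT(t,f) = [∏_{i=1..o} CWT(t,f,c_i)]^{1/o}`, a geometric mean of
   wavelets of increasing cycle count that achieves joint super-resolution;
   and the Wigner-Ville distribution with its Choi-Williams
   reduced-interference variant (ambiguity-domain kernel
   `exp(−(θτ)²/σ)`).
2. **Standardized features**: every grid is resampled by bicubic
   interpolation to 1 ms × 0.5 Hz bins over a protocol-specific window,
   averaged over a tile grid, and linearized (e.g. 14 time × 25 frequency
   tiles → 350 features for the EEG geometry).
3. **Information content**: mean best-state validation accuracy of a
   from-scratch two-hidden-layer MLP (Soft++ activations, softmax output,
   dropout, full-batch iRPROP+ training) over repeated random 60/40
   splits and initializations, with chance level estimated by rerunning
   the identical protocol on shuffled labels.
4. **Importance maps**: correlated-feature permutation importance — each
   feature is co-permuted with its |Pearson r| > 0.5 neighborhood on the
   validation set and the mean increase in MSE (ΔMSE) and decrease in
   accuracy (−ΔPAcc) are mapped back onto the time-frequency tiles.
   Negative values flag distractor components.

## Worked example

Score two estimators on a synthetic receptive-field-mapping experiment
(8 stimulus directions × 10 trials; one gamma burst per trial whose
latency encodes the direction):

```python
from tfrinfo import ProtocolSpec, make_dataset
from tfrinfo.io import build_method_datasets, _mlp_config_for, _rprop_for
from tfrinfo.protocol import ProtocolConfig, compare_methods

signals, labels = make_dataset(ProtocolSpec.default("rf_like"), seed=0)
datasets = build_method_datasets(signals, labels, "rf_like", ["stft", "cwt"])
table = compare_methods(
    datasets,
    _mlp_config_for("rf_like", 600, 8, dropout_p=0.1),
    _rprop_for("rf_like", epochs=1000),
    ProtocolConfig(n_runs=5, base_seed=0),
)
print(table.to_string(index=False))
```

prints

```
method   labels  mean_accuracy  sem_accuracy  n_runs
  stft     true        1.00000      0.000000       5
  stft shuffled        0.12500      0.013975       5
   cwt     true        1.00000      0.000000       5
   cwt shuffled        0.13125      0.011693       5
```

Both estimators reach 100% on true labels — the planted bursts separate
the classes purely in time, so every representation suffices — while the
shuffled-label control sits at the 1/8 = 12.5% chance level, confirming
the protocol does not manufacture accuracy.  Differences between
estimators emerge on harder regimes: weak periodic bursts under broadband
click contamination (where the spectrogram's long windows beat the
transient-sensitive CWT), or the unbalanced two-class EEG-like design
(chance 60%), where sharper estimators localize an alpha-band (8–15 Hz)
effect in the importance maps.

The same pipeline is scriptable from the shell:

```
tfrinfo simulate --kind eeg_like --seed 1 --out trials.tsv
tfrinfo evaluate --trials trials.tsv --kind eeg_like --methods stft,slt --n-runs 20 --seed 1 --out report.tsv
tfrinfo pipeline --config run.yaml --out results/
```

## Acceptance script

`scripts/acceptance.py` recomputes the protocol's calibration quantities
from scratch — it synthesizes the balanced 8-class and the unbalanced
90/60 two-class datasets, builds wavelet feature vectors, runs the
shuffled-label repeated-split protocol (50 repetitions of split +
initialization + training each), and writes the mean best validation
accuracies (in percent) as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Both numbers estimate chance levels, so they should land near the
majority-class fractions of the two designs.

## Layout

- `src/tfrinfo/tfr.py` — the four estimators and grid containers
- `src/tfrinfo/synthetic.py` — seeded surrogate experiments (RF / SRCS / EEG-like)
- `src/tfrinfo/features.py` — standardization, tiling, normalization
- `src/tfrinfo/mlp.py` — Soft++ MLP and iRPROP+ trainer
- `src/tfrinfo/protocol.py` — repeated-split evaluation harness
- `src/tfrinfo/importance.py` — correlated-feature permutation importance
- `src/tfrinfo/io.py`, `cli.py` — file formats, run configuration, pipeline, CLI
- `docs/methods.md` — the model, parameters, and design choices in detail
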