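# sleephht

Sleep/wake classification of single-channel EEG from empirical mode
decomposition (EMD), Hilbert spectra, and a mixed-input neural network —
implemented end to end on numpy/scipy, with a synthetic EEG generator and an
EDF/EDF+ ingestion path for real recordings.

## The science

Sleep is scored in 30-second epochs of polysomnography. This package
classifies each epoch from one EEG channel (nominally Pz–Oz at 100 Hz) in two
steps:

1. **Decompose.** Empirical mode decomposition sifts the epoch into intrinsic
   mode functions (IMFs) — oscillatory components whose extrema and
   zero-crossing counts differ by at most one and whose local envelope mean is
   near zero — plus a near-monotone residue, such that the signal equals the
   sum of its IMFs and the residue.
2. **Represent and classify.** Two complementary representations are computed
   from the IMFs:
   - *Tabular:* 16 waveform statistics (moments, RMS, crest/shape/impulse/
     clearance factors, energy, power, range, …) for each of the first 4 IMFs
     → a 64-value feature vector.
   - *Image:* the Hilbert spectrum — instantaneous amplitude from the analytic
     signal of each IMF, accumulated along its instantaneous-frequency
     trajectory on a 64×64 time×frequency grid (0–50 Hz, log amplitude).

   A **mixed-input network** processes the image through a convolutional
   branch (3×3 convs of 16/32/64 filters, each with 2×2 max pooling, then
   fully connected 16→8) and the features through a dense branch (16→8),
   concatenates both (width 16), and classifies through a 4-node layer and a
   sigmoid unit (sleep/wake) or a 6-unit softmax (stages W/1/2/3/4/R). A
   CNN-only baseline reuses the image branch alone.

Wake is the positive class: accuracy, precision, recall and F1 are computed
from wake-positive TP/FP/TN/FN counts, one-vs-rest per class in the six-class
task. See `docs/methods.md` for assumptions, defaults, and limitations.

The package ships a seeded synthetic EEG generator (stage-dependent band
mixtures: alpha-dominant wake, delta-dominant deep sleep, spindle-band stage
2, …) so every stage of the chain can be exercised and verified without
protected recordings, plus EDF/EDF+ readers (via `mne`) and a fixture writer
for the Sleep-EDFx annotation dialect.

## Worked example

Decompose one synthetic wake epoch, inspect its modes, and featurize it:

```python
import numpy as np
from sleephht import (DEFAULT_STAGE_SPECS, decompose, featurize_epoch,
                      generate_epoch, hilbert_spectrum)

epoch = generate_epoch(DEFAULT_STAGE_SPECS["W"], seed=0)   # 30 s at 100 Hz
dec = decompose(epoch.samples)
print("IMFs:", dec.n_imfs, " reconstruction error:", dec.reconstruction_error())
for i, h in enumerate(dec.imfs[:4], 1):
    print(f"  IMF{i} RMS {np.sqrt(np.mean(h**2)):7.3f} uV")

features = featurize_epoch(dec, n_imfs_used=4)
fdict = dict(zip(features.feature_names, features.values))
print("feature vector:", features.values.shape)
print("IMF1 rms/crest:", round(fdict["imf1_rms"], 3),
      round(fdict["imf1_crest_factor"], 3))

image = hilbert_spectrum(dec)
row = np.argmax(image.pixels.sum(axis=1))
print("hottest frequency bin:", f"{row * 50/64:.1f}-{(row+1) * 50/64:.1f} Hz")
```

Output:

```text
IMFs: 8  reconstruction error: 3.5275295187933186e-16
  IMF1 RMS  11.589 uV
  IMF2 RMS  20.190 uV
  IMF3 RMS   4.343 uV
  IMF4 RMS   4.734 uV
feature vector: (64,)
IMF1 rms/crest: 11.589 5.286
hottest frequency bin: 10.2-10.9 Hz
```

The hottest band is the alpha band, as the wake recipe prescribes. Then train
and evaluate the full pipeline on a small synthetic sleep-vs-wake dataset from
the command line:

```bash
sleephht run --scheme binary --n-per-class 50 --epochs 30 --seed 7 --out runs/demo
```

```text
{
  "test_accuracy": 1.0,
  "n_test": 30,
  "report": "runs/demo/report.json"
}
```

`runs/demo/` now holds `report.json` (metrics, confusion matrix, training
history), `manifest.json` (seeds and stage checksums), loss/accuracy curves
and a confusion-matrix figure. The cached EMD features/images under the same
directory are reused by reruns with the same data configuration.

## Reproduction

All randomness derives from explicit seeds; identical configurations
reproduce identical reports.

```bash
# full test suite (the two end-to-end tests dominate; ~15-20 min on one CPU)
python -m pytest -q tests/

# recompute the headline quantities into a JSON summary (~6 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reports, among others: the EMD reconstruction error and
IMF validity rate on synthetic epochs, agreement of the 16 statistics with a
direct-summation oracle, Hilbert-spectrum tone localization, exact metric
identities, and test accuracy/precision/recall/F1 of the binary run (400
epochs per class, 100 training epochs) plus per-class F1 of a six-class run.

## Command-line interface

```text
sleephht run      # full pipeline (synthetic or EDF input, YAML-configurable)
sleephht prepare  # cut an EDF recording + hypnogram into labelled epochs
sleephht sweep    # training-epoch sweep of mixed vs CNN-only models
```

## Package layout

| module | contents |
| --- | --- |
| `sleephht.synthetic` | stage recipes, epoch/dataset generation, EDF+ fixture writer |
| `sleephht.ingest` | EDF channel/hypnogram reading, epoching, label merge, balancing |
| `sleephht.emd` | extrema, spline envelopes, sifting, IMF checks, decomposition |
| `sleephht.hht` | analytic signal, instantaneous frequency, spectrum images |
| `sleephht.features` | the 16 waveform statistics, per-epoch feature vectors |
| `sleephht.nn`, `sleephht.model` | numpy NN engine; mixed and CNN-only models, training |
| `sleephht.evaluate` | confusion matrices, metrics, sweeps, reports/figures |
| `sleephht.pipeline`, `sleephht.cli` | seeded end-to-end orchestration, caching, CLI |
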