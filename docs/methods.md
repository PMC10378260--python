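# Methods

This note records what the package computes, the assumptions behind it, the
default parameters, and the known limitations.

## Problem setting

Sleep scoring assigns one of six stage labels (wake W, non-REM stages 1–4,
REM R) to each 30-second epoch of a single-channel EEG recording sampled at
100 Hz. The package classifies epochs either binarily (sleep vs. wake, with
wake as the positive class) or into all six stages. Two representations are
computed per epoch from an empirical mode decomposition (EMD) of the raw
signal and fed to a two-branch neural network:

1. a **tabular vector** of 16 waveform statistics per intrinsic mode function
   (IMF), for the first 4 IMFs (64 values), and
2. a **Hilbert spectrum image**, a 64×64 time×frequency raster of
   instantaneous amplitude.

## Empirical mode decomposition

`sleephht.emd` implements classical envelope-mean sifting:

- Local maxima/minima are strict interior extrema; runs of equal samples
  (plateaus) collapse to their midpoint.
- Upper/lower envelopes are natural cubic splines through the extrema, with
  `boundary_extension = 2` extrema mirrored about each end to suppress spline
  end swings.
- One sifting pass subtracts the mean envelope. Sifting of a candidate stops
  when it satisfies both IMF conditions —
  (a) |#extrema − #zero-crossings| ≤ 1 and
  (b) envelope-mean RMS < `envelope_mean_tolerance` (default 0.05) × candidate
  RMS — or when the pointwise normalized squared difference between successive
  candidates falls below `sd_threshold` (default 0.2), or after
  `max_sift_iterations` (default 50) passes.
- Decomposition stops at `max_imfs` (default 10) or when the remainder has
  fewer than two maxima or two minima (a near-monotone residue); such
  degenerate remainders stay in the residue rather than being emitted as IMFs.

The identity `x = Σ IMF_i + residue` holds to machine precision by
construction, and is verified to < 1e−8 relative error in the tests.

## Hilbert spectrum

For each IMF, `scipy.signal.hilbert` gives the analytic signal; instantaneous
amplitude is its modulus and instantaneous frequency the (clipped-nonnegative)
central-difference derivative of the unwrapped phase, in Hz. Amplitude is
accumulated on a 64×64 grid spanning 0–50 Hz (the full band at 100 Hz
sampling) across the 30-s epoch; samples whose frequency leaves the band are
dropped. The grid is normalized to [0, 1]; the default `log` amplitude scale
applies a 1e−6 relative floor before taking log10, which lifts weak ridges
that a linear scale would render invisible to the convolutional branch.

## Statistical features

Per IMF, 16 statistics: minimum, maximum, mean, population standard deviation,
kurtosis (1/N, σ⁴ normalization, so a Gaussian is ≈3), skewness, RMS, crest
factor (peak/RMS), shape factor (RMS/mean|y|), impulse factor (peak/mean|y|),
clearance factor (peak/(mean √|y|)²), sample variance (N−1), energy Σy²,
power (1/N)Σy², peak-to-RMS, and range. "Peak" is max|y|. Constant or
all-zero inputs are flagged and the undefined ratios reported as 0. Missing
IMFs (when an epoch decomposes into fewer than `n_imfs_used`) are zero-padded
and flagged. Features are standardized with mean/scale fit on the training
split only.

## Classifier

The mixed model has two branches:

- **CNN branch** (image input, H×W×1): three 3×3 same-padding ReLU
  convolutions with 16, 32 and 64 filters, each followed by 2×2 max pooling
  (64×64 → 8×8), then flatten and fully connected layers of 16 and 8 nodes.
- **ANN branch** (tabular input): fully connected layers of 16 and 8 nodes.

Neither branch has a softmax. Their outputs concatenate to a width-16 vector,
pass through a 4-node fully connected layer, and a single sigmoid unit
(binary) or a 6-unit softmax (six-class) classifies. A CNN-only baseline
reuses the convolutional branch with the same head. Training uses mini-batch
Adam (learning rate 1e−3, batch 32) with binary/categorical cross-entropy for
100 epochs by default. The network is implemented directly on numpy
(im2col convolution, explicit backward passes, float32) so runs are
bit-reproducible from a single seed without a deep-learning framework.

Default data handling: 30% stratified test split; 15% of the remaining
training portion held out for validation; random under-sampling equalizes the
binary classes before splitting.

## Synthetic data generator

Each stage is a recipe of (center frequency Hz, bandwidth Hz, amplitude µV)
band components. An epoch is the sum of one sinusoid per component — frequency
drawn uniformly within the band, random phase, slow (0.05–0.3 Hz) random-depth
amplitude modulation — plus white Gaussian noise. Defaults emulate textbook
band structure at a posterior derivation: alpha-dominant wake, mixed
theta/alpha stage 1, spindle-band stage 2, delta-dominant stages 3–4,
mixed-frequency REM.

The generator deliberately does **not** emulate: 1/f background spectra,
transient graphoelements (K-complexes, vertex waves, discrete spindle
bursts), artifacts (ocular, muscle, electrode), inter-subject variability, or
stage transitions within an epoch. Consequently the synthetic two-class task
(wake vs. stage 3) is much easier than real recordings — the end-to-end run
below reaches test accuracy 1.0 — so synthetic accuracies must not be read as
expected performance on real polysomnography.

## Problem sizes and numerical choices

- End-to-end verification runs use 400 epochs per class (binary, 100 training
  epochs) and 60 epochs per stage (six-class, 30 training epochs); both sizes
  were chosen to exercise the full chain in minutes on one CPU.
- The logged mixed-vs-CNN-only comparison uses 5 seeds at 15 training epochs,
  a budget-driven reduction; at the sizes above the two variants are
  indistinguishable because both saturate the synthetic task.
- EMD splines use not-a-knot boundary conditions with ≥4 knots, natural at 3,
  linear interpolation at 2; plateau extrema round down to the midpoint.
- Instantaneous frequency is clipped at 0 Hz; negative excursions occur only
  near epoch edges where the analytic signal is unreliable.
- One global seed fans out via `numpy.random.SeedSequence` to per-stage seeds
  (data, balancing, splitting, training), so a whole run is reproduced by a
  single integer.

## Limitations

- EMD splits near-Nyquist tones (> ~35 Hz at fs = 100 Hz) into spurious
  modes; spectral content that high is therefore localized reliably only when
  it reaches the spectrum stage as a clean mode.
- The numpy training loop is single-threaded and far slower than a GPU
  framework; default sizes reflect that.
- Real-EDF ingestion is implemented and tested against files written by the
  package's own EDF+ writer; it has not been validated against the full
  variety of vendor EDF dialects.
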