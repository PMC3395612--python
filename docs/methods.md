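# Methods

## Model and inference

Each whitened spectrogram patch `x ∈ R^k` is modelled as a sparse linear
combination of unit-norm dictionary atoms, `x ≈ Φa`.  The coefficients are
inferred by integrating the locally competitive algorithm (LCA) from
`u(0) = 0` with forward Euler:

```
u ← u + (dt/τ)·[Φᵀx − u − (ΦᵀΦ − I)·a],     a = T_λ(u)
```

`T_λ` is ideal soft thresholding (`sign(u)·max(|u|−λ, 0)`) in L1 mode or
ideal hard thresholding (`u` where `|u| > λ`, else 0; ties stay inactive) in
L0 mode.  Coefficients are signed in both modes.  The Gram kernel
`ΦᵀΦ − I` is computed once per dictionary; inference never mutates the
dictionary.

**Threshold–penalty correspondence.**  The package's energy is
`E(a) = ‖x − Φa‖² + λ·S(a)`.  With this scaling (no ½ on the quadratic
term), soft-threshold LCA at level λ descends `‖r‖² + 2λ‖a‖₁`, and ideal
hard thresholding at level λ targets `‖r‖² + λ²‖a‖₀` (for an orthonormal
dictionary, activating a unit is optimal exactly when `|Φᵀx|_i > λ`, i.e. a
per-atom price of λ²).  `LcaConfig.energy_lam` exposes the targeted penalty
weight; all energy-based comparisons (descent checks, exhaustive-search
oracles, `SparseCode.final_energy`) use it, so the dynamics and the
objective they are scored on always agree.

**Numerics.**  Defaults: `dt/τ = 0.1`, 400 steps, early stop when
`max|Δu| < 1e-6`.  `dt/τ` is validated against the stability bound
`dt/τ ≤ 1`; a non-finite state raises an error naming the ratio.  For hard
sparseness we recommend (and use in the reference studies) threshold
annealing: the threshold starts at `anneal_factor·λ` (default 10×) and
decays geometrically to λ over the first part of the run before convergence
is checked.  Annealing mimics a homotopy continuation in λ — strong atoms
activate first and suppress correlated competitors — and substantially
improves hard-threshold fixed points: on the coherent two-atom oracle
instances below, the match rate against exhaustive search is ≈ 0.9+ with
annealing versus ≈ 0.7 without.  It is off by default for plain inference.

**λ selection.**  λ is fixed per run.  `calibrate_lambda` bisects (in log λ,
using the monotone mean active fraction) to a target population sparseness;
the reference studies pick λ so the inferred active fraction is near the
generative sparsity (planted data) or in the 5–25% range (speech-like data).

## Learning

Stochastic gradient descent on the energy plus an orthogonality prior
`(γ/2)‖ΦᵀΦ − I‖_F²` (gradient `γ·Φ(ΦᵀΦ − I)`), which pressures atoms to be
unique.  Per mini-batch (default 100 patches) the reconstruction gradient
`(x − Φa)aᵀ` is averaged over the batch — the batch size is thereby folded
out of the learning rate — the update is applied once, and every column is
renormalized to unit length.  An element inactive for a full epoch is
re-initialized from a random (normalized) training patch and counted in the
log.  The same `LcaConfig` is used during learning and evaluation.  Exactly
duplicated columns are a symmetric fixed point of the orthogonality gradient
(both shrink along their common direction and renormalization restores
them); any perturbation off exact parallelism decorrelates them, which is
the regime the tests exercise.

## Front end

Waveforms (16 kHz; other rates are polyphase-resampled) are framed with a
16 ms Hann window.  The default hop is 25/3 ms — realized by rounding each
frame start to the nearest sample — so 25 frames span exactly 216 ms; a
plain 8 ms hop is a config switch.  Per-frame power spectra are linearly
interpolated in log-frequency onto 256 log-spaced channels between 100 and
4000 Hz, floored at 1e-10 of the maximum power, and expressed in dB.
Patches cover all channels and 25 consecutive frames (6400 values,
frequency-major); the training-set hop is 12 frames (~50% overlap).  Edge
patches are dropped, not padded.

PCA (scikit-learn) on mean-centered patches retains 200 components
(reduced, with a warning, when the data are rank deficient); whitening
divides each score by the square root of its eigenvalue so the fitting set
has unit component variance.  A reduce-only variant (no variance
equalization) is a flag.  `inverse_transform` re-adds the mean;
`dewhiten_elements` maps dictionary atoms to spectrogram space *without*
the mean, since an atom is a deviation from the zero-coefficient baseline.

## Dictionary characterization

* **Usage** — an element is "used" by a stimulus when its coefficient is
  nonzero at convergence; no residual-accuracy gate is added (a gate would
  introduce an arbitrary extra threshold).  Display order sorts ascending by
  count, ties by element index (deterministic).
* **Display normalization** — images scaled to max |value| = 1; a
  negatively skewed image is sign-flipped so displayed polarity matches how
  the element is used.
* **Modulation power spectra** — mean-removed 2-D DFT magnitude squared;
  spectral modulation in cycles/octave (valid because channels are
  log-spaced), temporal in cycles/s.  Both the peak bin and the
  power-weighted centroid are computed over the half-plane with spectral
  modulation ≥ 0, folding temporal modulation to magnitudes; centroids are
  the default summary for tradeoff plots.  The signed spectrum remains
  accessible via the raw DFT if up/down sweep asymmetry is of interest.
* **Separability** — `σ₁²/Σσᵢ²` from the SVD of the STRF image; 1 means an
  exact product of a time profile and a frequency profile.
* **SNR–sparseness curves** — for each λ in a grid, mean active fraction
  and mean reconstruction SNR `10·log10(‖x‖²/‖x − Φa‖²)` (capped at 300 dB
  for numerically exact reconstructions).

## Synthetic data

*Planted problems* draw a Gaussian unit-norm dictionary, uniform random
supports of size `k_active`, Laplacian (unit-scale, sign-symmetric)
amplitudes, and additive Gaussian noise — exactly the generative model the
coder assumes, so recovery is measurable against ground truth.

*Speech-like audio* sums harmonic partials `k·f0(t)` of a fundamental that
drifts as an Ornstein–Uhlenbeck walk clipped to `f0_range` (default
100–300 Hz, correlation time 0.5 s), with amplitudes shaped by Gaussian
bumps in log-frequency whose centers drift linearly (formant-like
converging/diverging envelope peaks, defaults near 500/1500/2500 Hz), a
1/k source roll-off, Poisson on/off gating with 4 ms raised-cosine edges
(abrupt broadband onsets/terminations and silence gaps, default 3 events/s),
and a white-noise floor specified in dB relative to the unit-RMS harmonic
component (default −50 dB; the source corpora's SNR and level normalization
are not standardized, so both are exposed as parameters).  All randomness
flows from one integer seed through a named generator.

What this emulates: the coarse second-order structure sparse coding feeds
on — harmonicity, slowly varying spectral envelopes, and transients.  What
it does not: phonetics, prosody, speaker variability, multiple voices,
reverberation, or recording-channel effects.  Tests passing on this corpus
show the pipeline recovers the structure the generator plants; they do not
certify the specific receptive-field taxonomy real speech would produce.

## Reference study sizes

Chosen so the whole suite runs in minutes on one CPU:

* Front-end arithmetic: one 40 s utterance at full scale (256 channels,
  200 components).
* L0 oracle equivalence: 100 instances, 6 features, 4–8 atoms, 2 active,
  noise σ = 0.01; annealed hard-threshold inference at λ = 0.5 (per-atom
  price λ² = 0.25, between the noise floor and a typical unit-scale atom);
  scored against support enumeration with least squares per support.
* L1 closed form: 20 orthonormal 16-dim dictionaries.
* Planted recovery: k = 32 features, 64 atoms (2× overcomplete), 3 active,
  20 dB SNR, 3000 samples, L1 λ = 0.4, η = 0.5, 40 epochs.  λ is set so
  the inferred active fraction matches the planted sparsity (~5%); weaker
  thresholds learn mixtures of atoms.
* Energy descent: 20 random coherent instances (inference) and a complete
  24-dim planted configuration with a 400-sample held-out set (training).
* Overcompleteness/SNR and modulation-tradeoff studies: a 6 × 15 s
  speech-like corpus, 64 channels, 64 retained components; dictionaries of
  32 (half), 256 (4×), and 128 (2×, tradeoff) elements.  The SNR comparison
  matches mean active fractions via `calibrate_lambda` before comparing; the
  tradeoff study trains soft-sparse dictionaries (12 epochs) and reports the
  Spearman correlation between temporal and spectral modulation centroids.

## Known limitations

* Hard-threshold LCA is a heuristic for the L0 objective: ~5–10% of
  coherent small instances settle in support-selection local minima even
  with annealing.
* The energy-descent guarantee is empirical for the discrete Euler scheme;
  the monotonicity test allows 1e-9 per-step slack.
* The modulation tradeoff is tested as a sign/significance trend, not
  against any particular coordinates: its effect size depends on corpus
  composition (onset rate vs. harmonic content).
* Cochleogram-style front ends (auditory filter banks) and shift-invariant
  (convolutional) sparse coding are out of scope.
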