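"""Synthetic inputs: planted sparse-coding problems and speech-like audio.

Two generators back the test and demonstration pipelines:

* :func:`make_planted_problem` draws a random unit-norm dictionary and sparse
  coefficient vectors and emits noisy observations ``X = phi @ codes + eps`` —
  the exact linear generative model the sparse coder assumes, so recovery can
  be checked against ground truth.

* :func:`make_speech_like_waveform` synthesizes audio with the coarse
  statistical structure of speech that the analysis relies on: a harmonic
  stack riding on a slowly drifting fundamental (Ornstein–Uhlenbeck pitch
  track), formant-like spectral-envelope peaks whose centers drift linearly
  (converging/diverging subfields), abrupt broadband onsets/terminations from
  a gating process, silence gaps, and an additive Gaussian noise floor.  It
  is not a speech synthesizer: no phonemes, no prosody, one "speaker" at a
  time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlantedProblem",
    "SpeechLikeParams",
    "make_planted_problem",
    "make_speech_like_waveform",
    "SAMPLE_RATE",
]

SAMPLE_RATE = 16_000  # Hz; all waveforms are generated at this rate


@dataclass
class PlantedProblem:
    """A sparse linear generative problem with known ground truth.

    ``observations = true_dictionary @ codes + noise`` with unit-norm
    dictionary columns and at most ``k_active`` nonzeros per code column.
    """

    true_dictionary: np.ndarray  # (n_features, n_elements)
    codes: np.ndarray  # (n_elements, n_samples)
    observations: np.ndarray  # (n_features, n_samples)
    noise_sigma: float
    seed: int

    @property
    def n_features(self) -> int:
        return self.true_dictionary.shape[0]

    @property
    def n_elements(self) -> int:
        return self.true_dictionary.shape[1]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]


def random_dictionary(n_features: int, n_elements: int, rng) -> np.ndarray:
    """I.i.d. Gaussian columns normalized to unit Euclidean length."""
    phi = rng.standard_normal((n_features, n_elements))
    norms = np.linalg.norm(phi, axis=0)
    # a zero column has probability zero; guard anyway
    norms[norms == 0] = 1.0
    return phi / norms


def make_planted_problem(
    n_features: int,
    n_elements: int,
    n_samples: int,
    k_active: int,
    noise_sigma: float,
    seed: int,
    amplitude_scale: float = 1.0,
) -> PlantedProblem:
    """Draw a planted dictionary-recovery problem.

    Nonzero code amplitudes are Laplacian with scale ``amplitude_scale``
    (sign-symmetric, matching the sparse prior of the model); the active set
    of each sample is a uniform random subset of ``k_active`` elements.
    Deterministic given ``seed``.
    """
    if n_features < 1 or n_elements < 1 or n_samples < 1:
        raise ValueError("n_features, n_elements and n_samples must be >= 1")
    if not 0 <= k_active <= n_elements:
        raise ValueError(f"k_active must lie in [0, {n_elements}] (got {k_active})")
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0 (got {noise_sigma})")
    rng = np.random.default_rng(seed)
    phi = random_dictionary(n_features, n_elements, rng)
    codes = np.zeros((n_elements, n_samples))
    for j in range(n_samples):
        support = rng.choice(n_elements, size=k_active, replace=False)
        codes[support, j] = rng.laplace(0.0, amplitude_scale, size=k_active)
    obs = phi @ codes
    if noise_sigma > 0:
        obs = obs + noise_sigma * rng.standard_normal(obs.shape)
    return PlantedProblem(
        true_dictionary=phi,
        codes=codes,
        observations=obs,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )


@dataclass
class SpeechLikeParams:
    """Parameters of the speech-like waveform generator.

    f0_range : (lo, hi) in Hz, within [80, 400]; the fundamental drifts inside
        this range as a clipped Ornstein–Uhlenbeck walk (lo == hi pins it).
    n_harmonics : number of partials k * f0 (partials above Nyquist are muted).
    formant_tracks : list of (center_hz, bandwidth_hz, drift_hz_per_s) Gaussian
        bumps (in log-frequency) multiplying the harmonic amplitudes; centers
        move linearly at the stated drift.
    onset_rate : Poisson rate (events/s) of abrupt on/off gating transitions;
        0 leaves the source on for the whole duration.
    noise_floor_db : additive white-noise level in dB relative to the
        unit-RMS harmonic component; ``-inf`` disables noise.
    duration_s : total duration; must exceed one analysis patch (216 ms).
    """

    f0_range: tuple[float, float] = (100.0, 300.0)
    n_harmonics: int = 30
    formant_tracks: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (500.0, 120.0, -300.0),
            (1500.0, 200.0, 500.0),
            (2500.0, 250.0, -400.0),
        ]
    )
    onset_rate: float = 3.0
    noise_floor_db: float = -50.0
    duration_s: float = 10.0
    seed: int = 0

    def problems(self) -> list[str]:
        out = []
        lo, hi = self.f0_range
        if not (80.0 <= lo <= hi <= 400.0):
            out.append(f"f0_range must satisfy 80 <= lo <= hi <= 400 Hz (got {self.f0_range})")
        if self.n_harmonics < 1:
            out.append("n_harmonics must be >= 1")
        if self.onset_rate < 0:
            out.append("onset_rate must be >= 0")
        if self.duration_s <= 0.216:
            out.append(
                f"duration_s = {self.duration_s} s is shorter than one 216 ms patch"
            )
        return out


def _ou_track(n: int, lo: float, hi: float, rng, corr_time_s: float = 0.5) -> np.ndarray:
    """Ornstein–Uhlenbeck walk clipped to [lo, hi], sampled at SAMPLE_RATE."""
    if hi == lo:
        return np.full(n, lo)
    mu = 0.5 * (lo + hi)
    sd = (hi - lo) / 6.0  # stationary spread keeps clipping rare
    dt = 1.0 / SAMPLE_RATE
    alpha = dt / corr_time_s
    sigma_step = sd * np.sqrt(2.0 * alpha)
    # AR(1) recursion x[i] = (1-alpha) x[i-1] + alpha*mu + noise, run as an IIR filter
    from scipy.signal import lfilter

    x0 = rng.uniform(lo, hi)
    drive = alpha * mu + sigma_step * rng.standard_normal(n)
    drive[0] = x0
    x = lfilter([1.0], [1.0, -(1.0 - alpha)], drive)
    return np.clip(x, lo, hi)


def _gate(n: int, rate: float, rng, ramp_s: float = 0.004) -> np.ndarray:
    """On/off gating with abrupt (short raised-cosine) transitions."""
    gate = np.ones(n)
    if rate <= 0:
        return gate
    t_total = n / SAMPLE_RATE
    n_events = rng.poisson(rate * t_total)
    times = np.sort(rng.uniform(0.0, t_total, size=n_events))
    state = True
    ramp = int(ramp_s * SAMPLE_RATE)
    edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))  # 0 -> 1
    prev = 0
    for t in times:
        idx = int(t * SAMPLE_RATE)
        gate[prev:idx] = 1.0 if state else 0.0
        state = not state
        prev = idx
    gate[prev:] = 1.0 if state else 0.0
    # smooth each transition
    flips = np.flatnonzero(np.diff(gate) != 0)
    for f in flips:
        lo_i, hi_i = f + 1, min(f + 1 + ramp, n)
        seg = edge[: hi_i - lo_i]
        if gate[f + 1] > gate[f]:
            gate[lo_i:hi_i] = seg
        else:
            gate[lo_i:hi_i] = 1.0 - seg
    return gate


def _formant_envelope(freqs_hz: np.ndarray, t_s: np.ndarray, tracks) -> np.ndarray:
    """Spectral envelope: Gaussian bumps in log2-frequency with drifting centers.

    ``freqs_hz`` and ``t_s`` are broadcast elementwise (e.g. the instantaneous
    frequency of one partial sampled at control times).
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    env = np.full(np.broadcast_shapes(freqs_hz.shape, np.shape(t_s)), 0.05)
    logf = np.log2(np.maximum(freqs_hz, 1e-6))
    for center, bw, drift in tracks:
        c = np.maximum(center + drift * np.asarray(t_s, dtype=float), 50.0)
        bw_oct = np.maximum(bw / (c * np.log(2.0)), 1e-3)
        env = env + np.exp(-0.5 * ((logf - np.log2(c)) / bw_oct) ** 2)
    return env


def make_speech_like_waveform(params: SpeechLikeParams) -> np.ndarray:
    """Synthesize a speech-like waveform at 16 kHz (see module docstring).

    The harmonic component is normalized to unit RMS (over its gated-on
    portion) before the noise floor is added, so ``noise_floor_db`` reads as
    an SNR in dB.  Bit-identical across calls with the same params/seed.
    """
    probs = params.problems()
    if probs:
        raise ValueError("; ".join(probs))
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * SAMPLE_RATE))
    f0 = _ou_track(n, params.f0_range[0], params.f0_range[1], rng)
    phase = 2.0 * np.pi * np.cumsum(f0) / SAMPLE_RATE

    # amplitude envelopes evaluated at a 100 Hz control rate, then interpolated
    ctrl_t = np.arange(0.0, params.duration_s, 0.01)
    ctrl_idx = np.minimum((ctrl_t * SAMPLE_RATE).astype(int), n - 1)
    t_samples = np.arange(n) / SAMPLE_RATE
    wave = np.zeros(n)
    harmonics = np.arange(1, params.n_harmonics + 1)
    nyq_margin = 0.95 * SAMPLE_RATE / 2.0
    for k in harmonics:
        fk_ctrl = k * f0[ctrl_idx]
        if params.formant_tracks:
            amp_ctrl = _formant_envelope(fk_ctrl, ctrl_t, params.formant_tracks)
        else:
            amp_ctrl = np.ones_like(fk_ctrl)
        amp_ctrl = amp_ctrl / k  # source roll-off
        amp_ctrl[fk_ctrl > nyq_margin] = 0.0
        amp = np.interp(t_samples, ctrl_t, amp_ctrl)
        wave += amp * np.sin(k * phase)

    gate = _gate(n, params.onset_rate, rng)
    wave *= gate
    on = gate > 0.5
    rms = np.sqrt(np.mean(wave[on] ** 2)) if on.any() else 0.0
    if rms > 0:
        wave /= rms
    if np.isfinite(params.noise_floor_db):
        sigma = 10.0 ** (params.noise_floor_db / 20.0)
        wave = wave + sigma * rng.standard_normal(n)
    return wave
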