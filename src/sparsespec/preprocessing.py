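"""Waveform → log-power spectrogram → patches → PCA-whitened vectors.

The front end mirrors a conventional auditory-modelling pipeline: short-time
power spectra on a Hann window, resampled onto a logarithmically spaced
frequency grid (default 256 channels, 100–4000 Hz), log-compressed, cut into
overlapping fixed-duration patches spanning all frequencies (default 25
frames ≈ 216 ms, flattened frequency-major to 6400 values), and projected
onto the leading principal components (default 200) with per-component
variance equalization.  :class:`PatchWhitener` is a scikit-learn transformer;
``inverse_transform`` maps whitened vectors (e.g. learned dictionary
elements) back into spectrogram-patch space for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window, resample_poly
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "Spectrogram",
    "PatchSet",
    "compute_spectrogram",
    "segment_patches",
    "PatchWhitener",
    "fit_whitening",
    "whiten",
    "dewhiten",
    "strf_images",
]

TARGET_RATE = 16_000


@dataclass
class Spectrogram:
    """Log-power time–frequency array on a log-spaced frequency grid."""

    values: np.ndarray  # (n_freq, n_frames), dB
    freqs_hz: np.ndarray  # ascending, constant ratio
    frame_times_s: np.ndarray  # frame centers, ascending

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class PatchSet:
    """Flattened spectrogram patches (one row per patch, frequency-major)."""

    patches: np.ndarray  # (n_patches, n_freq * n_frames_per_patch)
    n_freq: int
    n_frames_per_patch: int
    patch_duration_ms: float

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_dim(self) -> int:
        return self.n_freq * self.n_frames_per_patch


def _frame_starts(n_samples: int, win: int, hop_samples: float) -> np.ndarray:
    """Frame start indices for a possibly fractional hop (rounded per frame)."""
    n_frames = int(np.floor((n_samples - win) / hop_samples)) + 1
    starts = np.round(np.arange(n_frames) * hop_samples).astype(int)
    return starts[starts + win <= n_samples]


def compute_spectrogram(
    waveform,
    sample_rate: int = TARGET_RATE,
    n_freq: int = 256,
    fmin_hz: float = 100.0,
    fmax_hz: float = 4000.0,
    window_ms: float = 16.0,
    hop_ms: float = 25.0 / 3.0,
    log_floor_ratio: float = 1e-10,
) -> Spectrogram:
    """Log-power spectrogram on ``n_freq`` log-spaced channels.

    Hann-windowed frames of ``window_ms`` are Fourier transformed, the power
    spectrum is linearly interpolated (in log-frequency) onto the log-spaced
    grid, floored at ``log_floor_ratio`` times the maximum power, and
    expressed in dB.  The default hop of 25/3 ms makes 25 frames span exactly
    216 ms (window + 24 hops); pass ``hop_ms=8.0`` for a plain 8 ms hop.
    Waveforms at other sample rates are resampled to 16 kHz first.
    """
    waveform = np.asarray(waveform, dtype=float).ravel()
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if sample_rate != TARGET_RATE:
        from fractions import Fraction

        frac = Fraction(TARGET_RATE, int(sample_rate)).limit_denominator(1000)
        waveform = resample_poly(waveform, frac.numerator, frac.denominator)
        sample_rate = TARGET_RATE
    nyquist = sample_rate / 2.0
    if not 0 < fmin_hz < fmax_hz:
        raise ValueError("need 0 < fmin_hz < fmax_hz")
    if fmax_hz > nyquist:
        raise ValueError(f"fmax_hz = {fmax_hz} exceeds the Nyquist frequency {nyquist}")
    win = int(round(window_ms * 1e-3 * sample_rate))
    if waveform.size < win:
        raise ValueError(
            f"waveform ({waveform.size} samples) is shorter than one {win}-sample window"
        )
    hop_samples = hop_ms * 1e-3 * sample_rate
    starts = _frame_starts(waveform.size, win, hop_samples)
    window = get_window("hann", win, fftbins=True)
    frames = np.stack([waveform[s : s + win] for s in starts])
    power = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2  # (n_frames, win//2+1)
    lin_freqs = np.fft.rfftfreq(win, d=1.0 / sample_rate)
    log_freqs = np.geomspace(fmin_hz, fmax_hz, n_freq)
    # interpolate power linearly in log-frequency onto the log-spaced grid
    interp = np.empty((len(starts), n_freq))
    log_lin = np.log(np.maximum(lin_freqs, lin_freqs[1] * 1e-3))
    for i in range(len(starts)):
        interp[i] = np.interp(np.log(log_freqs), log_lin, power[i])
    ref = interp.max()
    if ref <= 0:
        ref = 1.0
    floored = np.maximum(interp, log_floor_ratio * ref)
    values = 10.0 * np.log10(floored).T  # (n_freq, n_frames)
    frame_times = (starts + win / 2.0) / sample_rate
    return Spectrogram(values=values, freqs_hz=log_freqs, frame_times_s=frame_times)


def check_log_spaced(freqs_hz: np.ndarray, rtol: float = 1e-6) -> float:
    """Validate constant-ratio spacing; return the channel spacing in octaves."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.ndim != 1 or freqs_hz.size < 2 or np.any(np.diff(freqs_hz) <= 0):
        raise ValueError("frequency axis must be 1-D, ascending, length >= 2")
    ratios = freqs_hz[1:] / freqs_hz[:-1]
    if not np.allclose(ratios, ratios[0], rtol=rtol):
        raise ValueError("frequency axis is not logarithmically spaced")
    return float(np.log2(ratios[0]))


def segment_patches(
    spec: Spectrogram,
    n_frames_per_patch: int = 25,
    patch_hop_frames: int = 12,
) -> PatchSet:
    """Cut overlapping fixed-duration patches spanning all frequencies.

    Each patch is a contiguous block of ``n_frames_per_patch`` frames covering
    every channel, flattened frequency-major (channel index varies slowest).
    Patches that would run past the end are dropped.  A spectrogram shorter
    than one patch yields an empty set with a warning.
    """
    values = spec.values
    n_freq, n_frames = values.shape
    if n_frames < n_frames_per_patch:
        warnings.warn(
            f"spectrogram has {n_frames} frames < patch length {n_frames_per_patch}; "
            "returning an empty patch set",
            stacklevel=2,
        )
        patches = np.empty((0, n_freq * n_frames_per_patch))
    else:
        starts = range(0, n_frames - n_frames_per_patch + 1, patch_hop_frames)
        patches = np.stack(
            [values[:, s : s + n_frames_per_patch].ravel() for s in starts]
        )
    if spec.frame_times_s.size > 1:
        frame_step_s = float(np.mean(np.diff(spec.frame_times_s)))
    else:
        frame_step_s = 0.0
    duration_ms = 1e3 * (
        frame_step_s * (n_frames_per_patch - 1) + 0.016
    )  # hop span + one window
    return PatchSet(
        patches=patches,
        n_freq=n_freq,
        n_frames_per_patch=n_frames_per_patch,
        patch_duration_ms=duration_ms,
    )


class PatchWhitener(TransformerMixin, BaseEstimator):
    """PCA dimensionality reduction with optional variance equalization.

    Fits a PCA on mean-centered patches and keeps ``n_components``
    (reduced to the effective rank, with a warning, when the data are rank
    deficient).  ``transform`` projects onto the retained basis and — when
    ``whiten=True`` — divides each component score by the square root of its
    eigenvalue, so the fitted training set has unit variance per component.
    ``inverse_transform`` undoes both steps and re-adds the mean, i.e. it
    returns the projection of the input onto the retained subspace.

    Attributes
    ----------
    mean_ : ndarray (n_features,)
    components_ : ndarray (k, n_features), orthonormal rows
    explained_variance_ : ndarray (k,), descending
    variance_fraction_ : float, retained / total variance
    n_components_ : int, retained components after rank reduction
    """

    def __init__(self, n_components: int = 200, whiten: bool = True):
        self.n_components = n_components
        self.whiten = whiten

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n_samples, n_features = X.shape
        k = int(self.n_components)
        if n_samples <= k:
            raise ValueError(
                f"need more than n_components={k} patches to fit (got {n_samples})"
            )
        k = min(k, n_features)
        pca = PCA(n_components=k, svd_solver="auto", random_state=0)
        pca.fit(X)
        ev = pca.explained_variance_
        rank = int(np.sum(ev > max(ev[0], 1e-300) * 1e-12))
        if rank < k:
            warnings.warn(
                f"patch set has rank {rank} < requested {k} components; reducing",
                stacklevel=2,
            )
            k = rank
        self.mean_ = pca.mean_
        self.components_ = pca.components_[:k]
        self.explained_variance_ = ev[:k]
        self.variance_fraction_ = float(np.sum(pca.explained_variance_ratio_[:k]))
        self.n_components_ = k
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.mean_.size:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.mean_.size}"
            )
        scores = (X - self.mean_) @ self.components_.T
        if self.whiten:
            scores = scores / np.sqrt(self.explained_variance_)
        return scores

    def inverse_transform(self, V):
        check_is_fitted(self, "components_")
        V = check_array(V, dtype=float)
        if V.shape[1] != self.n_components_:
            raise ValueError(
                f"V has {V.shape[1]} components, model has {self.n_components_}"
            )
        if self.whiten:
            V = V * np.sqrt(self.explained_variance_)
        return V @ self.components_ + self.mean_

    def dewhiten_elements(self, phi):
        """Map dictionary elements (columns of ``phi``) back to patch space.

        Unlike :meth:`inverse_transform`, the patch mean is *not* re-added:
        a dictionary element is a deviation a stimulus adds on top of the
        zero-coefficient baseline, so its display image should not carry the
        mean spectrum.
        """
        check_is_fitted(self, "components_")
        phi = np.asarray(phi, dtype=float)
        V = phi.T
        if self.whiten:
            V = V * np.sqrt(self.explained_variance_)
        return (V @ self.components_).T  # (n_features_patch, n_elements)


def fit_whitening(patches: PatchSet | np.ndarray, k: int = 200, whiten: bool = True) -> PatchWhitener:
    """Fit a :class:`PatchWhitener` on a patch set (functional wrapper)."""
    X = patches.patches if isinstance(patches, PatchSet) else patches
    return PatchWhitener(n_components=k, whiten=whiten).fit(X)


def whiten(model: PatchWhitener, patches) -> np.ndarray:
    X = patches.patches if isinstance(patches, PatchSet) else patches
    return model.transform(X)


def dewhiten(model: PatchWhitener, vectors) -> np.ndarray:
    return model.inverse_transform(vectors)


def strf_images(model: PatchWhitener, phi, n_freq: int) -> np.ndarray:
    """Dewhiten dictionary columns into (n_elements, n_freq, n_frames) images."""
    flat = model.dewhiten_elements(phi).T  # (n_elements, patch_dim)
    n_elements, patch_dim = flat.shape
    if patch_dim % n_freq:
        raise ValueError(f"patch dim {patch_dim} not divisible by n_freq {n_freq}")
    return flat.reshape(n_elements, n_freq, patch_dim // n_freq)
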