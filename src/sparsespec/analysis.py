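"""Characterization of learned dictionaries.

Usage profiles (how many stimuli recruit each element during inference, and
the ascending-usage display ordering), display normalization of
spectrotemporal receptive-field (STRF) images (scale to ±1; flip sign when
the pixel skewness is negative, reflecting that coefficients may be used
with either sign), modulation power spectra (2-D Fourier magnitude of an
STRF, temporal axis in cycles/s and spectral axis in cycles/octave, peak and
power-weighted centroid), time–frequency separability (dominance of the
leading singular value), and reconstruction-SNR vs. sparseness curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lca import LcaConfig, gram_matrix, lca_infer_batch, reconstruct, snr_db
from .preprocessing import check_log_spaced

__all__ = [
    "UsageProfile",
    "ModulationSummary",
    "usage_profile",
    "display_normalize",
    "modulation_spectrum",
    "separability_index",
    "snr_sparsity_curve",
]


@dataclass
class UsageProfile:
    """Per-element stimulus counts and the ascending-usage ordering."""

    counts: np.ndarray  # (n_elements,), nonnegative ints
    order: np.ndarray  # permutation sorting elements by ascending usage
    n_stimuli: int


@dataclass
class ModulationSummary:
    """Peak and centroid of an STRF's modulation power spectrum.

    Temporal modulation in cycles/s (magnitudes), spectral modulation in
    cycles/octave (non-negative half-plane).  ``zero_power`` flags a constant
    image whose mean-removed spectrum vanishes.
    """

    temporal_peak: float
    spectral_peak: float
    temporal_centroid: float
    spectral_centroid: float
    zero_power: bool = False


def usage_profile(phi, patches, lca_config: LcaConfig) -> UsageProfile:
    """Count, per element, the stimuli with a nonzero coefficient at inference.

    "Used" means the element participates in the reconstruction (``a_i != 0``
    at LCA convergence).  ``order`` sorts ascending by count with ties broken
    by element index, so reruns with the same inputs reproduce it exactly.
    """
    X = np.atleast_2d(np.asarray(patches, dtype=float))
    A, _ = lca_infer_batch(X, phi, lca_config)
    counts = np.count_nonzero(A, axis=0)
    order = np.lexsort((np.arange(counts.size), counts))
    return UsageProfile(counts=counts, order=order, n_stimuli=X.shape[0])


def display_normalize(strf_image: np.ndarray) -> np.ndarray:
    """Normalize an STRF image for display: max |value| = 1, skewness >= 0.

    A negatively skewed image is sign-flipped (the element is evidently used
    with negative coefficients), so the displayed polarity matches how the
    element acts during encoding.  A constant image is returned unchanged.
    """
    img = np.asarray(strf_image, dtype=float)
    peak = np.max(np.abs(img))
    if peak == 0 or np.ptp(img) == 0:
        return img.copy()
    out = img / peak
    if stats.skew(out.ravel()) < 0:
        out = -out
    return out


def modulation_spectrum(strf_image, freqs_hz, frame_times_s) -> ModulationSummary:
    """Modulation power spectrum summary of one STRF image.

    The mean is removed (so the DC bin does not dominate), the 2-D DFT
    magnitude-squared is formed, and the peak location and power-weighted
    centroid are reported over the half-plane with spectral modulation >= 0,
    using the magnitude of the temporal modulation.  Requires a log-spaced
    frequency axis so "cycles/octave" is well defined.
    """
    img = np.asarray(strf_image, dtype=float)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    if img.shape != (freqs_hz.size, frame_times_s.size):
        raise ValueError("image shape must be (n_freq, n_frames)")
    d_oct = check_log_spaced(freqs_hz)
    dt = float(np.mean(np.diff(frame_times_s)))
    power = np.abs(np.fft.fft2(img - img.mean())) ** 2
    f_spec = np.fft.fftfreq(img.shape[0], d=d_oct)  # cycles/octave
    f_temp = np.fft.fftfreq(img.shape[1], d=dt)  # cycles/s
    keep = f_spec >= 0
    P = power[keep]
    fs = f_spec[keep]
    ft_mag = np.abs(f_temp)
    total = P.sum()
    if total <= 0 or not np.isfinite(total):
        return ModulationSummary(0.0, 0.0, 0.0, 0.0, zero_power=True)
    i, j = np.unravel_index(np.argmax(P), P.shape)
    t_centroid = float((P * ft_mag[None, :]).sum() / total)
    s_centroid = float((P * fs[:, None]).sum() / total)
    return ModulationSummary(
        temporal_peak=float(ft_mag[j]),
        spectral_peak=float(fs[i]),
        temporal_centroid=t_centroid,
        spectral_centroid=s_centroid,
    )


def separability_index(strf_image) -> float:
    """Time–frequency separability: fraction of energy in the leading SVD mode.

    1.0 means the STRF is exactly a product of a frequency profile and a time
    profile; values near 1/rank indicate inseparable (e.g. diagonal) structure.
    """
    img = np.asarray(strf_image, dtype=float)
    if not np.any(img):
        raise ValueError("separability_index is undefined for a zero image")
    s = np.linalg.svd(img, compute_uv=False)
    return float(s[0] ** 2 / np.sum(s**2))


def snr_sparsity_curve(phi, patches, lambda_grid, lca_config: LcaConfig) -> pd.DataFrame:
    """Sweep the threshold and record mean active fraction and mean SNR.

    Returns a DataFrame with columns ``lam``, ``active_fraction``, ``snr_db``
    (one row per grid value).  Patches with zero norm are skipped in the SNR
    average.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda_grid must be nonempty")
    X = np.atleast_2d(np.asarray(patches, dtype=float))
    phi = np.asarray(phi, dtype=float)
    g = gram_matrix(phi)
    rows = []
    from dataclasses import replace

    for lam in lambda_grid:
        cfg = replace(lca_config, lam=float(lam))
        A, _ = lca_infer_batch(X, phi, cfg, gram=g)
        frac = np.count_nonzero(A) / A.size
        snrs = [
            snr_db(x, reconstruct(phi, a))
            for x, a in zip(X, A)
            if np.any(x)
        ]
        rows.append(
            {
                "lam": float(lam),
                "active_fraction": float(frac),
                "snr_db": float(np.mean(snrs)) if snrs else np.nan,
            }
        )
    return pd.DataFrame(rows)
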