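"""HDF5 persistence for pipeline artifacts.

All array artifacts (spectrograms, patch sets, whitening models,
dictionaries, codes) travel as self-describing HDF5 files with axis metadata
in attributes.  Datasets are written with ``track_times=False`` so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import numpy as np

import h5py

from .learning import Dictionary
from .preprocessing import PatchSet, PatchWhitener, Spectrogram

__all__ = [
    "save_spectrogram",
    "load_spectrogram",
    "save_patches",
    "load_patches",
    "save_whitener",
    "load_whitener",
    "save_dictionary",
    "load_dictionary",
    "save_codes",
    "load_codes",
]


def _write(group, name, data):
    group.create_dataset(name, data=np.asarray(data), track_times=False)


def save_spectrogram(path, spec: Spectrogram, **attrs) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "values", spec.values)
        _write(f, "freqs_hz", spec.freqs_hz)
        _write(f, "frame_times_s", spec.frame_times_s)
        f.attrs.update(attrs)


def load_spectrogram(path) -> Spectrogram:
    with h5py.File(path, "r") as f:
        return Spectrogram(
            values=f["values"][()],
            freqs_hz=f["freqs_hz"][()],
            frame_times_s=f["frame_times_s"][()],
        )


def save_patches(path, patches: PatchSet, **attrs) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "patches", patches.patches)
        f.attrs["n_freq"] = patches.n_freq
        f.attrs["n_frames_per_patch"] = patches.n_frames_per_patch
        f.attrs["patch_duration_ms"] = patches.patch_duration_ms
        f.attrs.update(attrs)


def load_patches(path) -> PatchSet:
    with h5py.File(path, "r") as f:
        return PatchSet(
            patches=f["patches"][()],
            n_freq=int(f.attrs["n_freq"]),
            n_frames_per_patch=int(f.attrs["n_frames_per_patch"]),
            patch_duration_ms=float(f.attrs["patch_duration_ms"]),
        )


def save_whitener(path, model: PatchWhitener, **attrs) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "mean", model.mean_)
        _write(f, "components", model.components_)
        _write(f, "explained_variance", model.explained_variance_)
        f.attrs["whiten"] = bool(model.whiten)
        f.attrs["variance_fraction"] = model.variance_fraction_
        f.attrs.update(attrs)


def load_whitener(path) -> PatchWhitener:
    with h5py.File(path, "r") as f:
        model = PatchWhitener(
            n_components=f["components"].shape[0], whiten=bool(f.attrs["whiten"])
        )
        model.mean_ = f["mean"][()]
        model.components_ = f["components"][()]
        model.explained_variance_ = f["explained_variance"][()]
        model.variance_fraction_ = float(f.attrs["variance_fraction"])
        model.n_components_ = model.components_.shape[0]
    return model


def save_dictionary(path, dictionary: Dictionary, **attrs) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "phi", dictionary.phi)
        if dictionary.element_order is not None:
            _write(f, "element_order", dictionary.element_order)
        f.attrs.update(attrs)


def load_dictionary(path) -> Dictionary:
    with h5py.File(path, "r") as f:
        order = f["element_order"][()] if "element_order" in f else None
        return Dictionary(phi=f["phi"][()], element_order=order)


def save_codes(path, codes: np.ndarray, **attrs) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "codes", codes)
        f.attrs.update(attrs)


def load_codes(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["codes"][()]
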