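"""Sparse inference with the locally competitive algorithm (LCA).

A dictionary ``phi`` (atoms as unit-norm columns, shape ``(n_features,
n_elements)``) represents an input ``x`` as a sparse combination ``x ≈ phi @ a``.
Each dictionary element is paired with a computing unit carrying an internal
(membrane-like) variable ``u_i`` and an output coefficient ``a_i``.  The units
are driven by the overlap of the input with their receptive field,
``b = phiᵀ x``, leak toward zero, and inhibit each other in proportion to the
overlap of their receptive fields and the competitors' output coefficients::

    tau * du/dt = b - u - (phiᵀ phi - I) @ a,      a = T_lambda(u)

All units start at ``u = 0``.  The thresholding function ``T_lambda`` selects
the sparseness regime: soft thresholding (L1, shrinks coefficients by
``lam``) or ideal hard thresholding (L0, passes ``u_i`` through unchanged
whenever ``|u_i| > lam``).

The sparse-coding energy is ``E(a) = ||x - phi a||^2 + lam * S(a)`` with
``S`` the number of nonzeros (L0) or the sum of absolute coefficients (L1).
With this scaling, LCA dynamics with threshold level ``lam`` descend the
energy with penalty weight ``2*lam`` (L1) and target the energy with weight
``lam**2`` (L0) — the classical threshold/penalty correspondence.
:attr:`LcaConfig.energy_lam` exposes the targeted weight.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "LcaConfig",
    "SparseCode",
    "threshold",
    "energy",
    "lca_infer",
    "lca_infer_batch",
    "reconstruct",
    "snr_db",
    "l0_exhaustive",
    "calibrate_lambda",
    "LcaSparseCoder",
    "SNR_CAP_DB",
]

SNR_CAP_DB = 300.0  # sentinel for a numerically perfect reconstruction

_MODES = ("l0", "l1")


def _check_mode(mode: str) -> str:
    m = str(mode).lower()
    if m not in _MODES:
        raise ValueError(f"unknown sparseness mode {mode!r}; expected 'l0' or 'l1'")
    return m


@dataclass(frozen=True)
class LcaConfig:
    """Numerical settings for LCA inference.

    Parameters
    ----------
    mode : {'l0', 'l1'}
        Hard (count the active units) or soft (penalize summed magnitude)
        sparseness.
    lam : float
        Threshold level of the units, > 0.
    tau : float
        Time constant of the dynamics; only the ratio ``dt/tau`` matters.
    dt : float
        Forward-Euler step.  ``dt/tau`` must lie in (0, 1] for stability.
    n_steps : int
        Maximum number of Euler steps.
    tol : float
        Early-stop threshold on ``max |du|``.
    anneal : bool
        If True, start the threshold at ``anneal_factor * lam`` and decay it
        geometrically to ``lam`` over ``anneal_steps`` steps before checking
        convergence.  Off by default.
    """

    mode: str = "l0"
    lam: float = 0.1
    tau: float = 1.0
    dt: float = 0.1
    n_steps: int = 400
    tol: float = 1e-6
    anneal: bool = False
    anneal_factor: float = 10.0
    anneal_steps: int = 100

    @property
    def energy_lam(self) -> float:
        """Penalty weight of the energy the dynamics target (2λ for L1, λ² for L0)."""
        return 2.0 * self.lam if _check_mode(self.mode) == "l1" else self.lam**2

    def problems(self) -> list[str]:
        """Return a list of human-readable constraint violations (empty if valid)."""
        out = []
        try:
            _check_mode(self.mode)
        except ValueError as exc:
            out.append(str(exc))
        if not self.lam > 0:
            out.append(f"lam must be > 0 (got {self.lam})")
        if not (self.tau > 0 and self.dt > 0):
            out.append(f"tau and dt must be > 0 (got tau={self.tau}, dt={self.dt})")
        elif not self.dt / self.tau <= 1.0:
            out.append(
                f"dt/tau = {self.dt / self.tau:g} violates the stability bound dt/tau <= 1"
            )
        if self.n_steps < 1:
            out.append(f"n_steps must be >= 1 (got {self.n_steps})")
        if self.tol < 0:
            out.append(f"tol must be >= 0 (got {self.tol})")
        return out

    def validate(self) -> "LcaConfig":
        probs = self.problems()
        if probs:
            raise ValueError("; ".join(probs))
        return self


@dataclass
class SparseCode:
    """Result of one LCA inference run."""

    a: np.ndarray
    u: np.ndarray
    n_iter: int
    converged: bool
    final_energy: float
    energy_path: np.ndarray | None = None


def threshold(u: np.ndarray, lam: float, mode: str = "l0") -> np.ndarray:
    """Apply the LCA thresholding function elementwise.

    L1 (soft): ``a = sign(u) * max(|u| - lam, 0)``.
    L0 (hard): ``a = u`` where ``|u| > lam``, else 0 (ties stay inactive).
    """
    mode = _check_mode(mode)
    u = np.asarray(u, dtype=float)
    if mode == "l1":
        return np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)
    return np.where(np.abs(u) > lam, u, 0.0)


def energy(x, dictionary, a, lam, mode="l0") -> float:
    """Sparse-coding energy ``||x - phi a||^2 + lam * S(a)``.

    ``S(a)`` counts nonzeros in L0 mode and sums ``|a_i|`` in L1 mode.
    """
    mode = _check_mode(mode)
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    phi = np.asarray(dictionary, dtype=float)
    r = x - phi @ a
    pen = np.count_nonzero(a) if mode == "l0" else np.abs(a).sum()
    return float(r @ r + lam * pen)


def _check_dictionary(phi: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2:
        raise ValueError("dictionary must be 2-D (n_features, n_elements)")
    norms = np.linalg.norm(phi, axis=0)
    if not np.allclose(norms, 1.0, atol=atol):
        raise ValueError("dictionary columns must be unit-norm")
    return phi


def _lam_schedule(config: LcaConfig) -> np.ndarray:
    if not config.anneal:
        return np.full(config.n_steps, config.lam)
    n_anneal = min(config.anneal_steps, config.n_steps)
    lam = np.full(config.n_steps, config.lam)
    if n_anneal > 1:
        lam[:n_anneal] = config.lam * np.geomspace(config.anneal_factor, 1.0, n_anneal)
    return lam


def _iterate(b, gram, config, x=None, phi=None, record_energy=False):
    """Core Euler loop shared by the single and batched entry points.

    ``b`` and the state arrays have shape ``(n_elements, n_cols)``.
    """
    s = config.dt / config.tau
    u = np.zeros_like(b)
    a = np.zeros_like(b)
    lam_path = _lam_schedule(config)
    n_anneal = config.anneal_steps if config.anneal else 0
    energies = [] if record_energy else None
    converged = False
    n_iter = 0
    for step in range(config.n_steps):
        a = threshold(u, lam_path[step], config.mode)
        if record_energy:
            r = x - phi @ a
            pen = (
                np.count_nonzero(a, axis=0)
                if config.mode == "l0"
                else np.abs(a).sum(axis=0)
            )
            energies.append(np.einsum("ij,ij->j", r, r) + config.energy_lam * pen)
        du = s * (b - u - gram @ a)
        u = u + du
        n_iter = step + 1
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(
                f"LCA state diverged at step {n_iter}; dt/tau = {s:g} is too large "
                "for this dictionary"
            )
        if step >= n_anneal and np.max(np.abs(du)) < config.tol:
            converged = True
            break
    a = threshold(u, config.lam, config.mode)
    if record_energy:
        r = x - phi @ a
        pen = (
            np.count_nonzero(a, axis=0)
            if config.mode == "l0"
            else np.abs(a).sum(axis=0)
        )
        energies.append(np.einsum("ij,ij->j", r, r) + config.energy_lam * pen)
        energies = np.asarray(energies)
    return u, a, n_iter, converged, energies


def gram_matrix(dictionary: np.ndarray) -> np.ndarray:
    """Lateral-inhibition kernel ``phiᵀ phi - I`` (precomputable per dictionary)."""
    phi = np.asarray(dictionary, dtype=float)
    g = phi.T @ phi
    np.fill_diagonal(g, g.diagonal() - 1.0)
    return g


def lca_infer(
    x,
    dictionary,
    config: LcaConfig,
    *,
    record_energy: bool = False,
    gram: np.ndarray | None = None,
) -> SparseCode:
    """Run LCA inference for a single input vector.

    Returns a :class:`SparseCode` whose ``a`` equals ``threshold(u, lam, mode)``
    at return.  ``final_energy`` is evaluated at the penalty weight the dynamics
    target (:attr:`LcaConfig.energy_lam`).  The dictionary is never mutated.
    """
    config.validate()
    phi = _check_dictionary(dictionary)
    x = np.asarray(x, dtype=float)
    if x.shape != (phi.shape[0],):
        raise ValueError(f"x has shape {x.shape}, expected ({phi.shape[0]},)")
    g = gram_matrix(phi) if gram is None else gram
    b = (phi.T @ x)[:, None]
    u, a, n_iter, converged, energies = _iterate(
        b, g, config, x=x[:, None], phi=phi, record_energy=record_energy
    )
    a1, u1 = a[:, 0], u[:, 0]
    return SparseCode(
        a=a1,
        u=u1,
        n_iter=n_iter,
        converged=converged,
        final_energy=energy(x, phi, a1, config.energy_lam, config.mode),
        energy_path=energies[:, 0] if record_energy else None,
    )


def lca_infer_batch(
    X, dictionary, config: LcaConfig, *, gram: np.ndarray | None = None
):
    """Vectorized LCA over rows of ``X`` (shape ``(n_samples, n_features)``).

    Returns ``(A, info)`` where ``A`` has shape ``(n_samples, n_elements)`` and
    ``info`` holds ``n_iter`` and ``converged`` for the batch as a whole (the
    early stop fires only when every column has settled).
    """
    config.validate()
    phi = _check_dictionary(dictionary)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != phi.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} features, dictionary expects {phi.shape[0]}"
        )
    g = gram_matrix(phi) if gram is None else gram
    b = phi.T @ X.T
    u, a, n_iter, converged, _ = _iterate(b, g, config)
    return a.T, {"n_iter": n_iter, "converged": converged}


def reconstruct(dictionary, a) -> np.ndarray:
    """Linear generative reconstruction ``x_hat = phi @ a``."""
    return np.asarray(dictionary, dtype=float) @ np.asarray(a, dtype=float)


def snr_db(x, x_hat) -> float:
    """Reconstruction SNR, ``10 log10(||x||^2 / ||x - x_hat||^2)``, capped at 300 dB."""
    x = np.asarray(x, dtype=float).ravel()
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    sig = float(x @ x)
    if sig == 0.0:
        raise ValueError("snr_db is undefined for an identically zero signal")
    r = x - x_hat
    err = float(r @ r)
    if err == 0.0:
        return SNR_CAP_DB
    return min(10.0 * np.log10(sig / err), SNR_CAP_DB)


def l0_exhaustive(x, dictionary, lam, max_support: int | None = None):
    """Exact small-scale L0 solver by enumeration of supports.

    Minimizes ``||x - phi a||^2 + lam * ||a||_0`` by solving a least-squares
    problem on every support set (optionally capped at ``max_support`` atoms).
    Exponential in the number of elements; intended as a reference for
    validating the LCA heuristic on problems with <= ~10 elements.
    """
    phi = np.asarray(dictionary, dtype=float)
    x = np.asarray(x, dtype=float)
    n_elements = phi.shape[1]
    if max_support is None:
        max_support = n_elements
    best_a = np.zeros(n_elements)
    best_e = energy(x, phi, best_a, lam, "l0")
    for size in range(1, max_support + 1):
        for support in itertools.combinations(range(n_elements), size):
            sub = phi[:, support]
            coef, *_ = np.linalg.lstsq(sub, x, rcond=None)
            a = np.zeros(n_elements)
            a[list(support)] = coef
            e = energy(x, phi, a, lam, "l0")
            if e < best_e:
                best_e, best_a = e, a
    return best_a, best_e


def calibrate_lambda(
    dictionary,
    X,
    target_active_fraction: float,
    config: LcaConfig,
    bounds: tuple[float, float] = (1e-4, 10.0),
    n_iter: int = 20,
) -> float:
    """Bisect (in log-lambda) for the threshold giving a target mean active fraction.

    The mean fraction of nonzero coefficients is non-increasing in ``lam``;
    returns the midpoint after ``n_iter`` bisection steps.
    """
    if not 0.0 < target_active_fraction < 1.0:
        raise ValueError("target_active_fraction must lie in (0, 1)")
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    phi = _check_dictionary(dictionary)
    g = gram_matrix(phi)

    def frac(lam):
        A, _ = lca_infer_batch(X, phi, replace(config, lam=float(lam)), gram=g)
        return np.count_nonzero(A) / A.size

    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if frac(np.exp(mid)) > target_active_fraction:
            lo = mid  # too many active units -> raise the threshold
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


class LcaSparseCoder(TransformerMixin, BaseEstimator):
    """Sparse coding transformer: inputs in, LCA coefficients out.

    Analogous to :class:`sklearn.decomposition.SparseCoder`: the dictionary is
    supplied at construction (``(n_components, n_features)``, unit-norm rows)
    and :meth:`transform` infers a sparse code per sample with the locally
    competitive algorithm.

    Parameters
    ----------
    dictionary : ndarray of shape (n_components, n_features)
        Atoms as rows, each with unit Euclidean norm.
    mode, lam, tau, dt, n_steps, tol, anneal
        See :class:`LcaConfig`.
    """

    def __init__(
        self,
        dictionary=None,
        *,
        mode="l0",
        lam=0.1,
        tau=1.0,
        dt=0.1,
        n_steps=400,
        tol=1e-6,
        anneal=False,
    ):
        self.dictionary = dictionary
        self.mode = mode
        self.lam = lam
        self.tau = tau
        self.dt = dt
        self.n_steps = n_steps
        self.tol = tol
        self.anneal = anneal

    def _config(self) -> LcaConfig:
        return LcaConfig(
            mode=self.mode,
            lam=self.lam,
            tau=self.tau,
            dt=self.dt,
            n_steps=self.n_steps,
            tol=self.tol,
            anneal=self.anneal,
        ).validate()

    def fit(self, X=None, y=None):
        if self.dictionary is None:
            raise ValueError("LcaSparseCoder requires a dictionary")
        phi = _check_dictionary(np.asarray(self.dictionary, dtype=float).T)
        self.components_ = phi.T
        self._gram = gram_matrix(phi)
        self._config()
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        A, _ = lca_infer_batch(
            X, self.components_.T, self._config(), gram=self._gram
        )
        return A

    @property
    def n_components_(self):
        check_is_fitted(self, "components_")
        return self.components_.shape[0]
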