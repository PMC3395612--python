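"""Dictionary learning by stochastic gradient descent with LCA in the loop.

The dictionary ``phi`` (unit-norm columns in the whitened input space) is
learned by alternating LCA inference of the coefficients with a gradient step
on the reconstruction error plus an orthogonality-promoting penalty
``(gamma/2) * ||phiᵀphi - I||_F²`` — a prior that basis functions be unique.
Per mini-batch of whitened patches::

    d_phi = eta * [ mean_batch (x - phi a) aᵀ  -  gamma * phi (phiᵀphi - I) ]

after which every column is renormalized to unit Euclidean length.  Elements
that stay inactive for a full epoch are re-initialized from a random training
patch to avoid wasted capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .lca import LcaConfig, gram_matrix, lca_infer_batch
from .synthetic import random_dictionary

__all__ = [
    "Dictionary",
    "LearnConfig",
    "init_dictionary",
    "n_elements_for",
    "learning_step",
    "learn_dictionary",
    "mean_energy",
    "match_atoms",
    "LcaDictionaryLearning",
]


@dataclass
class Dictionary:
    """A learned (or planted) dictionary: unit-norm atoms as columns of ``phi``."""

    phi: np.ndarray  # (n_features, n_elements)
    element_order: np.ndarray | None = None  # ascending-usage permutation

    @property
    def n_features(self) -> int:
        return self.phi.shape[0]

    @property
    def n_elements(self) -> int:
        return self.phi.shape[1]

    @property
    def overcompleteness(self) -> float:
        return self.n_elements / self.n_features


@dataclass
class LearnConfig:
    """Hyperparameters of the dictionary learner."""

    n_elements: int = 100
    eta: float = 0.1
    gamma: float = 0.02
    batch_size: int = 100
    n_epochs: int = 10
    seed: int = 0
    lca: LcaConfig = field(default_factory=LcaConfig)
    per_sample_updates: bool = False
    reinit_dead: bool = True

    def problems(self) -> list[str]:
        out = []
        if self.n_elements < 1:
            out.append("n_elements must be >= 1")
        if not self.eta >= 0:
            out.append(f"eta must be >= 0 (got {self.eta})")
        if not self.gamma >= 0:
            out.append(f"gamma must be >= 0 (got {self.gamma})")
        if self.batch_size < 1 or self.n_epochs < 1:
            out.append("batch_size and n_epochs must be >= 1")
        out.extend(self.lca.problems())
        return out

    def validate(self) -> "LearnConfig":
        probs = self.problems()
        if probs:
            raise ValueError("; ".join(probs))
        return self


def n_elements_for(overcompleteness: float, n_features: int) -> int:
    """Dictionary size at a given overcompleteness (relative to the input dim)."""
    if overcompleteness <= 0 or n_features < 1:
        raise ValueError("overcompleteness and n_features must be positive")
    return int(round(overcompleteness * n_features))


def _renormalize(phi: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(phi, axis=0)
    norms[norms == 0] = 1.0  # leave a collapsed column for dead-element handling
    return phi / norms


def init_dictionary(n_features: int, n_elements: int, seed: int) -> Dictionary:
    """Random initial dictionary: i.i.d. Gaussian columns, unit-normalized."""
    if n_features < 1 or n_elements < 1:
        raise ValueError("n_features and n_elements must be >= 1")
    rng = np.random.default_rng(seed)
    return Dictionary(phi=random_dictionary(n_features, n_elements, rng))


def learning_step(phi: np.ndarray, batch: np.ndarray, config: LearnConfig):
    """One gradient step on a mini-batch of whitened patches (rows of ``batch``).

    Returns ``(phi_new, diagnostics)`` where diagnostics hold the mean
    residual norm, the mean active fraction, and the indices of elements
    active anywhere in the batch.  ``phi`` is not mutated.
    """
    phi = np.asarray(phi, dtype=float)
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    A, _ = lca_infer_batch(batch, phi, config.lca)
    X = batch.T  # (n_features, B)
    At = A.T  # (n_elements, B)
    R = X - phi @ At
    n_batch = X.shape[1]
    grad_recon = (R @ At.T) / n_batch
    grad = grad_recon
    if config.gamma > 0:
        grad = grad - config.gamma * phi @ gram_matrix(phi)
    phi_new = _renormalize(phi + config.eta * grad)
    if not np.all(np.isfinite(phi_new)):
        raise FloatingPointError(
            f"non-finite dictionary update (eta={config.eta}, gamma={config.gamma}, "
            f"mean residual={np.linalg.norm(R, axis=0).mean():g})"
        )
    diagnostics = {
        "mean_residual": float(np.linalg.norm(R, axis=0).mean()),
        "mean_active_fraction": float(np.count_nonzero(A) / A.size),
        "active_elements": np.flatnonzero(np.any(A != 0, axis=0)),
    }
    return phi_new, diagnostics


def mean_energy(X, phi, lca_config: LcaConfig) -> float:
    """Mean sparse-coding energy of ``X`` (rows) under LCA inference.

    Evaluated at the penalty weight the dynamics target
    (:attr:`LcaConfig.energy_lam`)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A, _ = lca_infer_batch(X, phi, lca_config)
    R = X.T - phi @ A.T
    if lca_config.mode.lower() == "l0":
        pen = np.count_nonzero(A, axis=1)
    else:
        pen = np.abs(A).sum(axis=1)
    e = np.einsum("ij,ij->j", R, R) + lca_config.energy_lam * pen
    return float(e.mean())


def learn_dictionary(X, config: LearnConfig, init: Dictionary | None = None):
    """Learn a dictionary from whitened patches (rows of ``X``).

    Runs ``n_epochs`` of shuffled mini-batches of :func:`learning_step`.
    Returns ``(Dictionary, log)`` where ``log`` is a list of per-epoch dicts
    with the mean energy, mean active fraction, extreme off-diagonal Gram
    entries, and the number of dead elements re-initialized.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    X = check_array(np.asarray(X, dtype=float))
    n_samples, n_features = X.shape
    if n_samples < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} patches (got {n_samples})"
        )
    rng = np.random.default_rng(config.seed)
    phi = (
        init.phi.copy()
        if init is not None
        else random_dictionary(n_features, config.n_elements, rng)
    )
    log = []
    batch = config.batch_size if not config.per_sample_updates else 1
    for epoch in range(config.n_epochs):
        order = rng.permutation(n_samples)
        active_any = np.zeros(phi.shape[1], dtype=bool)
        energies, fracs = [], []
        for start in range(0, n_samples - batch + 1, batch):
            idx = order[start : start + batch]
            phi, diag = learning_step(phi, X[idx], config)
            active_any[diag["active_elements"]] = True
            energies.append(diag["mean_residual"] ** 2)
            fracs.append(diag["mean_active_fraction"])
        n_dead = 0
        if config.reinit_dead:
            dead = np.flatnonzero(~active_any)
            n_dead = dead.size
            for j in dead:
                p = X[rng.integers(n_samples)]
                norm = np.linalg.norm(p)
                phi[:, j] = (
                    p / norm if norm > 0 else random_dictionary(n_features, 1, rng)[:, 0]
                )
        gram = phi.T @ phi
        off = gram[~np.eye(phi.shape[1], dtype=bool)]
        log.append(
            {
                "epoch": epoch,
                "mean_energy": mean_energy(X[order[: min(n_samples, 500)]], phi, config.lca),
                "mean_active_fraction": float(np.mean(fracs)) if fracs else 0.0,
                "gram_offdiag_min": float(off.min()) if off.size else 0.0,
                "gram_offdiag_max": float(off.max()) if off.size else 0.0,
                "n_dead_reinit": int(n_dead),
            }
        )
    return Dictionary(phi=phi), log


def match_atoms(phi_learned: np.ndarray, phi_true: np.ndarray) -> np.ndarray:
    """Best one-to-one |cosine| match between learned and planted atoms.

    Uses the Hungarian algorithm on ``|phi_learnedᵀ phi_true|`` and returns
    the matched absolute cosines (one per planted atom, sign/permutation
    invariant).
    """
    C = np.abs(np.asarray(phi_learned).T @ np.asarray(phi_true))
    rows, cols = linear_sum_assignment(-C)
    out = np.zeros(phi_true.shape[1])
    out[cols] = C[rows, cols]
    return out


class LcaDictionaryLearning(TransformerMixin, BaseEstimator):
    """Sparse dictionary learning with LCA inference (scikit-learn estimator).

    ``fit`` learns ``components_`` (shape ``(n_components, n_features)``,
    unit-norm rows) from data rows by mini-batch gradient descent;
    ``transform`` returns the LCA sparse codes under the fitted dictionary.

    Parameters mirror :class:`LearnConfig` / :class:`LcaConfig`; pass
    ``random_state`` for reproducibility.
    """

    def __init__(
        self,
        n_components: int = 100,
        *,
        mode: str = "l0",
        lam: float = 0.1,
        eta: float = 0.1,
        gamma: float = 0.02,
        batch_size: int = 100,
        n_epochs: int = 10,
        tau: float = 1.0,
        dt: float = 0.1,
        n_steps: int = 400,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.mode = mode
        self.lam = lam
        self.eta = eta
        self.gamma = gamma
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.tau = tau
        self.dt = dt
        self.n_steps = n_steps
        self.tol = tol
        self.random_state = random_state

    def _learn_config(self) -> LearnConfig:
        return LearnConfig(
            n_elements=self.n_components,
            eta=self.eta,
            gamma=self.gamma,
            batch_size=self.batch_size,
            n_epochs=self.n_epochs,
            seed=self.random_state,
            lca=LcaConfig(
                mode=self.mode,
                lam=self.lam,
                tau=self.tau,
                dt=self.dt,
                n_steps=self.n_steps,
                tol=self.tol,
            ),
        ).validate()

    def fit(self, X, y=None):
        config = self._learn_config()
        dictionary, log = learn_dictionary(X, config)
        self.components_ = dictionary.phi.T
        self.log_ = log
        self.n_components_ = dictionary.n_elements
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        A, _ = lca_infer_batch(X, self.components_.T, self._learn_config().lca)
        return A
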