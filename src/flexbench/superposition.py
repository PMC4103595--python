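"""Rigid-body superposition of conformational ensembles.

Before per-residue fluctuations mean anything, global rotation and
translation must be removed from every conformer. The workhorse is the
Kabsch algorithm (closed-form optimal proper rotation via SVD); ensembles
are aligned by the classical iterative scheme — superpose everything onto
a reference, recompute the mean structure, use the mean as the new
reference — optionally with inverse-variance residue weights so highly
mobile residues do not dominate the fit (the behaviour of
maximum-likelihood superposition tools such as theseus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Conformer, Ensemble

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "kabsch",
    "superpose_ensemble",
]

#: variance regularizer for inverse-variance weights, Å²
VARIANCE_EPS = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: x ↦ R·x + t."""

    rotation: np.ndarray  # (3, 3), orthogonal, det = +1
    translation: np.ndarray  # (3,), Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def is_proper(self, tol: float = 1e-8) -> bool:
        R = self.rotation
        return (
            np.allclose(R.T @ R, np.eye(3), atol=tol)
            and abs(np.linalg.det(R) - 1.0) < tol
        )


@dataclass
class SuperpositionResult:
    """Transformed ensemble plus the converged mean structure and weights."""

    ensemble: Ensemble
    mean_structure: np.ndarray  # (N, 3), Å
    weights: np.ndarray  # (N,), non-negative, sums to N
    iterations: int
    converged: bool
    mode: str = "uniform"
    residual_history: list[float] = field(default_factory=list)


def kabsch(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Optimal weighted rigid superposition of ``mobile`` onto ``target``.

    Minimizes Σ wᵢ‖R·mobileᵢ + t − targetᵢ‖² over proper rotations;
    reflections are suppressed by flipping the sign of the smallest
    singular direction when det would be −1.

    Raises
    ------
    ValueError
        If fewer than 3 points, all-zero weights, or the point set is
        degenerate (collinear), leaving the rotation underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("underdetermined: need at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per point")
        if not np.any(w > 0):
            raise ValueError("weights must not be all zero")
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(0) / wsum
    ct = (w[:, None] * target).sum(0) / wsum
    A = mobile - cm
    B = target - ct
    H = (w[:, None] * A).T @ B
    U, S, Vt = np.linalg.svd(H)
    # collinear point sets leave rotation about the common axis free
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise ValueError("underdetermined: points are (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return RigidTransform(rotation=R, translation=t)


def _weighted_residual(coords: np.ndarray, mean: np.ndarray, w: np.ndarray) -> float:
    # summed weighted squared deviation of all conformers about the mean
    d = coords - mean[None, :, :]
    return float(np.sum(w[None, :] * np.sum(d * d, axis=2)))


def superpose_ensemble(
    ensemble: Ensemble,
    mode: str = "inverse_variance",
    tol: float = 1e-4,
    max_iter: int = 50,
) -> SuperpositionResult:
    """Iteratively superpose all conformers onto their evolving mean.

    Parameters
    ----------
    ensemble : Ensemble
        M ≥ 2 conformers over N ≥ 3 residues.
    mode : {"inverse_variance", "uniform"}
        ``"uniform"`` is plain least squares. ``"inverse_variance"``
        reweights residues each iteration by 1/(vᵢ + ε), where vᵢ is the
        residue's current mean-square deviation about the mean — mobile
        loops stop steering the fit, approximating maximum-likelihood
        superposition.
    tol : float
        Convergence threshold on the RMSD between successive mean
        structures, Å.
    max_iter : int
        Iteration cap; hitting it yields ``converged=False``, not an
        error.
    """
    if ensemble.n_models < 2:
        raise ValueError("nothing to superpose: ensemble has fewer than 2 models")
    if ensemble.n_residues < 3:
        raise ValueError("need at least 3 residues to superpose")
    if mode not in ("uniform", "inverse_variance"):
        raise ValueError(f"unknown mode {mode!r}")

    X = ensemble.coords_array().copy()  # (M, N, 3)
    M, N, _ = X.shape
    w = np.ones(N)
    reference = X[0].copy()
    prev_mean = None
    converged = False
    iterations = 0
    history: list[float] = []

    for iterations in range(1, max_iter + 1):
        for j in range(M):
            T = kabsch(X[j], reference, w)
            X[j] = T.apply(X[j])
        mean = X.mean(axis=0)
        history.append(_weighted_residual(X, mean, w))
        if prev_mean is not None:
            shift = float(np.sqrt(np.mean(np.sum((mean - prev_mean) ** 2, axis=1))))
            if shift < tol:
                converged = True
                prev_mean = mean
                break
        prev_mean = mean
        if mode == "inverse_variance":
            v = np.mean(np.sum((X - mean[None]) ** 2, axis=2), axis=0)
            w = 1.0 / (v + VARIANCE_EPS)
            w *= N / w.sum()
        reference = mean

    mean = X.mean(axis=0)
    conformers = [
        Conformer(c.model_id, X[j], c.residues)
        for j, c in enumerate(ensemble.conformers)
    ]
    out = Ensemble(
        conformers,
        source_label=ensemble.source_label,
        warnings=list(ensemble.warnings),
    )
    return SuperpositionResult(
        ensemble=out,
        mean_structure=mean,
        weights=w * (N / w.sum()),
        iterations=iterations,
        converged=converged,
        mode=mode,
        residual_history=history,
    )
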