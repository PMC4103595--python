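"""Residue-fluctuation (RMSF) profiles.

The RMSF of residue i over an M-model superposed ensemble is

    RMSF_i = sqrt( (1/M) Σ_j ‖x_ij − ⟨x_i⟩‖² ),   ⟨x_i⟩ = (1/M) Σ_j x_ij

with the population divisor M (the average runs over the whole ensemble).
The residue-averaged RMSF — "average displacement per residue" — is the
scalar used to stratify ensembles by variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Ensemble, ResidueKey
from .superposition import SuperpositionResult

__all__ = ["FluctuationProfile", "rmsf_profile", "average_displacement"]


@dataclass
class FluctuationProfile:
    """Per-residue RMSF values (Å) with provenance."""

    residues: tuple[ResidueKey, ...]
    rmsf: np.ndarray  # (N,), non-negative, Å
    ensemble_size: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        self.residues = tuple(self.residues)
        if self.rmsf.ndim != 1 or len(self.residues) != self.rmsf.shape[0]:
            raise ValueError("rmsf and residues lengths differ")
        if np.any(self.rmsf < 0) or np.any(~np.isfinite(self.rmsf)):
            raise ValueError("RMSF values must be finite and non-negative")

    def __len__(self) -> int:
        return self.rmsf.shape[0]


def rmsf_profile(
    source: SuperpositionResult | Ensemble, label: str | None = None
) -> FluctuationProfile:
    """Compute the RMSF profile of a superposed ensemble.

    Accepts either a :class:`SuperpositionResult` or a bare
    :class:`Ensemble` whose conformers are already in a common frame
    (e.g. an M=1 ensemble, where every RMSF is 0 by definition).
    """
    if isinstance(source, SuperpositionResult):
        ensemble = source.ensemble
    else:
        ensemble = source
    X = ensemble.coords_array()  # (M, N, 3)
    mean = X.mean(axis=0)
    msd = np.mean(np.sum((X - mean[None]) ** 2, axis=2), axis=0)
    rmsf = np.sqrt(msd)
    if label is None:
        label = ensemble.source_label
    return FluctuationProfile(
        residues=ensemble.residues,
        rmsf=rmsf,
        ensemble_size=ensemble.n_models,
        label=label,
    )


def average_displacement(profile: FluctuationProfile) -> float:
    """Mean RMSF over residues (Å) — the ensemble's scalar variability."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    return float(np.mean(profile.rmsf))
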