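"""Gaussian network model (GNM) flexibility prediction from one structure.

The GNM treats the Cα trace as an elastic network: residues closer than a
cutoff are joined by identical springs, encoded in the Kirchhoff
(connectivity) matrix Γ. Relative mean-square fluctuations are the
diagonal of the Moore–Penrose pseudo-inverse of Γ (the rigid-body zero
mode excluded). This gives a cheap single-structure flexibility profile —
the coarse-grained normal-mode alternative to ensemble-based methods —
whose *shape* can be compared against ensemble RMSF profiles with
Spearman r_s; an overall scale can be imposed by normalizing the
profile's mean to a chosen average displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .fluctuation import FluctuationProfile
from .structures import Conformer

__all__ = ["GnmModel", "build_gnm", "gnm_profile"]

#: eigenvalues below this fraction of the largest count as zero modes
ZERO_MODE_RTOL = 1e-10


@dataclass
class GnmModel:
    """Kirchhoff matrix of the elastic network, plus its provenance."""

    kirchhoff: np.ndarray  # (N, N), symmetric, zero row sums
    cutoff: float  # Å
    residues: tuple  # ResidueKey per node
    n_zero_modes: int = 1


def build_gnm(conformer: Conformer, cutoff: float = 7.3) -> GnmModel:
    """Build the GNM Kirchhoff matrix from one Cα conformer.

    Γ_ij = −1 for i≠j with ‖x_i − x_j‖ ≤ cutoff, else 0; the diagonal
    makes every row sum to zero. The default 7.3 Å is the conventional
    Cα–Cα contact cutoff.

    Raises
    ------
    ValueError
        If N < 4 or the contact graph is disconnected (fluctuations are
        then undefined up to independent per-component shifts).
    """
    coords = np.asarray(conformer.coords, dtype=float)
    n = coords.shape[0]
    if n < 4:
        raise ValueError("GNM needs at least 4 residues")
    dist = squareform(pdist(coords))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    n_comp, labels = connected_components(contact, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"contact graph disconnected at cutoff {cutoff} Å: "
            f"{n_comp} components of sizes {sizes.tolist()}"
        )
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    return GnmModel(
        kirchhoff=gamma,
        cutoff=cutoff,
        residues=conformer.residues,
        n_zero_modes=1,
    )


def gnm_profile(
    model: GnmModel, scale_to: float | None = None, label: str = "GNM"
) -> FluctuationProfile:
    """Per-residue fluctuation profile from the GNM.

    raw_i = [Γ⁺]_ii summed over non-zero modes; the profile is
    c·sqrt(raw), with c chosen so the residue-averaged value equals
    ``scale_to`` (Å) when given, else c = 1 (arbitrary units — only the
    shape is meaningful).
    """
    gamma = model.kirchhoff
    evals, evecs = np.linalg.eigh(gamma)
    nonzero = evals > ZERO_MODE_RTOL * evals[-1]
    if np.count_nonzero(~nonzero) != model.n_zero_modes:
        raise ValueError(
            f"expected {model.n_zero_modes} zero mode(s), found "
            f"{np.count_nonzero(~nonzero)}"
        )
    # diag(Γ⁺) = Σ_k u_ki² / λ_k over non-rigid modes
    raw = (evecs[:, nonzero] ** 2 / evals[nonzero]).sum(axis=1)
    prof = np.sqrt(raw)
    if scale_to is not None:
        if scale_to <= 0:
            raise ValueError("scale_to must be positive")
        prof = prof * (scale_to / prof.mean())
    return FluctuationProfile(
        residues=model.residues, rmsf=prof, ensemble_size=1, label=label
    )
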