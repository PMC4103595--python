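"""Core containers for conformational ensembles of Cα traces.

An :class:`Ensemble` is an ordered set of conformers (models) over one
common residue list — the shape of an NMR ensemble deposited as a
multi-model PDB entry, or of trajectory snapshots exported the same way.
Coordinates are Cα positions in Ångström throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ResidueKey", "Conformer", "Ensemble"]


@dataclass(frozen=True)
class ResidueKey:
    """Identity of one residue: chain, author residue number, insertion code.

    ``res_name`` is carried for readability but residue *matching* across
    profiles uses only ``(chain_id, seq_num, insertion_code)``.
    """

    chain_id: str
    seq_num: int
    insertion_code: str = ""
    res_name: str = ""

    @property
    def match_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def __str__(self) -> str:
        ic = self.insertion_code or ""
        return f"{self.chain_id}/{self.res_name}{self.seq_num}{ic}"


@dataclass
class Conformer:
    """One model: an ordered Cα coordinate set with residue identities."""

    model_id: int
    coords: np.ndarray  # (N, 3) float, Å
    residues: tuple[ResidueKey, ...]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residues = tuple(self.residues)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.residues) != self.coords.shape[0]:
            raise ValueError("coords and residues lengths differ")
        if self.coords.shape[0] < 2:
            raise ValueError("a conformer needs at least 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = [r.match_key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys within one conformer")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass
class Ensemble:
    """Ordered conformers sharing an identical residue list.

    ``source_label`` records provenance ("NMR", "MD", "GNM", ...); it is
    free text and never interpreted.
    """

    conformers: list[Conformer]
    source_label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.conformers) < 1:
            raise ValueError("an ensemble needs at least one conformer")
        ref = self.conformers[0].residues
        for c in self.conformers[1:]:
            if c.residues != ref:
                raise ValueError(
                    f"conformer {c.model_id} has a different residue list "
                    f"than conformer {self.conformers[0].model_id}"
                )

    @property
    def n_models(self) -> int:
        return len(self.conformers)

    @property
    def n_residues(self) -> int:
        return self.conformers[0].n_residues

    @property
    def residues(self) -> tuple[ResidueKey, ...]:
        return self.conformers[0].residues

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an (M, N, 3) array."""
        return np.stack([c.coords for c in self.conformers])
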