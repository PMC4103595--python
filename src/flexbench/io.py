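"""Reading and writing multi-model PDB ensembles and RMSF profile tables.

PDB parsing goes through :mod:`gemmi`; only ``ATOM`` records with atom
name ``CA`` and a standard amino-acid residue name are used (HETATM and
hydrogens ignored). Output files are Cα-only and always wrapped in
MODEL/ENDMDL records, even for a single model, so they round-trip as
ensembles. Profile tables are plain CSV with columns
``chain,seq_num,icode,res_name,rmsf``.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd

from .fluctuation import FluctuationProfile
from .structures import Conformer, Ensemble, ResidueKey

__all__ = [
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_profile_table",
    "write_profile_table",
]

PROFILE_COLUMNS = ["chain", "seq_num", "icode", "res_name", "rmsf"]

_KEPT_ALTLOCS = ("\0", "", " ", "A")


def _is_standard_aa(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def _extract_ca(model: gemmi.Model, chain: str | None):
    """Ordered {match_key -> (ResidueKey, xyz)} of Cα atoms in one model."""
    out: dict[tuple, tuple[ResidueKey, np.ndarray]] = {}
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.het_flag != "A" or not _is_standard_aa(res.name):
                continue
            ca = None
            for atom in res:
                if atom.name == "CA" and atom.altloc in _KEPT_ALTLOCS:
                    ca = atom
                    break
            if ca is None:
                continue
            icode = res.seqid.icode.strip()
            key = ResidueKey(ch.name, res.seqid.num, icode, res.name)
            if key.match_key not in out:  # first occurrence wins
                out[key.match_key] = (
                    key,
                    np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                )
    return out


def read_multimodel_pdb(
    path: str | os.PathLike,
    chain: str | None = None,
    model_limit: int | None = None,
    source_label: str = "",
) -> Ensemble:
    """Read a (multi-)model PDB file into a Cα :class:`Ensemble`.

    Residues present in every model are kept, in the file order of the
    first model; residues missing from any model are dropped and listed
    in ``Ensemble.warnings``. Alternate locations other than blank/'A'
    are discarded.

    Raises
    ------
    ValueError
        If the file is malformed, contains no Cα atoms, or fewer than
        2 residues survive the across-model intersection.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path!r}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path!r}")

    models = list(st)
    if model_limit is not None:
        models = models[:model_limit]

    per_model = [_extract_ca(m, chain) for m in models]
    if not per_model[0]:
        raise ValueError(f"no Cα atoms found in {path!r}")

    common = set(per_model[0])
    for pm in per_model[1:]:
        common &= set(pm)

    warnings: list[str] = []
    first_order = list(per_model[0].keys())
    kept = [k for k in first_order if k in common]
    for pm in per_model:
        for k, (rk, _) in pm.items():
            if k not in common:
                msg = f"residue {rk} missing from some models; dropped"
                if msg not in warnings:
                    warnings.append(msg)
    if len(kept) < 2:
        raise ValueError(
            f"fewer than 2 residues shared by all models in {path!r}"
        )

    conformers = []
    for model, pm in zip(models, per_model):
        residues = tuple(pm[k][0] for k in kept)
        coords = np.array([pm[k][1] for k in kept])
        # residue identity must agree across models, not just numbering
        conformers.append(Conformer(model.num, coords, residues))
    ref = conformers[0].residues
    for c in conformers[1:]:
        if c.residues != ref:
            raise ValueError(
                f"model {c.model_id} disagrees on residue names in {path!r}"
            )
    return Ensemble(conformers, source_label=source_label, warnings=warnings)


def write_multimodel_pdb(ensemble: Ensemble, path: str | os.PathLike) -> None:
    """Write a Cα-only multi-model PDB (MODEL/ENDMDL per conformer).

    Coordinates use the fixed 8.3 PDB columns, so a round-trip preserves
    them to 0.001 Å.
    """
    lines = []
    for conf in ensemble.conformers:
        lines.append(f"MODEL     {conf.model_id:4d}")
        serial = 0
        for key, xyz in zip(conf.residues, conf.coords):
            serial += 1
            icode = key.insertion_code or " "
            lines.append(
                f"ATOM  {serial:5d}  CA  {key.res_name:>3s} "
                f"{key.chain_id:1s}{key.seq_num:4d}{icode:1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          "
                f" C  "
            )
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_profile_table(
    profile: FluctuationProfile, path: str | os.PathLike
) -> None:
    """Write a per-residue RMSF profile as CSV (Å)."""
    df = pd.DataFrame(
        {
            "chain": [r.chain_id for r in profile.residues],
            "seq_num": [r.seq_num for r in profile.residues],
            "icode": [r.insertion_code for r in profile.residues],
            "res_name": [r.res_name for r in profile.residues],
            "rmsf": profile.rmsf,
        }
    )
    df.to_csv(path, index=False)


def read_profile_table(
    path: str | os.PathLike, label: str = ""
) -> FluctuationProfile:
    """Read a profile CSV written by :func:`write_profile_table`.

    Row order is preserved; duplicate residue keys or non-numeric RMSF
    values are errors.
    """
    df = pd.read_csv(path, dtype={"chain": str, "icode": str}, keep_default_na=False)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("empty profile")
    rmsf = pd.to_numeric(df["rmsf"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(rmsf)):
        bad = df.index[~np.isfinite(rmsf)][0]
        raise ValueError(f"non-numeric RMSF value in row {bad + 1}")
    residues = tuple(
        ResidueKey(str(c), int(s), str(i).strip(), str(n))
        for c, s, i, n in zip(
            df["chain"], df["seq_num"], df["icode"], df["res_name"]
        )
    )
    keys = [r.match_key for r in residues]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate residue keys in profile table")
    return FluctuationProfile(
        residues=residues, rmsf=rmsf, ensemble_size=0, label=label
    )
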