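"""Pairwise comparison of residue-fluctuation profiles.

Two complementary metrics: Spearman's rank correlation r_s (monotone
association of the profile *shapes*, robust to amplitude differences and
outliers) and the profile RMSD (root mean square difference of the RMSF
values themselves, which *does* see amplitude). Residues are paired by
identity (chain, residue number, insertion code); a rank-order fallback
handles differently numbered profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .fluctuation import FluctuationProfile

__all__ = [
    "ProfileComparison",
    "match_profiles",
    "spearman",
    "profile_rmsd",
    "compare_profiles",
]


@dataclass
class ProfileComparison:
    """Paired-profile statistics for one method pair.

    ``r_s`` is NaN when undefined (fewer than 2 matched residues or zero
    rank variance in either profile) — explicitly *not* reported as 0.
    """

    r_s: float
    profile_rmsd: float
    n_matched: int
    labels: tuple[str, str] = ("", "")

    @property
    def rs_defined(self) -> bool:
        return not math.isnan(self.r_s)


def match_profiles(
    a: FluctuationProfile,
    b: FluctuationProfile,
    renumber: bool = False,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair the two profiles residue-by-residue.

    By default residues are matched on (chain, seq_num, icode); unmatched
    residues are dropped. With ``renumber=True`` residues are paired by
    rank order instead (for profiles with different numbering schemes),
    truncating to the shorter profile.

    Returns ``(x, y, n_dropped)`` where x follows a's order.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot match an empty profile")
    if renumber:
        n = min(len(a), len(b))
        x = np.asarray(a.rmsf[:n], dtype=float)
        y = np.asarray(b.rmsf[:n], dtype=float)
        dropped = (len(a) - n) + (len(b) - n)
    else:
        b_index = {r.match_key: v for r, v in zip(b.residues, b.rmsf)}
        xs, ys = [], []
        for r, v in zip(a.residues, a.rmsf):
            if r.match_key in b_index:
                xs.append(v)
                ys.append(b_index[r.match_key])
        if len(xs) == 0:
            raise ValueError(
                "no residues matched between profiles; if the numbering "
                "schemes differ, retry with renumber=True (--renumber)"
            )
        x = np.array(xs)
        y = np.array(ys)
        dropped = (len(a) - len(x)) + (len(b) - len(x))
    if len(x) < 2:
        raise ValueError("fewer than 2 matched residues")
    return x, y, dropped


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Ties receive fractional (average) ranks. With no ties this equals the
    classical 1 − 6·Σd²/(n(n²−1)). Returns NaN when either list has zero
    rank variance (constant input), where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return math.nan
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def profile_rmsd(x, y) -> float:
    """Root mean square difference between paired profile values (Å)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length non-empty sequences")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def compare_profiles(
    a: FluctuationProfile,
    b: FluctuationProfile,
    renumber: bool = False,
) -> ProfileComparison:
    """Match two profiles and compute r_s and profile RMSD."""
    x, y, _ = match_profiles(a, b, renumber=renumber)
    return ProfileComparison(
        r_s=spearman(x, y),
        profile_rmsd=profile_rmsd(x, y),
        n_matched=len(x),
        labels=(a.label, b.label),
    )
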