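"""Synthetic ensembles and benchmark tables with known ground truth.

Two generators make the whole pipeline testable without any downloads:

* :func:`make_ensemble` builds an NMR-like multi-model ensemble — a mean
  backbone plus independent per-residue isotropic Gaussian displacements
  with a prescribed per-axis amplitude profile σ_i, each model then hit
  by a random rigid-body transform (so superposition has real work to
  do). The pre-jitter coordinates define an oracle RMSF profile that the
  pipeline must recover.

* :func:`make_benchmark_table` builds a per-protein benchmark table whose
  subset structure and summary statistics (means, SDs, counts) are fixed
  *by construction*, so aggregation can be checked exactly. The defaults
  reproduce the published benchmark's summary: 140 proteins, 60/80
  low/high-variability split at 1 Å, overall mean r_s 0.72 (SD 0.15)
  prediction-vs-NMR and 0.64 (SD 0.23) MD-vs-NMR, high-subset means
  0.78/0.69, a 10-protein poor subset (r_s < 0.5) with means 0.35/0.26,
  and mean ensemble variability 1.68 Å.

Displacements are independent across residues — no correlated collective
motions — which is sufficient for testing the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .benchmark import BenchmarkRecord
from .fluctuation import FluctuationProfile
from .structures import Conformer, Ensemble, ResidueKey

__all__ = [
    "SyntheticSpec",
    "sigma_shape",
    "make_backbone",
    "make_ensemble",
    "make_benchmark_table",
]


def make_backbone(n_residues: int, geometry: str = "helix") -> Conformer:
    """Idealized Cα trace: a straight chain or an α-helix.

    "line": collinear points spaced 3.8 Å. "helix": radius 2.3 Å, rise
    1.5 Å and 100° twist per residue, giving consecutive Cα–Cα distances
    of ≈3.8 Å.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    i = np.arange(n_residues, dtype=float)
    if geometry == "line":
        coords = np.column_stack([3.8 * i, np.zeros_like(i), np.zeros_like(i)])
    elif geometry == "helix":
        theta = np.deg2rad(100.0) * i
        coords = np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
        )
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    residues = tuple(
        ResidueKey("A", int(k) + 1, "", "ALA") for k in range(n_residues)
    )
    return Conformer(model_id=1, coords=coords, residues=residues)


def sigma_shape(
    n_residues: int,
    shape: str = "flat",
    base: float = 0.3,
    amp: float = 1.2,
    width: int | None = None,
) -> np.ndarray:
    """Named per-residue amplitude profiles (per-axis SD, Å).

    "flat": constant ``base``. "terminal-ramp": ``base + amp`` at both
    termini, decaying smoothly (exponentially, length scale ``width``,
    default n//5) toward ``base`` in the core — mimics floppy tails. The
    decay is strictly monotone toward mid-chain, so no two core residues
    share exactly the same amplitude (rank structure stays informative).
    "loop-bump": a Gaussian bump of height ``amp`` and SD ``width``
    (default n//10) centred mid-chain — mimics a mobile loop.
    """
    i = np.arange(n_residues, dtype=float)
    if shape == "flat":
        return np.full(n_residues, float(base))
    if shape == "terminal-ramp":
        w = width if width is not None else max(n_residues // 5, 2)
        edge = np.minimum(i, n_residues - 1 - i)
        return base + amp * np.exp(-edge / w)
    if shape == "loop-bump":
        w = width if width is not None else max(n_residues // 10, 2)
        c = (n_residues - 1) / 2.0
        return base + amp * np.exp(-0.5 * ((i - c) / w) ** 2)
    raise ValueError(f"unknown sigma shape {shape!r}")


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic ensemble; the seed fixes everything."""

    n_residues: int = 100
    n_models: int = 20
    sigma: np.ndarray | float = 0.5  # per-residue per-axis SD, Å
    max_rotation_deg: float = 30.0
    max_translation: float = 5.0  # Å
    geometry: str = "helix"
    seed: int = 0

    def sigma_array(self) -> np.ndarray:
        s = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), (self.n_residues,)
        ).copy()
        if np.any(s < 0):
            raise ValueError("sigma amplitudes must be >= 0")
        return s


def _random_rigid(rng: np.random.Generator, max_deg: float, max_trans: float):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, np.deg2rad(max_deg))
    R = Rotation.from_rotvec(axis * angle).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, max_trans)
    return R, t


def make_ensemble(spec: SyntheticSpec) -> tuple[Ensemble, FluctuationProfile]:
    """Generate an ensemble and the oracle RMSF of its pre-jitter frames.

    Model j = backbone + N(0, σ_i²) per axis, then one random rotation
    (angle ≤ max) and translation (length ≤ max) applied to the whole
    model. The oracle profile is the population RMSF of the coordinates
    *before* the rigid jitter — what a perfect superposition would see.
    """
    rng = np.random.default_rng(spec.seed)
    backbone = make_backbone(spec.n_residues, spec.geometry)
    sigma = spec.sigma_array()
    M, N = spec.n_models, spec.n_residues
    disp = rng.normal(size=(M, N, 3)) * sigma[None, :, None]
    pre = backbone.coords[None, :, :] + disp  # (M, N, 3)

    mean = pre.mean(axis=0)
    oracle = np.sqrt(np.mean(np.sum((pre - mean[None]) ** 2, axis=2), axis=0))

    conformers = []
    for j in range(M):
        R, t = _random_rigid(rng, spec.max_rotation_deg, spec.max_translation)
        coords = pre[j] @ R.T + t
        conformers.append(Conformer(j + 1, coords, backbone.residues))
    ensemble = Ensemble(conformers, source_label="synthetic")
    profile = FluctuationProfile(
        residues=backbone.residues,
        rmsf=oracle,
        ensemble_size=M,
        label="oracle",
    )
    return ensemble, profile


# ---------------------------------------------------------------------------
# benchmark-table construction with exact summary statistics


_SKEW_POWERS = (1.0, 1.5, 2.0, 3.0, 4.0, 6.0)


def _skew_z(k: int, power: float, flip: bool) -> np.ndarray:
    """Deterministic standardized pattern (mean 0, sample SD 1).

    ``power=1`` gives a symmetric linspace; larger powers concentrate
    most points on one side with a long tail on the other, which lets a
    large SD fit inside an asymmetric value range. ``flip`` mirrors the
    tail direction.
    """
    if k == 1:
        return np.zeros(1)
    g = -(np.linspace(0.0, 1.0, k) ** power)
    if flip:
        g = -g
    return (g - g.mean()) / g.std(ddof=1)


def _best_sd_cap(k: int, room_lo: float, room_hi: float):
    """Largest sample SD placeable in [mean−room_lo, mean+room_hi].

    Searches the skew-pattern family; returns (cap, power, flip).
    """
    if k == 1 or min(room_lo, room_hi) < 0:
        return 0.0, 1.0, False
    best = (0.0, 1.0, False)
    for p in _SKEW_POWERS:
        for flip in (False, True):
            z = _skew_z(k, p, flip)
            cap = min(
                room_hi / z.max() if z.max() > 0 else np.inf,
                room_lo / -z.min() if z.min() < 0 else np.inf,
            )
            if cap > best[0]:
                best = (cap, p, flip)
    return best


def _bounded_pattern(
    k: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """k values within [lo, hi] with exactly the given mean and sample SD."""
    if k == 1:
        if not lo <= mean <= hi:
            raise ValueError("singleton mean outside bounds")
        return np.array([mean])
    cap, power, flip = _best_sd_cap(k, mean - lo, hi - mean)
    if sd > cap * (1 + 1e-12):
        raise ValueError(
            f"cannot place SD {sd:.4g} inside [{lo}, {hi}] around {mean:.4g}"
        )
    return mean + sd * _skew_z(k, power, flip)


def _rs_column(
    k_pl: int,
    k_ph: int,
    k_ol: int,
    k_oh: int,
    overall_mean: float,
    overall_sd: float,
    high_mean: float,
    poor_mean: float,
    poor_sd: float,
    poor_threshold: float | None,
    lo: float = -1.0,
    hi: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """r_s values for groups (poor-low, poor-high, ok-low, ok-high).

    Group means are solved so the overall and high-subset means come out
    exactly; within-group spreads are chosen so the overall sample SD is
    exact. When ``poor_threshold`` is given (the column that *defines*
    the poor subset), poor-group values stay strictly below it and
    ok-group values at or above it.
    """
    n = k_pl + k_ph + k_ol + k_oh
    n_low, n_high = k_pl + k_ol, k_ph + k_oh
    low_mean = (n * overall_mean - n_high * high_mean) / n_low
    ol_mean = (n_low * low_mean - k_pl * poor_mean) / k_ol
    oh_mean = (n_high * high_mean - k_ph * poor_mean) / k_oh

    if poor_threshold is not None:
        poor_hi = poor_threshold - 1e-6
        ok_lo = poor_threshold
    else:
        poor_hi = hi
        ok_lo = lo

    means = {"pl": poor_mean, "ph": poor_mean, "ol": ol_mean, "oh": oh_mean}
    ks = {"pl": k_pl, "ph": k_ph, "ol": k_ol, "oh": k_oh}
    ss_between = sum(
        ks[g] * (means[g] - overall_mean) ** 2 for g in means if ks[g] > 0
    )
    ss_total = overall_sd**2 * (n - 1)
    ss_poor = poor_sd**2 * (max(k_pl - 1, 0) + max(k_ph - 1, 0))
    ss_within_ok = ss_total - ss_between - ss_poor
    if ss_within_ok < -1e-9:
        raise ValueError(
            "requested overall SD is smaller than the between-group spread"
        )
    ss_within_ok = max(ss_within_ok, 0.0)

    # split ok-group SS proportional to df, then honour range caps
    cap_ol = _best_sd_cap(k_ol, ol_mean - ok_lo, hi - ol_mean)[0]
    cap_oh = _best_sd_cap(k_oh, oh_mean - ok_lo, hi - oh_mean)[0]
    df_ol, df_oh = k_ol - 1, k_oh - 1
    ss_ol = ss_within_ok * df_ol / (df_ol + df_oh)
    ss_oh = ss_within_ok - ss_ol
    max_ol, max_oh = cap_ol**2 * df_ol, cap_oh**2 * df_oh
    if ss_oh > max_oh:
        ss_ol += ss_oh - max_oh
        ss_oh = max_oh
    if ss_ol > max_ol:
        ss_oh += ss_ol - max_ol
        ss_ol = max_ol
    if ss_oh > max_oh * (1 + 1e-9):
        raise ValueError("cannot realize requested SD within r_s bounds")
    sd_ol = np.sqrt(ss_ol / df_ol) if df_ol else 0.0
    sd_oh = np.sqrt(ss_oh / df_oh) if df_oh else 0.0

    def poor_vals(k):
        if k == 0:
            return np.empty(0)
        return _bounded_pattern(k, poor_mean, poor_sd if k > 1 else 0.0, lo, poor_hi)

    return (
        poor_vals(k_pl),
        poor_vals(k_ph),
        _bounded_pattern(k_ol, ol_mean, sd_ol, ok_lo, hi),
        _bounded_pattern(k_oh, oh_mean, sd_oh, ok_lo, hi),
    )


def _variability_column(
    k_pl: int,
    k_ph: int,
    k_ol: int,
    k_oh: int,
    overall_mean: float,
    threshold: float,
    poor_low_max: float = 0.45,
    floor: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NMR-variability values (Å): exact overall mean, exact subset split.

    Low-subset values sit in [floor, threshold] (poor proteins below
    ``poor_low_max``, emulating near-rigid ensembles); high-subset values
    exceed the threshold with a right-skewed spread reaching ~12 Å, the
    shape seen in real ensemble variabilities.
    """
    n = k_pl + k_ph + k_ol + k_oh
    pl = np.linspace(floor + 0.05, poor_low_max, k_pl) if k_pl else np.empty(0)
    ol = np.linspace(floor, threshold, k_ol) if k_ol else np.empty(0)
    ph = np.full(k_ph, threshold + 0.3)
    target_sum = overall_mean * n
    oh_sum = target_sum - pl.sum() - ol.sum() - ph.sum()
    base = threshold + 0.05
    if oh_sum <= base * k_oh:
        raise ValueError("overall mean too small for the requested split")
    ramp = np.linspace(0.0, 1.0, k_oh) ** 6  # right-skewed tail
    oh = base + ramp * (oh_sum - base * k_oh) / ramp.sum()
    return pl, ph, ol, oh


def make_benchmark_table(
    n_proteins: int = 140,
    n_low: int = 60,
    n_poor: int = 10,
    n_poor_high: int = 1,
    mean_rs_cabs: float = 0.72,
    sd_rs_cabs: float = 0.15,
    mean_rs_md: float = 0.64,
    sd_rs_md: float = 0.23,
    high_mean_rs_cabs: float = 0.78,
    high_mean_rs_md: float = 0.69,
    poor_mean_rs_cabs: float = 0.35,
    poor_mean_rs_md: float = 0.26,
    mean_variability: float = 1.68,
    variability_threshold: float = 1.0,
    poor_threshold: float = 0.5,
    seed: int = 0,
) -> tuple[list[BenchmarkRecord], dict]:
    """Construct a benchmark table with exactly known summary statistics.

    Proteins fall into four groups: poor-prediction proteins (prediction
    r_s below ``poor_threshold``; all but ``n_poor_high`` of them in the
    low-variability subset, emulating over-rigid reference ensembles) and
    ordinary proteins in each variability subset. Values are laid down by
    deterministic mean/SD-exact patterns — the seed only shuffles the row
    order and names — so the returned ``summary`` dict (means, SDs,
    counts, fractions) holds to machine precision.
    """
    n_high = n_proteins - n_low
    k_pl = n_poor - n_poor_high
    k_ph = n_poor_high
    k_ol = n_low - k_pl
    k_oh = n_high - k_ph
    if min(k_pl, k_ol, k_oh) < 0 or k_ph < 0 or n_high <= 0:
        raise ValueError("inconsistent group sizes")

    cabs = _rs_column(
        k_pl, k_ph, k_ol, k_oh,
        mean_rs_cabs, sd_rs_cabs, high_mean_rs_cabs,
        poor_mean_rs_cabs, 0.08, poor_threshold,
    )
    md = _rs_column(
        k_pl, k_ph, k_ol, k_oh,
        mean_rs_md, sd_rs_md, high_mean_rs_md,
        poor_mean_rs_md, 0.10, poor_threshold=None,
    )
    var = _variability_column(
        k_pl, k_ph, k_ol, k_oh, mean_variability, variability_threshold
    )

    groups = ("pl", "ph", "ol", "oh")
    records: list[BenchmarkRecord] = []
    idx = 0
    for g, c_vals, m_vals, v_vals in zip(groups, cabs, md, var):
        for c, m, v in zip(c_vals, m_vals, v_vals):
            idx += 1
            # uncalibrated companion columns: plausible, not asserted on
            rs_cabs_md = float(np.clip(0.5 * (c + m) + 0.1, -1.0, 1.0))
            records.append(
                BenchmarkRecord(
                    protein_id=f"syn{idx:04d}",
                    rs_cabs_nmr=float(c),
                    rs_md_nmr=float(m),
                    rs_cabs_md=rs_cabs_md,
                    rmsd_cabs_nmr=round(0.25 + 0.30 * v, 4),
                    rmsd_md_nmr=round(0.30 + 0.35 * v, 4),
                    rmsd_cabs_md=round(0.20 + 0.25 * v, 4),
                    nmr_variability=float(v),
                )
            )

    rng = np.random.default_rng(seed)
    rng.shuffle(records)

    summary = {
        "n_total": n_proteins,
        "n_low": n_low,
        "n_high": n_high,
        "mean_rs_cabs_nmr": mean_rs_cabs,
        "sd_rs_cabs_nmr": sd_rs_cabs,
        "mean_rs_md_nmr": mean_rs_md,
        "sd_rs_md_nmr": sd_rs_md,
        "high_mean_rs_cabs_nmr": high_mean_rs_cabs,
        "high_mean_rs_md_nmr": high_mean_rs_md,
        "low_mean_rs_cabs_nmr": (
            (n_proteins * mean_rs_cabs - n_high * high_mean_rs_cabs) / n_low
        ),
        "low_mean_rs_md_nmr": (
            (n_proteins * mean_rs_md - n_high * high_mean_rs_md) / n_low
        ),
        "poor_count": n_poor,
        "poor_mean_rs_cabs_nmr": poor_mean_rs_cabs,
        "poor_mean_rs_md_nmr": poor_mean_rs_md,
        "mean_variability": mean_variability,
        "fraction_high": n_high / n_proteins,
    }
    return records, summary
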