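"""Benchmark-level aggregation of per-protein profile comparisons.

Each protein contributes one row: Spearman r_s and profile RMSD for each
method pair (coarse-grained prediction vs NMR, MD vs NMR, prediction vs
MD), plus the NMR ensemble's average displacement per residue. The
aggregate reports per-pair means ± SD over the whole set, the same means
after stratifying proteins into low-variability (average displacement
≤ threshold, default 1 Å) and high-variability (> threshold) subsets,
and the "poor-prediction" subset of proteins whose prediction-vs-NMR
r_s falls below a cutoff (default 0.5).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as fio
from .comparison import compare_profiles
from .fluctuation import average_displacement, rmsf_profile
from .superposition import superpose_ensemble

__all__ = [
    "BenchmarkRecord",
    "SubsetStats",
    "BenchmarkSummary",
    "ProteinInput",
    "read_benchmark_table",
    "write_benchmark_table",
    "aggregate",
    "run_benchmark",
]

PAIRS = ("cabs_nmr", "md_nmr", "cabs_md")

_RS_COLS = {p: f"rs_{p}" for p in PAIRS}
_RMSD_COLS = {p: f"rmsd_{p}" for p in PAIRS}


@dataclass
class BenchmarkRecord:
    """One protein's comparison row; any metric may be absent (None)."""

    protein_id: str
    rs_cabs_nmr: float | None = None
    rs_md_nmr: float | None = None
    rs_cabs_md: float | None = None
    rmsd_cabs_nmr: float | None = None
    rmsd_md_nmr: float | None = None
    rmsd_cabs_md: float | None = None
    nmr_variability: float | None = None

    def __post_init__(self) -> None:
        for p in PAIRS:
            v = getattr(self, f"rs_{p}")
            if v is not None and not -1.0 <= v <= 1.0:
                raise ValueError(f"rs_{p}={v} outside [-1, 1]")
        if self.nmr_variability is not None and self.nmr_variability < 0:
            raise ValueError("nmr_variability must be >= 0")


@dataclass
class SubsetStats:
    count: int
    mean_rs: dict[str, float]  # per pair; NaN when no data
    sd_rs: dict[str, float]


@dataclass
class BenchmarkSummary:
    n_total: int
    mean_rs: dict[str, float]
    sd_rs: dict[str, float]
    mean_rmsd: dict[str, float]
    mean_variability: float
    variability_threshold: float
    subset_low: SubsetStats
    subset_high: SubsetStats
    fraction_high: float  # of records with variability present
    poor_threshold: float
    poor_ids: list[str] = field(default_factory=list)
    poor_mean_rs: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def f(d):
            return {k: (None if math.isnan(v) else v) for k, v in d.items()}

        return {
            "n_total": self.n_total,
            "mean_rs": f(self.mean_rs),
            "sd_rs": f(self.sd_rs),
            "mean_rmsd": f(self.mean_rmsd),
            "mean_variability": self.mean_variability,
            "variability_threshold": self.variability_threshold,
            "subset_low": {
                "count": self.subset_low.count,
                "mean_rs": f(self.subset_low.mean_rs),
                "sd_rs": f(self.subset_low.sd_rs),
            },
            "subset_high": {
                "count": self.subset_high.count,
                "mean_rs": f(self.subset_high.mean_rs),
                "sd_rs": f(self.subset_high.sd_rs),
            },
            "fraction_high": self.fraction_high,
            "poor_threshold": self.poor_threshold,
            "poor_ids": list(self.poor_ids),
            "poor_mean_rs": f(self.poor_mean_rs),
        }

    def render_text(self) -> str:
        """Three-row, three-column text table of mean r_s (SD in brackets)."""
        rows = {
            "cabs_nmr": "CABS-flex vs NMR",
            "md_nmr": "MD vs NMR",
            "cabs_md": "CABS-flex vs MD",
        }
        thr = self.variability_threshold

        def cell(m, s):
            if math.isnan(m):
                return "-"
            return f"{m:.2f} ({s:.2f})" if not math.isnan(s) else f"{m:.2f}"

        lines = [
            "Average Spearman correlation r_s between residue-fluctuation profiles",
            f"{'Compared methods':<20}"
            f"{'Entire set (n=%d)' % self.n_total:<22}"
            f"{'<=%.4g A (n=%d)' % (thr, self.subset_low.count):<20}"
            f"{'>%.4g A (n=%d)' % (thr, self.subset_high.count):<20}",
        ]
        for pair, name in rows.items():
            lines.append(
                f"{name:<20}"
                f"{cell(self.mean_rs[pair], self.sd_rs[pair]):<22}"
                f"{cell(self.subset_low.mean_rs[pair], self.subset_low.sd_rs[pair]):<20}"
                f"{cell(self.subset_high.mean_rs[pair], self.subset_high.sd_rs[pair]):<20}"
            )
        return "\n".join(lines)


def _opt(v) -> float | None:
    if v is None:
        return None
    if isinstance(v, str) and v.strip() == "":
        return None
    v = float(v)
    return None if math.isnan(v) else v


def read_benchmark_table(path: str | os.PathLike) -> list[BenchmarkRecord]:
    """Read a per-protein benchmark table (CSV/TSV, any column order).

    Requires a ``protein_id`` column; metric columns are optional and
    empty cells become absent fields.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if "protein_id" not in df.columns:
        raise ValueError("benchmark table lacks a protein_id column")
    ids = df["protein_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate protein ids: {dupes}")
    records = []
    for _, row in df.iterrows():
        kwargs = {"protein_id": str(row["protein_id"])}
        for col in list(_RS_COLS.values()) + list(_RMSD_COLS.values()) + [
            "nmr_variability"
        ]:
            if col in df.columns:
                kwargs[col] = _opt(row[col])
        records.append(BenchmarkRecord(**kwargs))
    if not records:
        raise ValueError("empty benchmark table")
    return records


def write_benchmark_table(
    records: list[BenchmarkRecord], path: str | os.PathLike
) -> None:
    cols = (
        ["protein_id"]
        + list(_RS_COLS.values())
        + list(_RMSD_COLS.values())
        + ["nmr_variability"]
    )
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    df.to_csv(path, index=False)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
    return mean, sd


def aggregate(
    records: list[BenchmarkRecord],
    variability_threshold: float = 1.0,
    poor_threshold: float = 0.5,
) -> BenchmarkSummary:
    """Aggregate per-protein rows into the stratified benchmark summary.

    Missing fields are excluded pairwise: each method pair's mean runs
    over the records where that pair is present. The low-variability
    subset is inclusive (≤ threshold). The poor subset collects proteins
    with prediction-vs-NMR r_s strictly below ``poor_threshold``.
    SDs use the sample (n−1) estimator.
    """
    if not records:
        raise ValueError("no records to aggregate")

    mean_rs, sd_rs, mean_rmsd = {}, {}, {}
    for p in PAIRS:
        vals = [getattr(r, f"rs_{p}") for r in records]
        vals = [v for v in vals if v is not None]
        mean_rs[p], sd_rs[p] = _mean_sd(vals)
        rvals = [getattr(r, f"rmsd_{p}") for r in records]
        mean_rmsd[p], _ = _mean_sd([v for v in rvals if v is not None])

    with_var = [r for r in records if r.nmr_variability is not None]
    low = [r for r in with_var if r.nmr_variability <= variability_threshold]
    high = [r for r in with_var if r.nmr_variability > variability_threshold]

    def subset_stats(subset) -> SubsetStats:
        m, s = {}, {}
        for p in PAIRS:
            vals = [getattr(r, f"rs_{p}") for r in subset]
            m[p], s[p] = _mean_sd([v for v in vals if v is not None])
        return SubsetStats(count=len(subset), mean_rs=m, sd_rs=s)

    var_vals = [r.nmr_variability for r in with_var]
    mean_var = float(np.mean(var_vals)) if var_vals else math.nan
    fraction_high = len(high) / len(with_var) if with_var else math.nan

    poor = [
        r
        for r in records
        if r.rs_cabs_nmr is not None and r.rs_cabs_nmr < poor_threshold
    ]
    poor_mean = {}
    for p in PAIRS:
        vals = [getattr(r, f"rs_{p}") for r in poor]
        poor_mean[p], _ = _mean_sd([v for v in vals if v is not None])

    return BenchmarkSummary(
        n_total=len(records),
        mean_rs=mean_rs,
        sd_rs=sd_rs,
        mean_rmsd=mean_rmsd,
        mean_variability=mean_var,
        variability_threshold=variability_threshold,
        subset_low=subset_stats(low),
        subset_high=subset_stats(high),
        fraction_high=fraction_high,
        poor_threshold=poor_threshold,
        poor_ids=[r.protein_id for r in poor],
        poor_mean_rs=poor_mean,
    )


@dataclass
class ProteinInput:
    """Paths for one protein: a reference NMR ensemble plus predictions.

    Prediction paths may be multi-model PDB ensembles or profile CSVs
    (dispatched on extension: ``.csv`` → profile table).
    """

    protein_id: str
    nmr_path: str
    cabs_path: str | None = None
    md_path: str | None = None


def _load_profile(path: str, label: str, mode: str):
    if str(path).endswith(".csv"):
        return fio.read_profile_table(path, label=label)
    ens = fio.read_multimodel_pdb(path, source_label=label)
    if ens.n_models == 1:
        return rmsf_profile(ens, label=label)
    return rmsf_profile(superpose_ensemble(ens, mode=mode), label=label)


def run_benchmark(
    inputs: list[ProteinInput],
    mode: str = "inverse_variance",
    renumber: bool = False,
) -> tuple[list[BenchmarkRecord], list[str]]:
    """Run the full per-protein pipeline over a set of proteins.

    read → superpose → RMSF profile → pairwise comparisons → one record
    per protein. Per-protein failures are logged and skipped, never
    fatal; returns ``(records, failure_messages)``.
    """
    records: list[BenchmarkRecord] = []
    failures: list[str] = []
    for item in inputs:
        try:
            nmr = _load_profile(item.nmr_path, "NMR", mode)
            profiles = {"nmr": nmr}
            if item.cabs_path is not None:
                profiles["cabs"] = _load_profile(item.cabs_path, "CABS", mode)
            if item.md_path is not None:
                profiles["md"] = _load_profile(item.md_path, "MD", mode)
            kwargs: dict = {
                "protein_id": item.protein_id,
                "nmr_variability": average_displacement(nmr),
            }
            pairs = [("cabs", "nmr"), ("md", "nmr"), ("cabs", "md")]
            for a, b in pairs:
                if a in profiles and b in profiles:
                    cmp_ = compare_profiles(
                        profiles[a], profiles[b], renumber=renumber
                    )
                    rs = cmp_.r_s if cmp_.rs_defined else None
                    kwargs[f"rs_{a}_{b}"] = rs
                    kwargs[f"rmsd_{a}_{b}"] = cmp_.profile_rmsd
            records.append(BenchmarkRecord(**kwargs))
        except (ValueError, OSError) as exc:
            failures.append(f"{item.protein_id}: {exc}")
    return records, failures
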