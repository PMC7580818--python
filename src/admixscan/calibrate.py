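"""Simulation-derived critical values and demographic-model checks.

Genome scans need a significance threshold that respects the
population's demography: the same |iHS| that is unremarkable in a
bottlenecked or admixed population can be extreme in an equilibrium
one.  This module builds empirical null distributions of a statistic
from seeded neutral simulations, extracts percentile critical values
(99.99th by default), and provides the derived-SFS comparison used to
check that the simulated demography matches the data it calibrates.
Two population classes are distinguished, mirroring the admixed /
unadmixed study design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import genome_io, ihs_scan
from .haplotypes import HaplotypeSet
from .simulate import DEFAULT_MU, DEFAULT_R, DemographicModel, simulate_neutral


@dataclass
class Thresholds:
    """A critical value for one statistic in one population class."""

    statistic: str            # "sfselect" | "ihs_snp" | "ihs_window"
    population_class: str     # "admixed" | "unadmixed"
    q: float                  # percentile in (0, 100)
    value: float
    provenance: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)

    @classmethod
    def load(cls, path) -> "Thresholds":
        with open(path) as fh:
            return cls(**json.load(fh))


def percentile_threshold(
    null_sample: np.ndarray,
    q: float = 99.99,
    *,
    statistic: str = "statistic",
    population_class: str = "unadmixed",
    provenance: dict | None = None,
) -> Thresholds:
    """Linear-interpolation percentile of an empirical null sample.

    Warns when the sample is too small to resolve the requested tail
    (fewer than ``100 / (100 - q)`` values).
    """
    null_sample = np.asarray(null_sample, dtype=float)
    null_sample = null_sample[np.isfinite(null_sample)]
    if len(null_sample) == 0:
        raise ValueError("empty null sample")
    if not 0 < q < 100:
        raise ValueError("percentile q must lie in (0, 100)")
    recommended = 100.0 / (100.0 - q)
    if len(null_sample) < recommended:
        warnings.warn(
            f"null sample of {len(null_sample)} values is small for the "
            f"{q}th percentile (>= {recommended:.0f} recommended)",
            stacklevel=2,
        )
    value = float(np.percentile(null_sample, q, method="linear"))
    prov = {"n": len(null_sample), "percentile_method": "linear"}
    if provenance:
        prov.update(provenance)
    return Thresholds(
        statistic=statistic, population_class=population_class,
        q=q, value=value, provenance=prov,
    )


def neutral_null(
    statistic: Callable[[HaplotypeSet], np.ndarray],
    model: DemographicModel,
    n_units: int,
    *,
    n_hap: int = 46,
    chunk_length: int = 2_000_000,
    mu: float = DEFAULT_MU,
    r: float = DEFAULT_R,
    seed: int = 1,
    max_chunks: int = 10_000,
) -> np.ndarray:
    """Pool statistic values from seeded neutral replicates until ``n_units``.

    ``statistic`` maps a HaplotypeSet to an array of per-unit values
    (per SNP or per window).  Replicates are simulated with child seeds
    derived from ``seed`` and pooled into one null sample.
    """
    if n_units <= 0:
        raise ValueError("n_units must be positive")
    rng = np.random.default_rng(seed)
    values: list[np.ndarray] = []
    total = 0
    for _ in range(max_chunks):
        child = int(rng.integers(1, 2**31 - 1))
        haps, _ = simulate_neutral(
            model, n_hap, chunk_length, mu=mu, r=r, seed=child
        )
        v = np.asarray(statistic(haps), dtype=float)
        v = v[np.isfinite(v)]
        values.append(v)
        total += len(v)
        if total >= n_units:
            break
    return np.concatenate(values) if values else np.empty(0)


def neutral_ihs_null(
    model: DemographicModel,
    *,
    n_hap: int = 46,
    n_chunks: int = 20,
    chunk_length: int = 5_000_000,
    mu: float = DEFAULT_MU,
    r: float = DEFAULT_R,
    seed: int = 1,
    maf: float = 0.05,
    window_spec: genome_io.WindowSpec = genome_io.WindowSpec(),
    n_bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Neutral null of per-SNP |iHS| and 30 kb-window mean |iHS|.

    Simulates ``n_chunks`` replicate chromosomes, computes
    unstandardized iHS per chunk, standardizes the pooled records in
    derived-frequency bins (as a genome-wide scan would), then
    aggregates per chunk into sliding windows.  Returns
    ``(abs_snp_ihs, window_mean_abs, records)``.
    """
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(n_chunks):
        child = int(rng.integers(1, 2**31 - 1))
        haps, _ = simulate_neutral(
            model, n_hap, chunk_length, mu=mu, r=r, seed=child,
            chrom=f"rep{i}",
        )
        haps = genome_io.maf_filter(haps, maf)
        tables.append(ihs_scan.ihs_table(haps))
    records = pd.concat(tables, ignore_index=True)
    records = ihs_scan.standardize(records, n_bins=n_bins)
    records = ihs_scan.add_pvalues(records)
    abs_snp = records["ihs"].abs().dropna().to_numpy()
    window_means = []
    for i in range(n_chunks):
        chunk = records[records["chrom"] == f"rep{i}"]
        windows = genome_io.make_windows(chunk_length, window_spec, chrom=f"rep{i}")
        wtab = ihs_scan.window_ihs(chunk, windows)
        window_means.append(wtab.loc[wtab["n"] > 0, "mean_abs_ihs"].to_numpy())
    return abs_snp, np.concatenate(window_means), records


def call_candidates(
    scores: pd.DataFrame, thr: Thresholds, score_column: str
) -> pd.DataFrame:
    """Rows whose score strictly exceeds the critical value, sorted by score."""
    if score_column not in scores.columns:
        raise ValueError(f"score column {score_column!r} not in table")
    hits = scores[scores[score_column] > thr.value]
    return hits.sort_values(score_column, ascending=False).reset_index(drop=True)


@dataclass
class SFSComparison:
    """Relative derived SFS of two datasets and their L1 distance."""

    sfs_a: np.ndarray
    sfs_b: np.ndarray
    l1: float
    per_count_diff: np.ndarray


def relative_sfs(haps: HaplotypeSet) -> np.ndarray:
    """Proportion of segregating sites at each derived count 1..n-1."""
    counts = (haps.matrix == 1).sum(axis=0)
    seg = (counts > 0) & (counts < haps.n_hap)
    hist = np.bincount(counts[seg], minlength=haps.n_hap)[1:haps.n_hap]
    total = hist.sum()
    if total == 0:
        raise ValueError("no segregating sites")
    return hist / total


def compare_sfs(a: np.ndarray, b: np.ndarray) -> SFSComparison:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            "relative SFS vectors have different haplotype counts; "
            "projection is not supported"
        )
    diff = a - b
    return SFSComparison(a, b, float(np.abs(diff).sum()), diff)
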