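"""EHH, iHH and the integrated haplotype score (iHS) with window summaries.

The statistic follows the classic construction: for a core SNP, the
extended haplotype homozygosity (EHH) at distance ``d`` is the
probability that two random carriers of the core allele are identical
over the interval from the core out to ``d``.  iHH is the trapezoidal
integral of EHH against physical distance (no genetic map), summed over
both sides; the unstandardized score is ``ln(iHH_A / iHH_D)`` and is
standardized to mean 0 / SD 1 within derived-allele-frequency bins.
Extreme standardized scores flag unusually long haplotypes around one
of the core alleles, the footprint of a recent sweep.

Two rules prune unreliable cores: the EHH computation stops when EHH
falls below a cutoff (default 0.05), and a core is discarded entirely
if an inter-SNP gap larger than 20 kb is hit before that, or if the
curve runs into the chromosome end — both situations truncate the
integral in a way that biases the score.

The per-core scan is implemented twice: a readable numpy path
(:func:`ehh`, :func:`ihh`) that serves as the reference, and a numba
kernel (:func:`ihs_table`) used for genome-scale scans; the two are
held equal by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome_io import GenomicWindow
from .haplotypes import MISSING, HaplotypeSet

# curve / core status codes (shared by both implementations)
OK = 0            # EHH fell below the cutoff: integral complete
CHROM_END = 1     # ran into the chromosome end first
GAP = 2           # inter-SNP gap > max_gap first
TOO_FEW = 3       # < 2 carriers (or unmasked carriers exhausted)

_TRUNCATION_NAMES = {OK: "below-cutoff", CHROM_END: "chrom-end",
                     GAP: "gap", TOO_FEW: "too-few-carriers"}

DEFAULT_MAX_GAP = 20_000
DEFAULT_MIN_EHH = 0.05


class UndefinedEHHError(ValueError):
    """Raised when EHH is requested for an allele with < 2 carriers."""


@dataclass
class EHHCurve:
    """One-sided EHH decay curve from a core site."""

    core: int
    side: str                 # "left" | "right"
    offsets: np.ndarray       # bp distance from the core, starting at 0
    values: np.ndarray        # EHH, starting at 1.0
    truncation: str           # "below-cutoff" | "gap" | "chrom-end" | ...


def ehh(
    haps: HaplotypeSet,
    core: int,
    allele: int,
    side: str,
    *,
    max_gap: int = DEFAULT_MAX_GAP,
    min_ehh: float = DEFAULT_MIN_EHH,
) -> EHHCurve:
    """EHH decay curve for one core allele on one side (reference path).

    At each successive site the carriers are partitioned into groups of
    identical extended haplotypes; EHH is the fraction of carrier pairs
    still in the same group.  Haplotypes with a missing (masked) allele
    in the extension drop out of the pair count from that site onward.
    The curve records the first value below ``min_ehh`` and stops; a
    gap larger than ``max_gap`` or the chromosome end stop it early.
    """
    step = -1 if side == "left" else 1
    H, pos = haps.matrix, haps.positions
    carriers = np.where(H[:, core] == allele)[0]
    if len(carriers) < 2:
        raise UndefinedEHHError(
            f"allele {allele} at core {core} has {len(carriers)} carriers"
        )
    offsets = [0]
    values = [1.0]
    groups = np.zeros(len(carriers), dtype=np.int64)
    active = np.ones(len(carriers), dtype=bool)
    j = core
    truncation = OK
    while True:
        jn = j + step
        if jn < 0 or jn >= haps.n_site:
            truncation = CHROM_END
            break
        if abs(int(pos[jn]) - int(pos[j])) > max_gap:
            truncation = GAP
            break
        alleles = H[carriers, jn]
        active &= alleles != MISSING
        if active.sum() < 2:
            truncation = TOO_FEW
            break
        # refine groups by the allele at the new site
        pair_key = groups * 2 + alleles
        _, groups = np.unique(pair_key, return_inverse=True)
        n_act = int(active.sum())
        _, counts = np.unique(groups[active], return_counts=True)
        value = float((counts * (counts - 1)).sum() / (n_act * (n_act - 1)))
        offsets.append(abs(int(pos[jn]) - int(pos[core])))
        values.append(value)
        j = jn
        if value < min_ehh:
            break
    return EHHCurve(
        core=core, side=side,
        offsets=np.array(offsets), values=np.array(values),
        truncation=_TRUNCATION_NAMES[truncation],
    )


def ihh(left: EHHCurve, right: EHHCurve) -> float:
    """Integrated EHH: trapezoid against bp distance, summed over sides.

    A side truncated at the core (single recorded point) contributes 0.
    """
    if left.core != right.core:
        raise ValueError("curves do not share a core")
    total = 0.0
    for curve in (left, right):
        if len(curve.offsets) > 1:
            total += float(np.trapezoid(curve.values, curve.offsets))
    return total


# ---------------------------------------------------------------------------
# numba kernel used for genome-scale scans


@nb.njit(cache=True)
def _side_ihh_kernel(H, pos, core, allele, step, max_gap, min_ehh):  # pragma: no cover
    n_hap, n_site = H.shape
    car = np.empty(n_hap, np.int64)
    n = 0
    for h in range(n_hap):
        if H[h, core] == allele:
            car[n] = h
            n += 1
    if n < 2:
        return 0.0, TOO_FEW
    gid = np.zeros(n, np.int64)
    newgid = np.empty(n, np.int64)
    sizes = np.empty(n, np.int64)
    combo_g = np.empty(n, np.int64)
    combo_a = np.empty(n, np.int8)
    active = np.ones(n, np.uint8)
    n_act = n
    total = 0.0
    prev_ehh = 1.0
    j = core
    while True:
        jn = j + step
        if jn < 0 or jn >= n_site:
            return total, CHROM_END
        gap = pos[jn] - pos[j] if step > 0 else pos[j] - pos[jn]
        if gap > max_gap:
            return total, GAP
        n_groups = 0
        for k in range(n):
            if active[k] == 0:
                continue
            a = H[car[k], jn]
            if a < 0:
                active[k] = 0
                n_act -= 1
                continue
            found = -1
            for c in range(n_groups):
                if combo_g[c] == gid[k] and combo_a[c] == a:
                    found = c
                    break
            if found < 0:
                combo_g[n_groups] = gid[k]
                combo_a[n_groups] = a
                found = n_groups
                n_groups += 1
            newgid[k] = found
        if n_act < 2:
            return total, TOO_FEW
        for c in range(n_groups):
            sizes[c] = 0
        for k in range(n):
            if active[k]:
                gid[k] = newgid[k]
                sizes[gid[k]] += 1
        pairs = 0.0
        for c in range(n_groups):
            pairs += sizes[c] * (sizes[c] - 1)
        value = pairs / (n_act * (n_act - 1))
        total += 0.5 * (prev_ehh + value) * gap
        prev_ehh = value
        j = jn
        if value < min_ehh:
            return total, OK


@nb.njit(cache=True)
def _ihs_kernel(H, pos, cores, max_gap, min_ehh, discard_border):  # pragma: no cover
    m = len(cores)
    ihh_a = np.full(m, np.nan)
    ihh_d = np.full(m, np.nan)
    status = np.zeros(m, np.int8)
    for i in range(m):
        c = cores[i]
        bad = 0
        for allele in range(2):
            tot = 0.0
            for step in (-1, 1):
                s_ihh, s_stat = _side_ihh_kernel(
                    H, pos, c, allele, step, max_gap, min_ehh
                )
                tot += s_ihh
                if s_stat == GAP or s_stat == TOO_FEW:
                    bad = s_stat
                elif s_stat == CHROM_END and discard_border and bad == 0:
                    bad = CHROM_END
            if allele == 0:
                ihh_a[i] = tot
            else:
                ihh_d[i] = tot
        status[i] = bad
    return ihh_a, ihh_d, status


def ihs_table(
    haps: HaplotypeSet,
    *,
    maf: float = 0.05,
    max_gap: int = DEFAULT_MAX_GAP,
    min_ehh: float = DEFAULT_MIN_EHH,
    min_hap: int = 20,
    discard_border: bool = True,
) -> pd.DataFrame:
    """Unstandardized iHS for every eligible SNP of one chromosome.

    Cores must pass the MAF filter, have >= 2 carriers of each allele
    and >= ``min_hap`` unmasked haplotypes.  Cores whose EHH curves hit
    a gap > ``max_gap`` (or, with ``discard_border``, the chromosome
    end) before decaying below ``min_ehh``, or whose integrals vanish,
    get ``uihs = NaN`` and are excluded from standardization.

    Returns a DataFrame with columns ``chrom, position, daf, ihh_a,
    ihh_d, uihs, status``.
    """
    p = haps.derived_freq()
    called = (haps.matrix != MISSING).sum(axis=0)
    n_derived = np.where(haps.matrix == 1, 1, 0).sum(axis=0)
    n_ancestral = called - n_derived
    with np.errstate(invalid="ignore"):
        eligible = (
            (np.minimum(p, 1 - p) > maf)
            & (n_derived >= 2) & (n_ancestral >= 2) & (called >= min_hap)
        )
    cores = np.where(np.nan_to_num(eligible))[0].astype(np.int64)
    ihh_a, ihh_d, status = _ihs_kernel(
        haps.matrix, haps.positions, cores,
        np.int64(max_gap), float(min_ehh), discard_border,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        uihs = np.log(ihh_a / ihh_d)
    valid = (status == OK) & (ihh_a > 0) & (ihh_d > 0)
    uihs = np.where(valid, uihs, np.nan)
    return pd.DataFrame({
        "chrom": haps.chrom,
        "position": haps.positions[cores],
        "daf": p[cores],
        "ihh_a": ihh_a,
        "ihh_d": ihh_d,
        "uihs": uihs,
        "status": status,
    })


def unstandardized_ihs(
    haps: HaplotypeSet,
    core: int,
    *,
    max_gap: int = DEFAULT_MAX_GAP,
    min_ehh: float = DEFAULT_MIN_EHH,
) -> float:
    """``ln(iHH_A / iHH_D)`` for one core via the reference EHH path."""
    integrals = []
    for allele in (0, 1):
        left = ehh(haps, core, allele, "left", max_gap=max_gap, min_ehh=min_ehh)
        right = ehh(haps, core, allele, "right", max_gap=max_gap, min_ehh=min_ehh)
        integrals.append(ihh(left, right))
    if integrals[0] <= 0 or integrals[1] <= 0:
        raise ValueError("iHH integral is zero; uiHS undefined at this core")
    return float(np.log(integrals[0] / integrals[1]))


def standardize(
    records: pd.DataFrame,
    *,
    n_bins: int = 50,
    min_per_bin: int = 10,
) -> pd.DataFrame:
    """Standardize uiHS within derived-allele-frequency bins.

    Frequencies in (0, 1) are split into ``n_bins`` equal-width bins;
    adjacent bins are merged left-to-right until each merged bin holds
    >= ``min_per_bin`` scored SNPs.  Within each bin
    ``ihs = (uihs - mean) / sd``; degenerate bins (sd = 0) leave their
    records unscored.  Adds ``bin`` and ``ihs`` columns.
    """
    out = records.copy()
    out["bin"] = -1
    out["ihs"] = np.nan
    scored = out["uihs"].notna()
    if scored.sum() == 0:
        return out
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    raw_bin = np.clip(np.digitize(out["daf"].to_numpy(), edges) - 1, 0, n_bins - 1)
    counts = np.bincount(raw_bin[scored], minlength=n_bins)
    # merge sparse bins into their right neighbour (last bin merges left)
    merged_id = np.arange(n_bins)
    acc = 0
    current = 0
    for b in range(n_bins):
        merged_id[b] = current
        acc += counts[b]
        if acc >= min_per_bin:
            current += 1
            acc = 0
    if acc > 0 and current > 0:   # leftover tail joins the previous merged bin
        merged_id[merged_id == current] = current - 1
    bin_of = merged_id[raw_bin]
    out["bin"] = bin_of
    for b in np.unique(bin_of[scored]):
        sel = scored & (bin_of == b)
        vals = out.loc[sel, "uihs"]
        sd = vals.std(ddof=0)
        if len(vals) < 2 or sd == 0:
            continue
        out.loc[sel, "ihs"] = (vals - vals.mean()) / sd
    return out


def ihs_pvalue(ihs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Gaussian p-value of a standardized score: ``2 * Phi(-|iHS|)``."""
    ihs = np.asarray(ihs, dtype=float)
    p = 2.0 * norm.sf(np.abs(ihs))
    with np.errstate(divide="ignore"):
        mlog10 = -np.log10(p)
    return p, mlog10


def add_pvalues(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    p, mlog10 = ihs_pvalue(out["ihs"].to_numpy())
    out["p"] = np.where(out["ihs"].notna(), p, np.nan)
    out["mlog10p"] = np.where(out["ihs"].notna(), mlog10, np.nan)
    return out


def window_ihs(records: pd.DataFrame, windows: list[GenomicWindow]) -> pd.DataFrame:
    """Per-window summaries of scored SNPs: mean |iHS|, max |iHS|, max -log10 p.

    Windows with no scored SNP are emitted with ``n = 0`` and NaN
    summaries.
    """
    scored = records[records["ihs"].notna()]
    pos = scored["position"].to_numpy()
    abs_ihs = scored["ihs"].abs().to_numpy()
    mlog10 = scored["mlog10p"].to_numpy() if "mlog10p" in scored else np.full(len(scored), np.nan)
    chroms = scored["chrom"].to_numpy()
    rows = []
    for w in windows:
        sel = (chroms == w.chrom) & (pos >= w.start) & (pos < w.end)
        n = int(sel.sum())
        rows.append({
            "chrom": w.chrom, "start": w.start, "end": w.end, "n": n,
            "mean_abs_ihs": float(abs_ihs[sel].mean()) if n else np.nan,
            "max_abs_ihs": float(abs_ihs[sel].max()) if n else np.nan,
            "max_mlog10p": float(np.nanmax(mlog10[sel])) if n else np.nan,
        })
    return pd.DataFrame(rows)
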