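"""Local ancestry assignment, masking, enrichment and imbalance detection.

Admixed haplotypes are mosaics of source ancestries.  This module
assigns ancestry on 20-SNP blocks by projecting each block onto the
principal axis separating two reference panels (an African and a
West-Eurasian surrogate), classifying to the nearer panel centroid and
smoothing labels by majority vote over adjacent blocks — a deliberately
simple stand-in for HMM-based deconvolution whose contract is tract
recovery on synthetic data.  Blocks labeled West-Eurasian are masked
(set to missing), and the per-SNP masked fraction becomes the local
ancestry-proportion track used for:

* the resampling test for ancestry enrichment among selected windows
  (draw |selected| windows 10^5 times, compare mean fractions), and
* detection of unbalanced-ancestry regions — long runs of windows whose
  ancestry fraction falls outside a resampling band around the
  genome-wide mean, candidate signals of post-admixture selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomicWindow
from .haplotypes import MISSING, HaplotypeSet
from .simulate import AFR_LABEL, WEA_LABEL

DEFAULT_BLOCK = 20       # SNPs per ancestry block
#: Blocks in the moving-average smoother.  A pulse ~100 generations old
#: leaves tracts of mean length ~1/(r t (1-f)) ~ 2 Mb; at typical
#: common-variant density a 20-SNP block spans ~15-20 kb, so 41 blocks
#: (~0.7 Mb) smooth well below the tract scale while pooling enough
#: blocks to make per-block evidence reliable.
DEFAULT_SMOOTH = 41
DEFAULT_RESAMPLES = 100_000


@dataclass
class AncestryAssignment:
    """Per (haplotype, block) ancestry labels with confidence scores."""

    labels: np.ndarray        # (n_hap, n_block) of {AFR_LABEL, WEA_LABEL}
    confidence: np.ndarray    # (n_hap, n_block) in [0, 1]
    block_bounds: np.ndarray  # (n_block + 1,) site-index boundaries
    haplotype_ids: list[str]

    @property
    def n_block(self) -> int:
        return self.labels.shape[1]

    def block_of_site(self, site: int) -> int:
        return int(np.searchsorted(self.block_bounds, site, side="right") - 1)


@dataclass
class MaskedHaplotypeSet:
    """Haplotypes with one ancestry masked, plus the per-SNP masked fraction."""

    haps: HaplotypeSet
    masked_fraction: np.ndarray   # per SNP, in [0, 1]
    target: str = WEA_LABEL


def _block_boundaries(n_site: int, block: int) -> np.ndarray:
    """Block edges; a terminal block with < ``block`` SNPs merges backward."""
    if n_site < block:
        return np.array([0, n_site])
    edges = list(range(0, n_site, block))
    if n_site - edges[-1] < block:
        edges.pop()
    edges.append(n_site)
    return np.array(edges)


def block_llr(
    query: HaplotypeSet,
    ref_afr: HaplotypeSet,
    ref_wea: HaplotypeSet,
    *,
    block: int = DEFAULT_BLOCK,
    pseudocount: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(haplotype, block) ancestry log-likelihood ratio.

    For each block the two reference panels define per-SNP allele
    frequencies (with a Laplace pseudocount); the score of a query
    haplotype is the log-likelihood ratio of its block alleles under
    the West-Eurasian vs the African frequencies — a linear projection
    of the block onto the axis of per-SNP log odds ratios.  Positive
    scores favour West-Eurasian ancestry.  Masked alleles contribute 0.

    Returns ``(scores, block_bounds)``.
    """
    for ref, name in ((ref_afr, "African"), (ref_wea, "West-Eurasian")):
        if not np.array_equal(ref.positions, query.positions):
            raise ValueError(f"{name} reference panel site set differs from query")
        if ref.n_hap < 10:
            raise ValueError(f"{name} reference panel has < 10 haplotypes")
    bounds = _block_boundaries(query.n_site, block)
    n_block = len(bounds) - 1
    fa = (ref_afr.matrix == 1).sum(axis=0)
    fw = (ref_wea.matrix == 1).sum(axis=0)
    na = (ref_afr.matrix != MISSING).sum(axis=0)
    nw = (ref_wea.matrix != MISSING).sum(axis=0)
    pa = (fa + pseudocount) / (na + 2 * pseudocount)
    pw = (fw + pseudocount) / (nw + 2 * pseudocount)
    w_der = np.log(pw) - np.log(pa)
    w_anc = np.log1p(-pw) - np.log1p(-pa)
    der = query.matrix == 1
    anc = query.matrix == 0
    per_site = der * w_der + anc * w_anc
    scores = np.empty((query.n_hap, n_block))
    for b in range(n_block):
        scores[:, b] = per_site[:, bounds[b]:bounds[b + 1]].sum(axis=1)
    return scores, bounds


def assign_local_ancestry(
    query: HaplotypeSet,
    ref_afr: HaplotypeSet,
    ref_wea: HaplotypeSet,
    *,
    block: int = DEFAULT_BLOCK,
    smooth_k: int = DEFAULT_SMOOTH,
) -> AncestryAssignment:
    """Classify each 20-SNP block of each query haplotype by ancestry.

    Block scores from :func:`block_llr` are smoothed with a centered
    moving average over ``smooth_k`` adjacent blocks (shrunk at the
    chromosome ends) and each block takes the label of the smoothed
    score's sign.  Confidence is ``tanh(|smoothed score| / 2)``, i.e. 0
    where the evidence is balanced and approaching 1 where it is
    overwhelming.
    """
    scores, bounds = block_llr(query, ref_afr, ref_wea, block=block)
    n_block = len(bounds) - 1
    if smooth_k > 1 and n_block > 1:
        half = smooth_k // 2
        smoothed = np.empty_like(scores)
        for b in range(n_block):
            lo, hi = max(0, b - half), min(n_block, b + half + 1)
            smoothed[:, b] = scores[:, lo:hi].mean(axis=1)
    else:
        smoothed = scores
    labels = np.where(smoothed > 0, WEA_LABEL, AFR_LABEL).astype(object)
    confidence = np.tanh(np.abs(smoothed) / 2.0)
    return AncestryAssignment(
        labels=labels, confidence=confidence, block_bounds=bounds,
        haplotype_ids=list(query.haplotype_ids),
    )


def mask(
    haps: HaplotypeSet,
    assignment: AncestryAssignment,
    target: str = WEA_LABEL,
) -> MaskedHaplotypeSet:
    """Set all sites of target-labeled blocks to MISSING."""
    if assignment.labels.shape[0] != haps.n_hap or assignment.block_bounds[-1] != haps.n_site:
        raise ValueError("assignment does not cover the haplotype set")
    matrix = haps.matrix.copy()
    bounds = assignment.block_bounds
    for b in range(assignment.n_block):
        lo, hi = bounds[b], bounds[b + 1]
        rows = assignment.labels[:, b] == target
        matrix[np.ix_(rows, range(lo, hi))] = MISSING
    masked = HaplotypeSet(
        chrom=haps.chrom, positions=haps.positions.copy(), matrix=matrix,
        haplotype_ids=list(haps.haplotype_ids),
        metadata={**haps.metadata, "masked": target},
    )
    fraction = (matrix == MISSING).sum(axis=0) / haps.n_hap
    return MaskedHaplotypeSet(haps=masked, masked_fraction=fraction, target=target)


def ancestry_proportion(
    masked: MaskedHaplotypeSet, region: GenomicWindow | None = None
) -> float:
    """Mean per-SNP masked fraction over a region (whole set if None).

    NaN when the region contains no SNP.
    """
    frac = masked.masked_fraction
    if region is not None:
        pos = masked.haps.positions
        sel = (pos >= region.start) & (pos < region.end)
        frac = frac[sel]
    if len(frac) == 0:
        return float("nan")
    return float(frac.mean())


def window_ancestry_track(
    masked: MaskedHaplotypeSet, windows: list[GenomicWindow]
) -> np.ndarray:
    """Per-window mean masked fraction (NaN for SNP-less windows)."""
    return np.array([ancestry_proportion(masked, w) for w in windows])


def merge_selected(windows: list[GenomicWindow]) -> list[GenomicWindow]:
    """Merge overlapping or book-ended windows into maximal intervals."""
    if not windows:
        return []
    swin = sorted(windows)
    merged = [swin[0]]
    for w in swin[1:]:
        last = merged[-1]
        if w.chrom == last.chrom and w.start <= last.end:
            if w.end > last.end:
                merged[-1] = GenomicWindow(last.chrom, last.start, w.end)
        else:
            merged.append(w)
    return merged


@dataclass
class EnrichmentResult:
    """Resampling test for ancestry enrichment among selected windows."""

    observed_mean: float
    n_resamples: int
    null_mean: float
    null_sd: float
    p: float
    with_replacement: bool = False
    provenance: dict = field(default_factory=dict)


def enrichment_resampling(
    track: np.ndarray,
    selected: np.ndarray,
    *,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 1,
    with_replacement: bool = False,
) -> EnrichmentResult:
    """One-sided resampling test: is ancestry higher in selected windows?

    Draws ``|selected|`` windows ``n_resamples`` times from the
    genome-wide track, forming a null distribution of mean fractions;
    the empirical p-value is ``(#null >= observed + 1) / (n + 1)``.
    """
    track = np.asarray(track, dtype=float)
    selected = np.asarray(selected, dtype=int)
    if len(selected) == 0:
        raise ValueError("selected window set is empty")
    if len(selected) > len(track):
        raise ValueError("more selected windows than windows in the track")
    valid = np.isfinite(track)
    observed = float(track[selected][np.isfinite(track[selected])].mean())
    pool = np.where(valid)[0]
    k = len(selected)
    rng = np.random.default_rng(seed)
    if with_replacement:
        draws = rng.choice(pool, size=(n_resamples, k), replace=True)
        null_means = track[draws].mean(axis=1)
    else:
        null_means = np.empty(n_resamples)
        for i in range(n_resamples):
            null_means[i] = track[rng.choice(pool, size=k, replace=False)].mean()
    p = (np.count_nonzero(null_means >= observed) + 1) / (n_resamples + 1)
    return EnrichmentResult(
        observed_mean=observed, n_resamples=n_resamples,
        null_mean=float(null_means.mean()), null_sd=float(null_means.std()),
        p=float(p), with_replacement=with_replacement,
        provenance={"seed": seed, "n_selected": k, "n_windows": int(valid.sum())},
    )


@dataclass
class UnbalancedRegion:
    """Run of windows with ancestry outside the neutral resampling band."""

    chrom: str
    start: int
    end: int
    mean_fraction: float
    genome_mean: float

    @property
    def span(self) -> int:
        return self.end - self.start


def unbalanced_regions(
    track: np.ndarray,
    windows: list[GenomicWindow],
    *,
    min_span: int = 500_000,
    band_q: float = 99.9,
    n_resamples: int = 10_000,
    seed: int = 1,
) -> list[UnbalancedRegion]:
    """Long runs of windows whose ancestry fraction leaves the neutral band.

    Under neutrality the admixture fraction should be evenly spread
    along the genome, so single-window fractions should stay inside a
    two-sided ``band_q``% band of resampled single-window values.  The
    band is built from the track after discarding gross outliers
    (beyond 3 robust SDs of the median), so that the anomalous regions
    being hunted do not inflate their own detection band.  Maximal runs
    of consecutive out-of-band windows (all deviating in the same
    direction) spanning >= ``min_span`` bp are reported.
    """
    track = np.asarray(track, dtype=float)
    if len(track) != len(windows):
        raise ValueError("track and window list differ in length")
    valid = np.isfinite(track)
    if not valid.any():
        return []
    genome_mean = float(track[valid].mean())
    values = track[valid]
    med = np.median(values)
    robust_sd = 1.4826 * np.median(np.abs(values - med))
    typical = values[np.abs(values - med) <= 3 * robust_sd + 1e-12]
    rng = np.random.default_rng(seed)
    draws = rng.choice(typical, size=n_resamples, replace=True)
    alpha = (100.0 - band_q) / 2.0
    lo, hi = np.percentile(draws, [alpha, 100.0 - alpha])
    out: list[UnbalancedRegion] = []
    i = 0
    n = len(windows)
    while i < n:
        if valid[i] and (track[i] < lo or track[i] > hi):
            direction = 1 if track[i] > hi else -1
            j = i
            while (
                j + 1 < n and valid[j + 1]
                and windows[j + 1].chrom == windows[i].chrom
                and ((track[j + 1] > hi) if direction > 0 else (track[j + 1] < lo))
            ):
                j += 1
            start, end = windows[i].start, windows[j].end
            if end - start >= min_span:
                out.append(UnbalancedRegion(
                    chrom=windows[i].chrom, start=start, end=end,
                    mean_fraction=float(np.nanmean(track[i:j + 1])),
                    genome_mean=genome_mean,
                ))
            i = j + 1
        else:
            i += 1
    return out
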