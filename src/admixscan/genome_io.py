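"""Standard-format I/O, sliding windows, variant filters and gene overlap.

Coordinates are 0-based half-open everywhere inside the package; VCF's
1-based convention is converted on read and write.  The windowing
follows the scan design used throughout: 30 kb windows whose starts are
25 kb apart, so adjacent windows share 5 kb, and incomplete terminal
windows are dropped so every window statistic refers to the same length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .haplotypes import MISSING, HaplotypeSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (bp)."""

    size: int = 30_000
    step: int = 25_000

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("window size must be positive")
        if not 0 < self.step <= self.size:
            raise ValueError("step must satisfy 0 < step <= size")


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """0-based half-open window on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad window [{self.start}, {self.end})")


def make_windows(chrom_length: int, spec: WindowSpec = WindowSpec(),
                 chrom: str = "sim") -> list[GenomicWindow]:
    """Complete sliding windows over ``[0, chrom_length)``.

    Window starts are multiples of ``spec.step``; a window is emitted
    only if it fits entirely on the chromosome.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    out = []
    start = 0
    while start + spec.size <= chrom_length:
        out.append(GenomicWindow(chrom, start, start + spec.size))
        start += spec.step
    return out


def maf_filter(haps: HaplotypeSet, threshold: float = 0.05) -> HaplotypeSet:
    """Keep sites with minor allele frequency strictly above ``threshold``.

    Frequencies are computed over non-missing entries; monomorphic
    sites are always removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    p = haps.derived_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = np.where(np.nan_to_num(maf, nan=0.0) > threshold)[0]
    return haps.take_sites(keep)


@dataclass
class GeneAnnotation:
    """Gene intervals (chrom, start, end, name), 0-based half-open."""

    records: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        for chrom, start, end, name in self.records:
            if start >= end:
                raise ValueError(f"empty gene interval {name} [{start}, {end})")


def read_bed_genes(path) -> GeneAnnotation:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else f"{fields[0]}:{fields[1]}"
            records.append((fields[0], int(fields[1]), int(fields[2]), name))
    return GeneAnnotation(records)


def write_bed(path, intervals: list[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def intersect_genes(windows: list[GenomicWindow],
                    annotation: GeneAnnotation) -> list[list[str]]:
    """Per-window gene names overlapping by >= 1 bp (half-open semantics)."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in annotation.records:
        by_chrom.setdefault(chrom, []).append((start, end, name))
    for rec in by_chrom.values():
        rec.sort()
    out = []
    for w in windows:
        genes = [
            name for start, end, name in by_chrom.get(w.chrom, [])
            if start < w.end and end > w.start
        ]
        out.append(genes)
    return out


# ---------------------------------------------------------------------------
# VCF


def write_phased_vcf(path, haps: HaplotypeSet) -> None:
    """Write a phased diploid VCF (GT like ``0|1``, masked alleles ``.``).

    Alleles are written REF=A (ancestral), ALT=G (derived) with an
    ``AA`` INFO tag recording the ancestral allele so polarity survives
    a round trip.  ``n_hap`` must be even.
    """
    if haps.n_hap % 2:
        raise ValueError("phased VCF requires an even number of haplotypes")
    samples = [hid.rsplit("_", 1)[0] for hid in haps.haplotype_ids[::2]]
    code = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={haps.chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(haps.n_site):
            gts = "\t".join(
                f"{code[int(haps.matrix[2 * i, j])]}|{code[int(haps.matrix[2 * i + 1, j])]}"
                for i in range(len(samples))
            )
            fh.write(
                f"{haps.chrom}\t{haps.positions[j] + 1}\t.\tA\tG\t.\tPASS\tAA=A\tGT\t{gts}\n"
            )


def read_phased_vcf(path) -> dict[str, HaplotypeSet]:
    """Read phased diploid VCFs into one HaplotypeSet per chromosome.

    Multiallelic and unphased records are skipped (counted in the log
    and metadata).  The ancestral allele comes from the ``AA`` INFO tag
    when present; otherwise REF is assumed ancestral with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    per_chrom: dict[str, dict] = {}
    n_skipped_multi = n_skipped_unphased = 0
    warned_aa = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped_multi += 1
            continue
        gts = var.genotypes  # [a, b, phased] per sample
        if any(len(g) < 3 or not g[2] for g in gts):
            n_skipped_unphased += 1
            continue
        aa = var.INFO.get("AA")
        if aa is None:
            if not warned_aa:
                logger.warning(
                    "no AA tag in %s: treating REF as the ancestral allele", path
                )
                warned_aa = True
            derived_is_alt = True
        else:
            derived_is_alt = str(aa).upper() == var.REF.upper()
        row = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            for k in (0, 1):
                a = g[k]
                if a < 0:
                    row[2 * i + k] = MISSING
                else:
                    row[2 * i + k] = a if derived_is_alt else 1 - a
        store = per_chrom.setdefault(var.CHROM, {"pos": [], "rows": []})
        store["pos"].append(var.POS - 1)
        store["rows"].append(row)
    if not per_chrom and (n_skipped_multi or n_skipped_unphased):
        raise ValueError(f"no phased biallelic records in {path}")
    if n_skipped_multi or n_skipped_unphased:
        logger.info(
            "skipped %d multiallelic and %d unphased records in %s",
            n_skipped_multi, n_skipped_unphased, path,
        )
    hap_ids = [f"{s}_{k}" for s in samples for k in (0, 1)]
    out = {}
    for chrom, store in per_chrom.items():
        out[chrom] = HaplotypeSet(
            chrom=chrom,
            positions=np.array(store["pos"], dtype=np.int64),
            matrix=np.array(store["rows"], dtype=np.int8).T.copy()
            if store["rows"] else np.empty((len(hap_ids), 0), dtype=np.int8),
            haplotype_ids=hap_ids,
            metadata={
                "skipped_multiallelic": n_skipped_multi,
                "skipped_unphased": n_skipped_unphased,
            },
        )
    return out


def write_tracts_bed(path, tract_set) -> None:
    """Sidecar tract file: chrom-less BED-like TSV (start, end, hap, label)."""
    with open(path, "w") as fh:
        for hap, tr in tract_set.tracts.items():
            for start, end, label in tr:
                fh.write(f"{start}\t{end}\t{hap}\t{label}\n")
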