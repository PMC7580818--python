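"""Core in-memory containers: phased haplotype matrices and ancestry tracts.

The haplotype matrix is the common currency of every statistic in this
package: rows are phased haplotypes, columns are biallelic sites coded
0 (ancestral) / 1 (derived), with ``MISSING`` (-1) reserved for entries
removed by local-ancestry masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for masked / missing alleles in the haplotype matrix.
MISSING: int = -1


@dataclass
class HaplotypeSet:
    """Phased haplotypes over one chromosome (or simulated replicate).

    Parameters
    ----------
    chrom
        Chromosome / replicate label.
    positions
        Strictly increasing 0-based bp coordinates, one per site.
    matrix
        ``(n_hap, n_site)`` int8 array with entries in {0, 1, MISSING}.
    haplotype_ids
        One identifier per row. Diploid sample ``S`` contributes rows
        ``S_1`` and ``S_2``.
    metadata
        Free-form provenance (simulation parameters, conditioning rule,
        filter counts).
    """

    chrom: str
    positions: np.ndarray
    matrix: np.ndarray
    haplotype_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (n_hap, n_site)")
        if self.matrix.shape != (len(self.haplotype_ids), len(self.positions)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.haplotype_ids)} haplotypes x {len(self.positions)} sites"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.matrix, (0, 1, MISSING))
        if bad.any():
            raise ValueError("matrix entries must be 0, 1 or MISSING")

    @property
    def n_hap(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_site(self) -> int:
        return self.matrix.shape[1]

    def derived_freq(self) -> np.ndarray:
        """Per-site derived allele frequency over non-missing entries.

        Sites with no called entries get frequency ``nan``.
        """
        called = self.matrix != MISSING
        n_called = called.sum(axis=0)
        n_derived = np.where(called, self.matrix, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, n_derived / np.maximum(n_called, 1), np.nan)

    def take_sites(self, index: np.ndarray) -> "HaplotypeSet":
        """Subset to the given site indices (order preserved)."""
        index = np.asarray(index)
        return HaplotypeSet(
            chrom=self.chrom,
            positions=self.positions[index],
            matrix=self.matrix[:, index],
            haplotype_ids=list(self.haplotype_ids),
            metadata=dict(self.metadata),
        )

    def take_haplotypes(self, index: np.ndarray) -> "HaplotypeSet":
        index = np.asarray(index)
        return HaplotypeSet(
            chrom=self.chrom,
            positions=self.positions.copy(),
            matrix=self.matrix[index, :],
            haplotype_ids=[self.haplotype_ids[i] for i in index],
            metadata=dict(self.metadata),
        )


@dataclass
class AncestryTractSet:
    """Ground-truth local ancestry as half-open bp intervals per haplotype.

    ``tracts[hap_id]`` is a sorted list of ``(start, end, label)`` tuples
    that tile ``[0, sequence_length)`` without overlap.
    """

    sequence_length: int
    tracts: dict[str, list[tuple[int, int, str]]]

    def validate(self) -> None:
        for hap, tr in self.tracts.items():
            if not tr:
                raise ValueError(f"haplotype {hap} has no tracts")
            if tr[0][0] != 0 or tr[-1][1] != self.sequence_length:
                raise ValueError(f"tracts of {hap} do not span the sequence")
            for (s0, e0, _), (s1, _e1, _) in zip(tr, tr[1:]):
                if e0 != s1 or s0 >= e0:
                    raise ValueError(f"tracts of {hap} are not a sorted tiling")
            if tr[-1][0] >= tr[-1][1]:
                raise ValueError(f"tracts of {hap} contain an empty interval")

    def coverage(self, label: str) -> dict[str, float]:
        """Fraction of each haplotype covered by tracts with ``label``."""
        out = {}
        for hap, tr in self.tracts.items():
            covered = sum(e - s for s, e, lab in tr if lab == label)
            out[hap] = covered / self.sequence_length
        return out

    def mean_coverage(self, label: str) -> float:
        cov = self.coverage(label)
        return float(np.mean(list(cov.values())))

    def label_at(self, hap_id: str, pos: int) -> str:
        """Ancestry label of haplotype ``hap_id`` at bp position ``pos``."""
        for s, e, lab in self.tracts[hap_id]:
            if s <= pos < e:
                return lab
        raise ValueError(f"position {pos} outside tracts of {hap_id}")

    def labels_at_sites(self, hap_ids: list[str], positions: np.ndarray) -> np.ndarray:
        """Label matrix (n_hap, n_site) of ancestry at each site, as strings."""
        positions = np.asarray(positions)
        out = np.empty((len(hap_ids), len(positions)), dtype=object)
        for i, hap in enumerate(hap_ids):
            tr = self.tracts[hap]
            starts = np.array([s for s, _, _ in tr])
            labs = [lab for _, _, lab in tr]
            idx = np.searchsorted(starts, positions, side="right") - 1
            out[i, :] = [labs[j] for j in idx]
        return out
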