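"""Windowed site-frequency-spectrum sweep classifier.

A hard sweep distorts the SFS of a genomic window toward rare and
high-frequency-derived variants.  This module turns each window into a
normalized derived-allele-frequency histogram and trains a soft-margin
linear support-vector classifier to separate windows simulated under
neutrality from windows simulated under a grid of hard sweeps
(selection coefficient s x time under selection tau), pooled into one
"selected" class.  The decision value ``w . x + b`` is the per-window
selection score; scores are comparable only within one trained model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .genome_io import GenomicWindow
from .haplotypes import HaplotypeSet

DEFAULT_BINS = 20

#: Default scaled-down training grid (s, tau in generations).
DEFAULT_GRID = [
    (s, tau)
    for s in (0.005, 0.01, 0.02, 0.05)
    for tau in (200, 500, 1000, 2000, 4000)
]


@dataclass
class SFSFeature:
    """Normalized derived-frequency histogram of one window."""

    window: GenomicWindow
    n_snps: int
    histogram: np.ndarray   # length B, sums to 1 unless empty
    empty: bool = False


@dataclass
class ClassifierModel:
    """Linear SVM decision rule ``score = w . x + b`` with provenance."""

    weights: np.ndarray
    bias: float
    C: float
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        doc = {
            "weights": list(map(float, self.weights)),
            "bias": self.bias,
            "C": self.C,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            weights=np.array(doc["weights"]), bias=float(doc["bias"]),
            C=float(doc["C"]), metadata=doc.get("metadata", {}),
        )


def window_sfs_feature(
    haps: HaplotypeSet, window: GenomicWindow, B: int = DEFAULT_BINS
) -> SFSFeature:
    """Derived-allele-frequency histogram of segregating sites in a window.

    ``B`` equal-width bins over (0, 1), normalized to sum 1.  A window
    without segregating sites yields a flagged zero vector.
    """
    sel = (haps.positions >= window.start) & (haps.positions < window.end)
    p = haps.derived_freq()[sel]
    p = p[np.isfinite(p) & (p > 0) & (p < 1)]
    if len(p) == 0:
        return SFSFeature(window, 0, np.zeros(B), empty=True)
    edges = np.linspace(0.0, 1.0, B + 1)
    hist, _ = np.histogram(p, bins=edges)
    return SFSFeature(window, int(len(p)), hist / hist.sum())


def features_matrix(features: list[SFSFeature]) -> np.ndarray:
    return np.array([f.histogram for f in features])


def train_sfselect(
    neutral: list[SFSFeature] | np.ndarray,
    swept: list[SFSFeature] | np.ndarray,
    *,
    C: float = 1.0,
    seed: int = 0,
    metadata: dict | None = None,
) -> ClassifierModel:
    """Train the linear SVM separating neutral from swept window spectra.

    Swept windows get label +1, so positive decision values indicate
    selection.  Training is deterministic for fixed inputs and seed.
    """
    Xn = neutral if isinstance(neutral, np.ndarray) else features_matrix(neutral)
    Xs = swept if isinstance(swept, np.ndarray) else features_matrix(swept)
    if len(Xn) == 0 or len(Xs) == 0:
        raise ValueError("both neutral and swept classes must be non-empty")
    X = np.vstack([Xn, Xs])
    y = np.concatenate([-np.ones(len(Xn)), np.ones(len(Xs))])
    svm = LinearSVC(C=C, random_state=seed, max_iter=20_000)
    svm.fit(X, y)
    meta = {"n_neutral": len(Xn), "n_swept": len(Xs), "seed": seed}
    if metadata:
        meta.update(metadata)
    return ClassifierModel(
        weights=svm.coef_.ravel().copy(), bias=float(svm.intercept_[0]),
        C=C, metadata=meta,
    )


def score_windows(
    features: list[SFSFeature] | np.ndarray, model: ClassifierModel
) -> np.ndarray:
    """Per-window decision values ``w . x + b``."""
    X = features if isinstance(features, np.ndarray) else features_matrix(features)
    if X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature length {X.shape[1]} != model dimension {len(model.weights)}"
        )
    return X @ model.weights + model.bias
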