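# Methods

This note records the models, conventions and numerical choices behind
`admixscan`, and what the synthetic-data tests do and do not establish
about real data.

## Demographic model and presets

Neutral data are simulated under a three-population out-of-Africa
coalescent (African / European / Asian branches) with the published
low-coverage whole-genome parameter set: ancestral size 7,310;
African expansion to 14,474 at 148 kya; out-of-Africa bottleneck to
1,861 at 51 kya with symmetric migration 1.5×10⁻⁴/generation to
Africa; European–Asian split at 23 kya with starting sizes 1,032 /
554, exponential growth 0.0038 / 0.0048 per generation, and the three
pairwise migration rates 2.5×10⁻⁵, 0.78×10⁻⁵ and 3.11×10⁻⁵. A
generation is 25 years throughout, so the ~2,600-year-old admixture
pulse sits at 104 generations.

Two presets define the population classes of the study design:

* **afroasiatic** — a deme `ADM` that splits from the African branch
  300 generations ago (recent enough to be nearly undifferentiated)
  and receives a single pulse of fraction f = 0.54 from the European
  branch (the West-Eurasian proxy) at 104 generations. The separate
  deme exists so that an *unadmixed* African reference panel can be
  sampled from `AFR` in the same simulation.
* **gumuz** — the same demography sampled from the unadmixed African
  deme.
* **constant** — one constant-size population, for analytic oracles
  (π = 4Nμ, Tajima's D ≈ 0, SFS ∝ 1/i).

Mutation and recombination default to μ = 1.25×10⁻⁸ and r = 1×10⁻⁸
per bp per generation, standard human point estimates (configurable). Mutations use a binary 0/1 model so ancestral/derived
polarity is exact by construction.

**Ancestry truth.** A census at 104.5 generations records every
lineage's population; linking each sample to its census ancestor
yields per-haplotype ancestry tracts that tile the sequence. Lineages
sitting in the European branch at the census are labelled
West-Eurasian (`WEA`), all others African (`AFR`). Continuous
AFR↔EUR migration contributes < 0.3% mislabelled census ancestry and
is ignored.

**Sweeps.** A hard sweep with coefficient *s* and time under selection
τ is generated in two steps: a forward Wright–Fisher trajectory of the
beneficial allele (genic selection, binomial resampling from one copy,
conditioned on non-loss with retries) fixes the present-day frequency
after τ generations; a structured-coalescent sweep model then
generates the ancestry up to that frequency in a single population of
the focal deme's size. `condition="fixation"` instead drives the
allele to near-fixation regardless of τ. Both conditioning modes are
provided because either is a defensible definition of "τ generations
under selection"; the mode is recorded in the output metadata. The trajectory tracks the
deterministic logistic path for large N (tested via the 0.1→0.9
traversal time ln 81 / s).

## iHS

EHH is pair-based homozygosity among carriers of the core allele,
computed cumulatively outward; iHH integrates the EHH curve against
physical distance (no genetic map is assumed) with the trapezoid rule,
including the first point below the 0.05 cutoff, and sums both sides.
uiHS = ln(iHH_A / iHH_D). Eligibility and exclusion rules:

* cores need MAF > 0.05, ≥ 2 carriers of each allele, and ≥ 20
  unmasked haplotypes;
* a core is discarded when any of its four EHH curves meets an
  inter-SNP gap > 20 kb before decaying below the cutoff (gaps bias
  the integral), and likewise — by default — when a curve runs into
  the chromosome end (`discard_border=False` disables this);
* haplotypes with a masked allele in the extension leave the pair
  count from that site onward; a side whose unmasked carriers drop
  below two also discards the core.

Standardization uses 50 equal-width derived-allele-frequency bins over
(0, 1); adjacent sparse bins are merged left-to-right until each holds
≥ 10 scored SNPs. Bins with zero variance leave their records
unscored. Per-SNP p-values are the two-sided Gaussian convention
p = 2Φ(−|iHS|), stated as a convention of this package, not a claim
about the score's exact null. Window summaries use the mean and max of
|iHS| ("mean iHS" is the mean of absolute scores; a signed mean is
available from the records table).

The per-core scan exists twice — a readable numpy path and a numba
kernel — and the test suite holds them equal to 10⁻⁹ relative; the
kernel is ~50× faster and is what genome-scale calibration uses.

## Windowed-SFS classifier

Windows of 30 kb (starts every 25 kb, incomplete terminal windows
dropped so all statistics share a length) are summarized as B = 20
equal-width derived-frequency histogram bins, normalized to sum 1;
empty windows carry a flagged zero vector and score exactly the bias.
The classifier is a soft-margin linear SVM (C = 1, seeded, metadata
logged) trained on single-population constant-size simulations:
neutral windows vs a pooled grid of hard sweeps (defaults: s ∈ {0.005,
0.01, 0.02, 0.05} × τ ∈ {200, 500, 1000, 2000, 4000}, a scaled-down
stand-in for the original 200-point grid; configurable). Both classes
come from the same single-population engine so the decision rule
learns the sweep distortion of the spectrum, not a demography
contrast. Scores are comparable only within one trained model, which
is why published score thresholds from other tools' weights are not
reproduced here.

## Calibration

Critical values are linear-interpolation percentiles (numpy
convention) of pooled statistic values from seeded neutral replicates
— pooling across replicate chromosomes, not averaging per-replicate
percentiles. Two classes (admixed / unadmixed) get separate
thresholds; candidate calling is a strict `>` comparison. A warning
fires when the sample is too small for the requested tail
(< 100/(100−q) values). The derived-SFS check compares relative
spectra (proportions at each derived count) by L1 distance, for
verifying that a simulated demography matches a dataset.

Default null sizes in the acceptance computation: 52 replicate 5 Mb
chromosomes per class (~260 Mb), giving ≥ 2×10⁵ MAF-filtered SNPs and
~10⁴ windows — enough that the 99.99th percentile is interpolated
rather than extrapolated. Standardization is done once on the pooled
records, as a genome-wide scan would.

## Local ancestry, masking, enrichment

Ancestry is assigned per (haplotype, 20-SNP block) by a per-block
allele-frequency log-likelihood ratio against the two reference panels
(Laplace pseudocount 0.5) — a linear projection of the block onto the
axis of per-SNP log odds ratios — smoothed by a centered moving
average over 41 blocks, with the label taken from the smoothed sign
and confidence tanh(|score|/2). Design rationale: per-block centroid
classification (PCA-style) on 24-haplotype panels and 20-SNP blocks
plateaus near 0.75 accuracy because single blocks carry too little
information for hard votes, while pooling log-likelihood evidence
across neighbouring blocks reaches ~0.90–0.92 against truth tracts.
The smoothing span (~0.7 Mb at common-variant density) is about a
third of the ~2 Mb mean tract length 1/(r·t·(1−f)) of a
104-generation pulse. A terminal block with < 20 SNPs merges into its
predecessor. Assignment is run on jointly MAF-filtered (> 0.05) sites,
emulating the array-like common-variant data such deconvolutions are
normally run on.

Masking sets every site of a West-Eurasian-labelled block to missing;
the per-SNP masked fraction is the ancestry-proportion track, averaged
over SNPs for regions or the genome. Selected windows are merged when
overlapping or book-ended before proportions are computed. The
enrichment test draws |selected| windows without replacement (a
with-replacement flag exists) 10⁵ times and reports the one-sided
empirical p with the (+1)/(n+1) correction, so p ∈ [1/(n+1), 1] and
p = 0 is impossible.

Unbalanced-ancestry regions are maximal same-direction runs of windows
whose fraction falls outside a two-sided 99.9% single-window
resampling band around the genome-wide mean, reported when the run
spans ≥ 0.5 Mb. The band is computed after discarding track values
beyond 3 robust (MAD-based) SDs of the median: without that trim, any
anomalous run long enough to satisfy the span rule would contribute
more than the band's own tail mass and suppress its own detection.

## What the synthetic data do and do not show

The generator reproduces the study conditions — sample sizes (46–48
haplotypes), the admixture pulse (f = 0.54 at 104 generations), the
out-of-Africa demography, hard sweeps on an (s, τ) grid — and records
exact tract truth. It does not emulate genotyping error, low-coverage
singleton deficits (typical of low-coverage calls), phasing switch
errors, uneven marker density, or background selection; passing tests
therefore demonstrate correctness of the statistics and internal
consistency of the calibration under the modelled demography, not
robustness to those artefacts. The classifier's AUC and the ancestry
accuracy are measured under the same model family that generated the
training data, which is the favourable case.

## Degenerate inputs and tie-breaks

Monomorphic or all-missing sites are removed by the MAF filter; empty
windows are emitted with n = 0 and NaN summaries; a zero iHH integral
or a degenerate standardization bin flags the record rather than
producing ±inf; equal distances in block classification resolve to the
African label (score 0 is not > 0); percentile ties follow numpy's
linear interpolation. All randomness flows from explicit integer
seeds, and identical seeds give bit-identical outputs end to end.
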