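"""Coalescent simulation of admixed East-African-like samples.

Provides the synthetic data every other module is calibrated on: a
three-population out-of-Africa demography (African, European and Asian
branches with the published growth/migration parameters of the
low-coverage whole-genome fit) extended with an optional single-pulse
admixture event from the out-of-Africa branch into a recently derived
African deme.  Two presets mirror the two population classes of the
study design:

``afroasiatic``
    an admixed deme receiving a pulse of fraction ``f`` (default 0.54)
    from the European/West-Eurasian branch 104 generations ago
    (2,600 years at 25 y/generation);
``gumuz``
    the same demography sampled from the unadmixed African deme;
``constant``
    a single constant-size population, used for analytic oracles.

Neutral samples are generated with the coalescent with recombination;
true local-ancestry tracts are read off the tree sequence through a
census placed immediately above the pulse.  Hard sweeps are generated
with a structured-coalescent sweep model whose end frequency comes from
a forward Wright-Fisher trajectory of the beneficial allele, so a sweep
is parameterized by the selection coefficient ``s`` and the time under
selection ``tau``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np

from .haplotypes import AncestryTractSet, HaplotypeSet

#: Published three-population out-of-Africa parameters (diploid sizes,
#: years, per-generation rates), 25 years per generation.
GRAVEL_PARAMS = {
    "N_A": 7310,        # ancestral
    "N_AF": 14474,      # African after expansion
    "N_B": 1861,        # out-of-Africa bottleneck
    "N_EU0": 1032,      # European at split
    "N_AS0": 554,       # Asian at split
    "r_EU": 0.0038,     # European growth rate /gen
    "r_AS": 0.0048,     # Asian growth rate /gen
    "T_AF_years": 148e3,
    "T_B_years": 51e3,
    "T_EU_AS_years": 23e3,
    "m_AF_B": 15e-5,
    "m_AF_EU": 2.5e-5,
    "m_AF_AS": 0.78e-5,
    "m_EU_AS": 3.11e-5,
}

DEFAULT_MU = 1.25e-8   # per bp per generation
DEFAULT_R = 1e-8       # per bp per generation
GENERATION_TIME = 25.0  # years

#: Ancestry labels used in tract sets and the ancestry module.
AFR_LABEL = "AFR"
WEA_LABEL = "WEA"

#: Population -> ancestry label for census ancestors.
_POP_ANCESTRY = {"AFR": AFR_LABEL, "ADM": AFR_LABEL, "EUR": WEA_LABEL,
                 "ASN": WEA_LABEL, "OOA": WEA_LABEL}


class SweepTrajectoryError(RuntimeError):
    """Raised when the forward allele trajectory is lost on every retry."""

    def __init__(self, retries: int):
        self.retries = retries
        super().__init__(
            f"beneficial-allele trajectory lost in all {retries} attempts"
        )


@dataclass
class AdmixtureEvent:
    """Single-generation gene-flow pulse contributing fraction ``f``."""

    time_generations: int
    source: str
    dest: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"admixture fraction {self.fraction} outside [0, 1]")
        if self.time_generations <= 0:
            raise ValueError("admixture time must be positive")


@dataclass
class SweepParams:
    """Hard-sweep parameters: selection coefficient and time under selection."""

    s: float
    tau: int
    position: float
    dominance: float = 0.5

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.tau < 0:
            raise ValueError("time under selection must be >= 0")


@dataclass
class DemographicModel:
    """A resolved demography plus bookkeeping for sampling and tracts."""

    name: str
    demography: msprime.Demography
    focal_population: str
    admixture: AdmixtureEvent | None = None
    generation_time: float = GENERATION_TIME
    census_time: float | None = None
    params: dict = field(default_factory=dict)

    @property
    def focal_size(self) -> float:
        """Present-day diploid size of the focal population."""
        for pop in self.demography.populations:
            if pop.name == self.focal_population:
                return pop.initial_size
        raise KeyError(self.focal_population)


def build_demography(
    preset: str = "afroasiatic",
    *,
    admixture_fraction: float = 0.54,
    admixture_time_gen: int = 104,
    adm_split_time_gen: int = 300,
    constant_size: float = 10_000,
    params: dict | None = None,
) -> DemographicModel:
    """Resolve a named demographic preset into a full model.

    The ``afroasiatic`` preset adds a recently derived African deme
    (``ADM``) that receives one pulse from the European branch
    ``admixture_time_gen`` generations ago; ``gumuz`` samples the
    unadmixed African deme of the same demography; ``constant`` is a
    single population of ``constant_size`` diploids.
    """
    if preset == "constant":
        if constant_size <= 0:
            raise ValueError("population size must be positive")
        dem = msprime.Demography()
        dem.add_population(name="AFR", initial_size=constant_size)
        return DemographicModel(
            name="constant", demography=dem, focal_population="AFR",
            params={"N": constant_size},
        )

    p = dict(GRAVEL_PARAMS)
    if params:
        p.update(params)
    for key in ("N_A", "N_AF", "N_B", "N_EU0", "N_AS0"):
        if p[key] <= 0:
            raise ValueError(f"population size {key} must be positive")

    if preset == "afroasiatic":
        admixture = AdmixtureEvent(
            time_generations=admixture_time_gen, source="EUR", dest="ADM",
            fraction=admixture_fraction,
        )
        focal = "ADM"
    elif preset == "gumuz":
        admixture = None
        focal = "AFR"
    else:
        raise ValueError(f"unknown preset {preset!r}")

    t_eu_as = p["T_EU_AS_years"] / GENERATION_TIME
    t_b = p["T_B_years"] / GENERATION_TIME
    t_af = p["T_AF_years"] / GENERATION_TIME
    n_eu_now = p["N_EU0"] * math.exp(p["r_EU"] * t_eu_as)
    n_as_now = p["N_AS0"] * math.exp(p["r_AS"] * t_eu_as)

    dem = msprime.Demography()
    # AFR is also the ancestral deme of the ADM split; keep it sampleable today
    dem.add_population(name="AFR", initial_size=p["N_AF"], initially_active=True)
    dem.add_population(name="EUR", initial_size=n_eu_now, growth_rate=p["r_EU"])
    dem.add_population(name="ASN", initial_size=n_as_now, growth_rate=p["r_AS"])
    dem.add_population(name="OOA", initial_size=p["N_B"], initially_active=False)
    dem.add_population(name="AMH", initial_size=p["N_AF"], initially_active=False)
    dem.add_population(name="ANC", initial_size=p["N_A"], initially_active=False)
    dem.set_symmetric_migration_rate(["AFR", "EUR"], p["m_AF_EU"])
    dem.set_symmetric_migration_rate(["AFR", "ASN"], p["m_AF_AS"])
    dem.set_symmetric_migration_rate(["EUR", "ASN"], p["m_EU_AS"])

    census_time = None
    if admixture is not None:
        dem.add_population(name="ADM", initial_size=p["N_AF"])
        if admixture.fraction > 0:
            # backwards in time: ADM lineages jump to the source branch
            dem.add_mass_migration(
                time=admixture.time_generations, source="ADM",
                dest=admixture.source, proportion=admixture.fraction,
            )
        census_time = admixture.time_generations + 0.5
        dem.add_census(time=census_time)
        dem.add_population_split(
            time=adm_split_time_gen, derived=["ADM"], ancestral="AFR"
        )
    dem.add_population_split(time=t_eu_as, derived=["EUR", "ASN"], ancestral="OOA")
    dem.add_symmetric_migration_rate_change(
        time=t_eu_as, populations=["AFR", "OOA"], rate=p["m_AF_B"]
    )
    dem.add_population_split(time=t_b, derived=["AFR", "OOA"], ancestral="AMH")
    dem.add_population_split(time=t_af, derived=["AMH"], ancestral="ANC")
    dem.sort_events()

    return DemographicModel(
        name=preset, demography=dem, focal_population=focal,
        admixture=admixture, census_time=census_time, params=p,
    )


def _split_seed(seed: int, n: int = 2) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(1, 2**31 - 1, size=n)]


def _haplotype_ids(sample_sets: list[tuple[str, int]]) -> list[str]:
    ids = []
    for pop, n_hap in sample_sets:
        ids.extend(f"{pop}_{i // 2}_{i % 2}" for i in range(n_hap))
    return ids


def _ts_to_haplotypes(ts, chrom: str, hap_ids: list[str], metadata: dict) -> HaplotypeSet:
    """Extract segregating biallelic 0/1 sites from a mutated tree sequence."""
    if ts.num_sites == 0:
        return HaplotypeSet(
            chrom=chrom,
            positions=np.empty(0, dtype=np.int64),
            matrix=np.empty((len(hap_ids), 0), dtype=np.int8),
            haplotype_ids=hap_ids, metadata=metadata,
        )
    geno = ts.genotype_matrix().T.astype(np.int8)  # (n_hap, n_site)
    positions = ts.tables.sites.position.astype(np.int64)
    derived = geno.sum(axis=0)
    seg = (derived > 0) & (derived < geno.shape[0])
    return HaplotypeSet(
        chrom=chrom, positions=positions[seg], matrix=geno[:, seg],
        haplotype_ids=hap_ids, metadata=metadata,
    )


def _tracts_from_census(ts, model: DemographicModel, hap_ids: list[str],
                        L: int) -> AncestryTractSet:
    """True local ancestry of every sample, read at the census time.

    Each sample lineage is linked to its ancestor at the census placed
    just above the admixture pulse; the ancestor's population determines
    the ancestry label of that interval.
    """
    pop_names = {pop.id: pop.name for pop in model.demography.populations}
    tables = ts.tables
    node_time = tables.nodes.time
    node_pop = tables.nodes.population
    census_nodes = np.where(node_time == model.census_time)[0]
    samples = ts.samples()
    edges = tables.link_ancestors(
        samples=samples.astype(np.int32), ancestors=census_nodes.astype(np.int32)
    )
    per_hap: dict[int, list[tuple[int, int, str]]] = {int(s): [] for s in samples}
    for left, right, parent, child in zip(
        edges.left, edges.right, edges.parent, edges.child
    ):
        label = _POP_ANCESTRY.get(pop_names[node_pop[parent]], AFR_LABEL)
        per_hap[int(child)].append((int(left), int(right), label))
    tracts: dict[str, list[tuple[int, int, str]]] = {}
    for node, hap in zip(samples, hap_ids):
        iv = sorted(per_hap[int(node)])
        merged: list[tuple[int, int, str]] = []
        cursor = 0
        for s, e, lab in iv:
            if s > cursor:  # uncovered gap: lineage coalesced below census
                merged.append((cursor, s, AFR_LABEL))
            if merged and merged[-1][2] == lab and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, lab)
            else:
                merged.append((s, e, lab))
            cursor = e
        if cursor < L:
            merged.append((cursor, L, AFR_LABEL))
        tracts[hap] = merged
    out = AncestryTractSet(sequence_length=L, tracts=tracts)
    out.validate()
    return out


def _uniform_tracts(model: DemographicModel, sample_sets, hap_ids, L) -> AncestryTractSet:
    tracts = {}
    i = 0
    for pop, n_hap in sample_sets:
        label = _POP_ANCESTRY.get(pop, AFR_LABEL)
        for _ in range(n_hap):
            tracts[hap_ids[i]] = [(0, L, label)]
            i += 1
    return AncestryTractSet(sequence_length=L, tracts=tracts)


def simulate_neutral(
    model: DemographicModel,
    n_hap: int,
    L: int,
    *,
    mu: float = DEFAULT_MU,
    r: float = DEFAULT_R,
    seed: int = 1,
    chrom: str = "sim",
    extra_samples: dict[str, int] | None = None,
) -> tuple[HaplotypeSet, AncestryTractSet]:
    """Simulate neutral phased haplotypes plus true ancestry tracts.

    ``n_hap`` haplotypes (must be even: phased diploids) are drawn from
    the model's focal population; ``extra_samples`` maps additional
    population names to haplotype counts (e.g. reference panels).
    Deterministic for a fixed ``(model, parameters, seed)``.
    """
    if n_hap <= 0 or n_hap % 2:
        raise ValueError("n_hap must be a positive even number (phased diploids)")
    if L <= 0:
        raise ValueError("sequence length must be positive")
    sample_sets = [(model.focal_population, n_hap)]
    if extra_samples:
        for pop, n in extra_samples.items():
            if n <= 0 or n % 2:
                raise ValueError("extra sample counts must be positive and even")
            sample_sets.append((pop, n))
    anc_seed, mut_seed = _split_seed(seed)
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(n // 2, population=pop, ploidy=2)
            for pop, n in sample_sets
        ],
        demography=model.demography,
        sequence_length=L,
        recombination_rate=r,
        random_seed=anc_seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=mu, random_seed=mut_seed, model=msprime.BinaryMutationModel()
    )
    hap_ids = _haplotype_ids(sample_sets)
    haps = _ts_to_haplotypes(
        mts, chrom, hap_ids,
        metadata={"model": model.name, "mu": mu, "r": r, "seed": seed, "L": L},
    )
    if model.census_time is not None:
        tract_set = _tracts_from_census(ts, model, hap_ids, L)
    else:
        tract_set = _uniform_tracts(model, sample_sets, hap_ids, L)
    return haps, tract_set


def wf_trajectory(
    s: float,
    N: int,
    tau: int,
    seed: int,
    *,
    max_retries: int = 1000,
) -> np.ndarray:
    """Forward Wright-Fisher frequency trajectory of a beneficial allele.

    Starts from a single copy (1/2N) and runs ``tau`` generations of
    binomial resampling with genic selection, retrying on loss.  Returns
    the frequency path of length ``tau + 1``.  With large ``N`` the path
    tracks the deterministic logistic trajectory.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    rng = np.random.default_rng(seed)
    two_n = 2 * N
    for _ in range(max_retries):
        p = 1.0 / two_n
        traj = [p]
        lost = False
        for _ in range(tau):
            w = p * (1 + s) / (1 + s * p)
            p = rng.binomial(two_n, w) / two_n
            if p == 0.0:
                lost = True
                break
            traj.append(p)
        if not lost:
            return np.array(traj)
    raise SweepTrajectoryError(max_retries)


def logistic_trajectory(s: float, N: int, tau: int) -> np.ndarray:
    """Deterministic genic-selection trajectory from one copy (oracle)."""
    p0 = 1.0 / (2 * N)
    t = np.arange(tau + 1)
    return p0 / (p0 + (1 - p0) * np.exp(-s * t))


def simulate_sweep(
    model: DemographicModel,
    sweep: SweepParams,
    n_hap: int,
    L: int,
    *,
    mu: float = DEFAULT_MU,
    r: float = DEFAULT_R,
    seed: int = 1,
    chrom: str = "sweep",
    condition: str = "frequency",
    max_retries: int = 1000,
) -> HaplotypeSet:
    """Simulate haplotypes carrying the footprint of a hard sweep.

    A forward Wright-Fisher trajectory with coefficient ``s`` run for
    ``tau`` generations (conditioned on non-loss) sets the present-day
    frequency of the beneficial allele; the ancestry is then generated
    with a structured-coalescent sweep model in a single population of
    the focal deme's size.  ``condition="fixation"`` instead drives the
    allele to (near) fixation regardless of ``tau``.  ``s = 0`` is the
    neutral identity case.
    """
    if not 0 <= sweep.position < L:
        raise ValueError("selected site must lie inside [0, L)")
    if n_hap <= 0 or n_hap % 2:
        raise ValueError("n_hap must be a positive even number")
    N = model.focal_size
    metadata = {
        "model": model.name, "s": sweep.s, "tau": sweep.tau,
        "position": sweep.position, "condition": condition,
        "mu": mu, "r": r, "seed": seed, "L": L,
    }
    anc_seed, mut_seed, traj_seed = _split_seed(seed, 3)
    if sweep.s == 0.0:
        ts = msprime.sim_ancestry(
            samples=n_hap // 2, population_size=N, ploidy=2,
            sequence_length=L, recombination_rate=r, random_seed=anc_seed,
        )
    else:
        start = 1.0 / (2 * N)
        if condition == "fixation":
            end = 1.0 - start
        elif condition == "frequency":
            traj = wf_trajectory(
                sweep.s, int(N), sweep.tau, traj_seed, max_retries=max_retries
            )
            end = min(float(traj[-1]), 1.0 - start)
            metadata["end_frequency"] = end
        else:
            raise ValueError(f"unknown conditioning mode {condition!r}")
        if end <= start:
            # allele still effectively at one copy: neutral ancestry
            ts = msprime.sim_ancestry(
                samples=n_hap // 2, population_size=N, ploidy=2,
                sequence_length=L, recombination_rate=r, random_seed=anc_seed,
            )
        else:
            sweep_model = msprime.SweepGenicSelection(
                position=sweep.position, start_frequency=start,
                end_frequency=end, s=sweep.s, dt=1.0 / (40 * N),
            )
            ts = msprime.sim_ancestry(
                samples=n_hap // 2, population_size=N, ploidy=2,
                sequence_length=L, recombination_rate=r, random_seed=anc_seed,
                model=[sweep_model, msprime.StandardCoalescent()],
            )
    mts = msprime.sim_mutations(
        ts, rate=mu, random_seed=mut_seed, model=msprime.BinaryMutationModel()
    )
    hap_ids = [f"{model.focal_population}_{i // 2}_{i % 2}" for i in range(n_hap)]
    return _ts_to_haplotypes(mts, chrom, hap_ids, metadata=metadata)
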