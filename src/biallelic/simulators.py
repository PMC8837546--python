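"""Simulators of infinite-sites violations in tumour mutation catalogs.

Two complementary models estimate how many biallelic (and back/forward)
mutations a tumour's burden is expected to produce by chance:

* **Uniform permutation** resamples the observed SNVs uniformly across the
  callable regions of both parental copies, respecting the observed
  trinucleotide spectrum, and tracks the allelic state of every hit locus so
  that parallel, divergent, back and forward events all arise naturally.
* **Neighbour resampling** keeps half the tumour's own (non-driver) mutations
  on one allele and draws the other half, without replacement, from pooled
  mutations of representative tumours (same histology, spectrum cosine >= 0.9).
  Positional collisions between the two halves are biallelic events; back and
  forward mutations cannot be produced.

Burden resampling follows a gamma-Poisson mixture whose gamma mode equals the
observed load with a relative spread of 5%; chromosomes receive mutations via
a Dirichlet-multinomial centred on the observed per-chromosome counts, and
each chromosome's spectrum is drawn from a Dirichlet around its observed
channel counts with a weak pseudocount prior from the sample-wide spectrum.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .spectra import (
    BASES,
    CHANNEL_CONTEXT,
    CHANNEL_OF,
    N_CHANNELS,
    ContextGenome,
    MutationRecord,
    ViolationClass,
    classify_violation,
    compute_spectrum,
    cosine_similarity,
)

#: Pseudocount scale for per-chromosome spectrum sampling (the weak prior is
#: (overall channel count + 1) * PSEUDOCOUNT_SCALE / total burden).
PSEUDOCOUNT_SCALE = 2.0 / 3.0

#: Rejection-sampling attempt budget per mutation.
MAX_ATTEMPTS_PER_MUTATION = 10**6


class ResamplingError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget."""


@dataclass
class BurdenModel:
    """Gamma-Poisson model of the total mutation burden.

    The Poisson rate lambda ~ Gamma(shape beta, rate r) with mode equal to the
    observed burden and standard deviation ``cv`` times it. Solving
    mode = (beta-1)/r = n and sd^2 = beta/r^2 = sigma^2 gives
    r = (n + sqrt(n^2 + 4 sigma^2)) / (2 sigma^2) and beta = 1 + n r.
    """

    n_t_obs: int
    cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_t_obs < 0:
            raise ValueError("observed burden must be non-negative")
        if self.cv <= 0:
            raise ValueError("burden coefficient of variation must be positive")

    @property
    def sigma(self) -> float:
        return self.cv * self.n_t_obs

    @property
    def rate(self) -> float:
        n, s2 = self.n_t_obs, self.sigma**2
        return (n + math.sqrt(n * n + 4 * s2)) / (2 * s2)

    @property
    def shape(self) -> float:
        return 1.0 + self.n_t_obs * self.rate


def sample_total_burden(model: BurdenModel, rng: np.random.Generator) -> int:
    """Draw a simulated total burden; an observed burden of 0 stays 0."""
    if model.n_t_obs == 0:
        return 0
    lam = rng.gamma(shape=model.shape, scale=1.0 / model.rate)
    return int(rng.poisson(lam))


@dataclass
class ChromosomeAllocation:
    """Dirichlet-multinomial allocation of mutations across chromosomes."""

    chromosomes: List[str]
    n_obs: np.ndarray  # observed per-chromosome counts

    def __post_init__(self) -> None:
        self.n_obs = np.asarray(self.n_obs, dtype=float)
        if len(self.chromosomes) == 0:
            raise ValueError("allocation needs at least one chromosome")
        if self.n_obs.shape != (len(self.chromosomes),):
            raise ValueError("one observed count per chromosome required")
        if np.any(self.n_obs < 0):
            raise ValueError("observed counts must be non-negative")

    @property
    def alpha(self) -> np.ndarray:
        return self.n_obs + 1.0


def allocate_to_chromosomes(
    n_t_sim: int, alloc: ChromosomeAllocation, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial draw with Dirichlet(alpha)-sampled probabilities."""
    if n_t_sim < 0:
        raise ValueError("simulated burden must be non-negative")
    pi = rng.dirichlet(alloc.alpha)
    return rng.multinomial(n_t_sim, pi)


def sample_chromosome_spectrum(
    chrom_channel_counts: np.ndarray,
    overall_spectrum_counts: np.ndarray,
    n_t_obs: int,
    rng: np.random.Generator,
    pseudocount_scale: float = PSEUDOCOUNT_SCALE,
) -> np.ndarray:
    """Draw a chromosome's 96 mutation-type probabilities.

    pi_i ~ Dirichlet(mu_i) with mu_ij = (chromosome channel-j count) + psi_j,
    psi_j = (overall channel-j count + 1) * pseudocount_scale / n_t_obs.
    """
    chrom = np.asarray(chrom_channel_counts, dtype=float)
    overall = np.asarray(overall_spectrum_counts, dtype=float)
    if np.any(chrom < 0) or np.any(overall < 0):
        raise ValueError("channel counts must be non-negative")
    if n_t_obs <= 0:
        raise ValueError("total observed burden must be positive")
    psi = (overall + 1.0) * pseudocount_scale / n_t_obs
    return rng.dirichlet(chrom + psi)


@dataclass
class ViolationTally:
    """Violation counts from one simulation replicate.

    Per-class counts tally each classified second hit once (one parallel pair
    contributes one parallel count). ``n_violating_mutations`` counts every
    mutation residing at a multi-hit locus (a pair contributes two); this is
    the quantity the birthday-problem closed form counts.
    """

    replicate: int
    parallel: int = 0
    divergent: int = 0
    back: int = 0
    forward: int = 0
    n_t_sim: int = 0
    n_violating_mutations: int = 0
    parallel_spectrum: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CHANNELS)
    )
    divergent_spectrum: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CHANNELS)
    )
    hit_spectrum: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CHANNELS)
    )

    @property
    def biallelic(self) -> int:
        return self.parallel + self.divergent

    @property
    def total(self) -> int:
        return self.parallel + self.divergent + self.back + self.forward


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # deterministic, order-independent child stream per replicate
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


class _ChromSampler:
    """Precomputed per-chromosome tables for overlay-aware rejection sampling."""

    def __init__(self, genome: ContextGenome, chrom: str):
        self.chrom = chrom
        self.seq = genome.sequences[chrom]
        self.positions = genome.callable_positions(chrom)  # 0-based
        if len(self.positions) == 0:
            raise ValueError(f"no callable context positions on {chrom}")
        self.f = genome.channel_abundance(chrom).astype(float)
        # reference-state lookup: for each callable position, the channel and
        # resulting base of each of the three alternate substitutions
        n = len(self.positions)
        self.ref_channels = np.empty((n, 3), dtype=np.int16)
        self.ref_newbase = np.empty((n, 3), dtype="U1")
        self.ref_centre = np.empty(n, dtype="U1")
        for i, p in enumerate(self.positions):
            tri = self.seq[p - 1 : p + 2]
            centre = tri[1]
            self.ref_centre[i] = centre
            for k, alt in enumerate(b for b in BASES if b != centre):
                self.ref_channels[i, k] = CHANNEL_OF[(tri, alt)]
                self.ref_newbase[i, k] = alt


def run_uniform_permutation(
    catalog: Sequence[MutationRecord],
    genome: ContextGenome,
    replicates: int,
    seed: int,
    burden_cv: float = 0.05,
    pseudocount_scale: float = PSEUDOCOUNT_SCALE,
    max_attempts: int = MAX_ATTEMPTS_PER_MUTATION,
) -> List[ViolationTally]:
    """Uniform-permutation simulation of infinite sites violations.

    Per replicate: resample the total burden (gamma-Poisson), divide it across
    chromosomes (Dirichlet-multinomial), draw per-chromosome spectra
    (Dirichlet), then sequentially rejection-sample mutations uniformly over
    the two allelic copies of the callable regions. A candidate draw at a
    position whose *current* (overlay-aware) trinucleotide is T and alternate
    base a is accepted with probability proportional to pi_j / f_j for the
    implied channel j, which reproduces the target spectrum over reference
    contexts and lets back/forward hits occur at already-mutated sites. Each
    accepted hit updates the diploid overlay and is classified against the
    locus's current allelic state.
    """
    snvs = [r for r in catalog if r.vtype == "snv"]
    if not snvs:
        raise ValueError("uniform permutation requires a non-empty SNV catalog")
    chroms = sorted({r.chrom for r in snvs})
    for c in chroms:
        if not genome.callable_intervals.get(c):
            raise ValueError(f"no callable intervals for chromosome {c}")

    per_chrom_counts = Counter(r.chrom for r in snvs)
    alloc = ChromosomeAllocation(
        chromosomes=chroms,
        n_obs=np.array([per_chrom_counts[c] for c in chroms], dtype=float),
    )
    overall_counts = compute_spectrum(snvs, genome).counts
    chrom_channel_counts = {
        c: compute_spectrum([r for r in snvs if r.chrom == c], genome).counts
        for c in chroms
    }
    n_t_obs = len(snvs)
    burden = BurdenModel(n_t_obs=n_t_obs, cv=burden_cv)
    samplers = {c: _ChromSampler(genome, c) for c in chroms}

    tallies: List[ViolationTally] = []
    for rep in range(replicates):
        rng = _replicate_rng(seed, rep)
        tally = ViolationTally(replicate=rep)
        n_t_sim = sample_total_burden(burden, rng)
        tally.n_t_sim = n_t_sim
        n_per_chrom = allocate_to_chromosomes(n_t_sim, alloc, rng)
        hit_counts: Dict[Tuple[str, int], int] = {}
        for c, n_i in zip(chroms, n_per_chrom):
            if n_i == 0:
                continue
            pi = sample_chromosome_spectrum(
                chrom_channel_counts[c],
                overall_counts,
                n_t_obs,
                rng,
                pseudocount_scale,
            )
            _sample_chromosome_hits(
                samplers[c], pi, int(n_i), rng, tally, hit_counts, max_attempts
            )
        tally.n_violating_mutations = sum(k for k in hit_counts.values() if k >= 2)
        tallies.append(tally)
    return tallies


def _sample_chromosome_hits(
    sampler: _ChromSampler,
    pi: np.ndarray,
    n_hits: int,
    rng: np.random.Generator,
    tally: ViolationTally,
    hit_counts: Dict[Tuple[str, int], int],
    max_attempts: int,
) -> None:
    """Sequential overlay-aware rejection sampling of ``n_hits`` mutations."""
    f = sampler.f
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = np.where(f > 0, pi / np.where(f > 0, f, 1.0), 0.0)
    m = weights.max()
    if m <= 0:
        raise ResamplingError(
            f"no channel with available context on {sampler.chrom}"
        )
    weights = weights / m

    chrom = sampler.chrom
    positions = sampler.positions
    n_pos = len(positions)
    overlay: Dict[Tuple[int, int], str] = {}  # (0-based pos, allele) -> base
    seq = sampler.seq

    accepted = 0
    attempts_since_accept = 0
    batch = max(256, 4 * n_hits)
    while accepted < n_hits:
        idxs = rng.integers(0, n_pos, size=batch)
        alleles = rng.integers(0, 2, size=batch)
        alt_choices = rng.integers(0, 3, size=batch)
        us = rng.random(size=batch)
        for idx, allele, kk, u in zip(idxs, alleles, alt_choices, us):
            attempts_since_accept += 1
            if attempts_since_accept > max_attempts:
                raise ResamplingError(
                    f"rejection sampling exhausted {max_attempts} attempts "
                    f"per mutation on {chrom}"
                )
            p = int(positions[idx])
            key_same = (p, int(allele))
            touched = (
                (p - 1, allele) in overlay
                or key_same in overlay
                or (p + 1, allele) in overlay
            )
            if not touched:
                ch = int(sampler.ref_channels[idx, kk])
                if u >= weights[ch]:
                    continue
                new_base = str(sampler.ref_newbase[idx, kk])
                cur_same = str(sampler.ref_centre[idx])
            else:
                b5 = overlay.get((p - 1, int(allele)), seq[p - 1])
                cur_same = overlay.get(key_same, seq[p])
                b3 = overlay.get((p + 1, int(allele)), seq[p + 1])
                tri = b5 + cur_same + b3
                alts = [b for b in BASES if b != cur_same]
                new_base = alts[kk]
                ch = CHANNEL_OF.get((tri, new_base))
                if ch is None:
                    continue
                fj = f[CHANNEL_CONTEXT[ch]]
                if fj == 0:
                    continue
                if u >= (pi[ch] / fj) / m:
                    continue
            # accepted hit
            tally.hit_spectrum[ch] += 1
            locus = (chrom, p)
            prior = hit_counts.get(locus, 0)
            ref_base = seq[p]
            if prior > 0:
                cur_other = overlay.get((p, 1 - int(allele)), ref_base)
                vclass = classify_violation(ref_base, cur_same, cur_other, new_base)
                if vclass is ViolationClass.PARALLEL:
                    tally.parallel += 1
                    _add_channel(tally.parallel_spectrum, seq, p, new_base)
                elif vclass is ViolationClass.DIVERGENT:
                    tally.divergent += 1
                    _add_channel(tally.divergent_spectrum, seq, p, new_base)
                elif vclass is ViolationClass.BACK:
                    tally.back += 1
                elif vclass is ViolationClass.FORWARD:
                    tally.forward += 1
            if new_base == ref_base:
                overlay.pop(key_same, None)
            else:
                overlay[key_same] = new_base
            hit_counts[locus] = prior + 1
            accepted += 1
            attempts_since_accept = 0
            if accepted == n_hits:
                return


def _add_channel(spectrum: np.ndarray, seq: str, p: int, alt: str) -> None:
    """Add a violation to a spectrum using the reference context at 0-based p."""
    tri = seq[p - 1 : p + 2]
    ch = CHANNEL_OF.get((tri, alt))
    if ch is None and alt == tri[1]:
        return  # back to reference: no substitution channel
    if ch is not None:
        spectrum[ch] += 1


@dataclass
class DonorCatalog:
    """A neighbour tumour's catalog with its histology label."""

    sample_id: str
    histology: str
    records: List[MutationRecord]


@dataclass
class CohortPool:
    """Pooled non-driver mutations from representative same-histology donors."""

    target_sample_id: str
    records: List[MutationRecord]
    eligible: bool
    donor_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(r.is_driver for r in self.records):
            raise ValueError("cohort pool must not contain driver mutations")


def select_representative_pool(
    target: DonorCatalog,
    cohort: Sequence[DonorCatalog],
    genome: ContextGenome,
    min_cosine: float = 0.9,
    pool_factor: float = 0.5,
) -> CohortPool:
    """Pool non-driver mutations of representative neighbours of a tumour.

    A donor is representative when it shares the target's histology and its
    mutation spectrum has cosine similarity >= ``min_cosine`` with the
    target's. The pool is eligible when it holds at least ``pool_factor``
    times the target's total burden.
    """
    target_snvs = [r for r in target.records if r.vtype == "snv"]
    target_spec = compute_spectrum(target_snvs, genome) if target_snvs else None
    pool: List[MutationRecord] = []
    donors: List[str] = []
    for donor in cohort:
        if donor.sample_id == target.sample_id:
            continue
        if donor.histology != target.histology:
            continue
        donor_snvs = [r for r in donor.records if r.vtype == "snv"]
        if target_spec is None or not donor_snvs:
            continue
        cos = cosine_similarity(target_spec, compute_spectrum(donor_snvs, genome))
        if cos >= min_cosine:
            pool.extend(r for r in donor.records if not r.is_driver)
            donors.append(donor.sample_id)
    eligible = len(pool) >= pool_factor * len(target.records)
    return CohortPool(
        target_sample_id=target.sample_id,
        records=pool,
        eligible=eligible,
        donor_ids=donors,
    )


def _indel_key(rec: MutationRecord) -> Tuple[str, int, str, str]:
    return (rec.chrom, rec.pos, rec.ref, rec.alts[0])


def run_neighbour_resampling(
    target_catalog: Sequence[MutationRecord],
    pool: CohortPool,
    replicates: int,
    seed: int,
    vtype: str = "snv",
    genome: Optional[ContextGenome] = None,
) -> List[ViolationTally]:
    """Neighbour-resampling simulation of biallelic violations.

    Per replicate, allele A keeps ceil(n/2) of the target's own non-driver
    mutations and allele B draws floor(n/2) from the pool without replacement
    (same-position duplicates within allele B are redrawn). Any A/B pair at
    the same position is a biallelic event: same alternate allele -> parallel,
    different -> divergent. Back and forward mutations cannot occur.
    """
    records = [
        r for r in target_catalog if r.vtype == vtype and not r.is_driver
    ]
    if not records:
        raise ValueError("target catalog has no resampleable mutations")
    pool_records = [r for r in pool.records if r.vtype == vtype]
    n = len(records)
    n_a = (n + 1) // 2
    n_b = n // 2
    if len(pool_records) < n_b:
        raise ValueError(
            f"pool of {len(pool_records)} records cannot supply {n_b} draws "
            "(pool ineligible)"
        )

    tallies: List[ViolationTally] = []
    for rep in range(replicates):
        rng = _replicate_rng(seed, rep)
        tally = ViolationTally(replicate=rep, n_t_sim=n)
        a_idx = rng.choice(n, size=n_a, replace=False)
        a_by_pos: Dict[Tuple[str, int], MutationRecord] = {
            (records[i].chrom, records[i].pos): records[i] for i in a_idx
        }
        # without-replacement walk of a permuted pool, skipping same-allele
        # (within-B) positional duplicates
        order = rng.permutation(len(pool_records))
        b_positions: set = set()
        taken = 0
        for j in order:
            rec = pool_records[j]
            key = (rec.chrom, rec.pos)
            if key in b_positions:
                continue
            b_positions.add(key)
            taken += 1
            mate = a_by_pos.get(key)
            if mate is not None:
                if vtype == "snv":
                    parallel = rec.alts[0] == mate.alts[0]
                else:
                    parallel = (rec.ref, rec.alts[0]) == (mate.ref, mate.alts[0])
                if parallel:
                    tally.parallel += 1
                    if genome is not None and vtype == "snv":
                        _add_channel(
                            tally.parallel_spectrum,
                            genome.sequences[rec.chrom],
                            rec.pos - 1,
                            rec.alts[0],
                        )
                else:
                    tally.divergent += 1
                    if genome is not None and vtype == "snv":
                        _add_channel(
                            tally.divergent_spectrum,
                            genome.sequences[rec.chrom],
                            rec.pos - 1,
                            rec.alts[0],
                        )
            if taken == n_b:
                break
        if taken < n_b:
            raise ValueError(
                "pool exhausted before drawing allele B (positional duplicates)"
            )
        tally.n_violating_mutations = 2 * (tally.parallel + tally.divergent)
        tallies.append(tally)
    return tallies


@dataclass
class TallySummary:
    """Replicate summary: per-class moments, percentiles and pooled spectra."""

    n_replicates: int
    mean: Dict[str, float]
    se: Dict[str, float]
    q025: Dict[str, float]
    q975: Dict[str, float]
    fraction_with_violation: float
    pooled_parallel_spectrum: np.ndarray
    pooled_divergent_spectrum: np.ndarray
    pooled_hit_spectrum: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CHANNELS)
    )

    @property
    def mean_biallelic(self) -> float:
        return self.mean["parallel"] + self.mean["divergent"]


def summarize_tallies(tallies: Sequence[ViolationTally]) -> TallySummary:
    """Mean, Monte-Carlo SE, 2.5/97.5 percentiles and pooled spectra."""
    if not tallies:
        raise ValueError("summary requires at least one replicate tally")
    r = len(tallies)
    classes = {
        "parallel": np.array([t.parallel for t in tallies], dtype=float),
        "divergent": np.array([t.divergent for t in tallies], dtype=float),
        "back": np.array([t.back for t in tallies], dtype=float),
        "forward": np.array([t.forward for t in tallies], dtype=float),
        "total": np.array([t.total for t in tallies], dtype=float),
        "violating_mutations": np.array(
            [t.n_violating_mutations for t in tallies], dtype=float
        ),
    }
    return TallySummary(
        n_replicates=r,
        mean={k: float(v.mean()) for k, v in classes.items()},
        se={k: float(v.std(ddof=1) / math.sqrt(r)) if r > 1 else 0.0
            for k, v in classes.items()},
        q025={k: float(np.percentile(v, 2.5)) for k, v in classes.items()},
        q975={k: float(np.percentile(v, 97.5)) for k, v in classes.items()},
        fraction_with_violation=float(
            np.mean([1.0 if t.total > 0 else 0.0 for t in tallies])
        ),
        pooled_parallel_spectrum=np.sum(
            [t.parallel_spectrum for t in tallies], axis=0
        ),
        pooled_divergent_spectrum=np.sum(
            [t.divergent_spectrum for t in tallies], axis=0
        ),
        pooled_hit_spectrum=np.sum([t.hit_spectrum for t in tallies], axis=0),
    )
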