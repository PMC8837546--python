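"""Synthetic tumour cohorts with known biallelic truth.

The generator inverts the detection model: it builds a random reference
genome, draws a mutation catalog from a requested trinucleotide spectrum with
planted biallelic parallel/divergent events, simulates beta-binomially
over-dispersed read counts at heterozygous SNPs and somatic SNVs conditioned
on purity and allele-specific copy number, and emits phased read-pair
evidence — together with a truth manifest so that every pipeline stage can be
benchmarked offline.

The expected variant allele frequency of a mutation present on k copies in a
segment with total tumour copy number c is rho*k / (2(1-rho) + rho*c); a
heterozygous SNP's major-allele frequency is ((1-rho) + rho*n_maj) over the
same denominator. Read depths are Poisson around the coverage implied by the
segment's copy number, and allele counts are beta-binomial with the
generator's concentration omega_true.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .spectra import (
    BASES,
    N_CHANNELS,
    ContextGenome,
    MutationRecord,
    TrinucleotideSpectrum,
)
from .vaf import (
    CopyNumberSegment,
    HetSNPObservation,
    PurityPloidy,
    SampleBundle,
    SiteResources,
    SNVObservation,
)
from .phasing import MAX_PHASING_DISTANCE, PhasedPairEvidence


@dataclass(frozen=True)
class SegmentSpec:
    """One copy-number state along a synthetic chromosome."""

    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.major < self.minor or self.minor < 0:
            raise ValueError("need major >= minor >= 0")

    @property
    def total(self) -> int:
        return self.major + self.minor


@dataclass
class SegmentLayout:
    """Contiguous, non-overlapping copy-number segments covering each chromosome."""

    segments: Dict[str, List[Tuple[int, int, SegmentSpec]]]  # 1-based inclusive

    def __post_init__(self) -> None:
        for chrom, segs in self.segments.items():
            pos = 1
            for start, end, _ in segs:
                if start != pos or end < start:
                    raise ValueError(
                        f"segments on {chrom} must tile the chromosome contiguously"
                    )
                pos = end + 1

    @classmethod
    def even(
        cls, chrom_lengths: Dict[str, int], states: Sequence[SegmentSpec]
    ) -> "SegmentLayout":
        """Split every chromosome evenly across the given copy states."""
        segments: Dict[str, List[Tuple[int, int, SegmentSpec]]] = {}
        for chrom, length in chrom_lengths.items():
            bounds = np.linspace(0, length, len(states) + 1).astype(int)
            segments[chrom] = [
                (int(bounds[i]) + 1, int(bounds[i + 1]), states[i])
                for i in range(len(states))
            ]
        return cls(segments)

    def spec_at(self, chrom: str, pos: int) -> SegmentSpec:
        for start, end, spec in self.segments[chrom]:
            if start <= pos <= end:
                return spec
        raise KeyError(f"no segment at {chrom}:{pos}")


@dataclass
class TruthManifest:
    """Ground truth of one synthetic sample, sufficient for regeneration."""

    sample_id: str
    seed: int
    parallel: List[Dict] = field(default_factory=list)
    divergent: List[Dict] = field(default_factory=list)
    singles: List[Dict] = field(default_factory=list)
    traps: List[Dict] = field(default_factory=list)
    params: Dict = field(default_factory=dict)

    def parallel_keys(self) -> set:
        return {(e["chrom"], e["pos"]) for e in self.parallel}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


def generate_reference(
    chrom_lengths: Dict[str, int],
    gc_fraction: float = 0.41,
    seed: int = 0,
    masked_windows: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> ContextGenome:
    """I.i.d. random reference at the stated GC with callable intervals.

    Callable intervals cover each chromosome minus any masked windows
    (0-based half-open).
    """
    for chrom, length in chrom_lengths.items():
        if length < 1000:
            raise ValueError(f"chromosome {chrom} must be at least 1 kb")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
         (1 - gc_fraction) / 2]
    )
    sequences: Dict[str, str] = {}
    callable_intervals: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, length in chrom_lengths.items():
        codes = rng.choice(4, size=length, p=probs)
        sequences[chrom] = "".join(BASES[c] for c in codes)
        masked = sorted((masked_windows or {}).get(chrom, []))
        intervals: List[Tuple[int, int]] = []
        cursor = 0
        for mstart, mend in masked:
            if mstart > cursor:
                intervals.append((cursor, mstart))
            cursor = max(cursor, mend)
        if cursor < length:
            intervals.append((cursor, length))
        callable_intervals[chrom] = intervals
    return ContextGenome(sequences, callable_intervals)


from .spectra import CHANNEL_CONTEXT, COMPLEMENT, SUBSTITUTIONS


class _PositionSampler:
    """Samples catalog positions per channel without replacement.

    Positions are indexed by pyrimidine-normalised context class; the actual
    alternate base at a purine-strand position is the complement of the
    channel's pyrimidine-frame alternate.
    """

    def __init__(self, genome: ContextGenome):
        self.by_class: Dict[int, List[Tuple[str, np.ndarray, np.ndarray]]] = {}
        for chrom in genome.chromosomes:
            seq = genome.sequences[chrom]
            pos = genome.callable_positions(chrom)  # 0-based
            if len(pos) == 0:
                continue
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            base_idx = np.full(codes.shape, -1, dtype=np.int8)
            for i, b in enumerate(BASES):
                base_idx[codes == ord(b)] = i
            five, centre, three = (
                base_idx[pos - 1], base_idx[pos], base_idx[pos + 1]
            )
            pur = (centre == 0) | (centre == 2)  # A or G: purine strand
            cls = np.where(
                pur,
                np.where(centre == 0, 1, 0) * 16 + (3 - three) * 4 + (3 - five),
                np.where(centre == 1, 0, 1) * 16 + five * 4 + three,
            )
            for c in np.unique(cls):
                mask = cls == c
                self.by_class.setdefault(int(c), []).append(
                    (chrom, pos[mask], pur[mask])
                )
        self.used: set = set()

    def draw(
        self,
        channel: int,
        rng: np.random.Generator,
        predicate=None,
    ) -> Tuple[str, int, str]:
        cls = int(CHANNEL_CONTEXT[channel])
        pools = self.by_class.get(cls, [])
        if not pools:
            raise ValueError(
                f"no genomic context available for channel {channel}"
            )
        sizes = np.array([len(p[1]) for p in pools])
        pyr_alt = SUBSTITUTIONS[channel // 16][1]
        for _ in range(10_000):
            k = int(rng.integers(0, sizes.sum()))
            for chrom, positions, flipped in pools:
                if k < len(positions):
                    break
                k -= len(positions)
            pos = int(positions[k]) + 1  # 1-based
            if (chrom, pos) in self.used:
                continue
            if predicate is not None and not predicate(chrom, pos):
                continue
            self.used.add((chrom, pos))
            alt = COMPLEMENT[pyr_alt] if flipped[k] else pyr_alt
            return chrom, pos, alt
        raise ValueError(
            f"insufficient unused context loci for channel {channel}"
        )


def generate_catalog(
    genome: ContextGenome,
    spectrum: TrinucleotideSpectrum,
    burden: int,
    biallelic_plan: Tuple[int, int] = (0, 0),
    seed: int = 0,
    sample_id: str = "synthetic",
    layout: Optional[SegmentLayout] = None,
) -> Tuple[List[MutationRecord], TruthManifest]:
    """Draw a mutation catalog with planted biallelic events.

    Single SNVs follow the requested spectrum at uniform positions within
    each context class; parallel events plant the same substitution on both
    alleles (emitted as an ordinary one-ALT record — their biallelic nature
    lives in the manifest and the read counts), divergent events emit two-ALT
    records. Planted events avoid LOH segments when a layout is given.
    """
    n_parallel, n_divergent = biallelic_plan
    if burden < n_parallel + n_divergent:
        raise ValueError("burden must cover the planted biallelic events")
    if not spectrum.normalised:
        spectrum = spectrum.normalise()
    rng = np.random.default_rng(seed)
    sampler = _PositionSampler(genome)

    def non_loh(chrom: str, pos: int) -> bool:
        if layout is None:
            return True
        return layout.spec_at(chrom, pos).minor >= 1

    channels = rng.choice(N_CHANNELS, size=burden, p=spectrum.counts)
    records: List[MutationRecord] = []
    manifest = TruthManifest(
        sample_id=sample_id,
        seed=seed,
        params={"burden": burden, "n_parallel": n_parallel,
                "n_divergent": n_divergent},
    )
    for i, ch in enumerate(channels):
        if i < n_parallel:
            chrom, pos, alt = sampler.draw(int(ch), rng, predicate=non_loh)
            ref = genome.base(chrom, pos)
            records.append(
                MutationRecord(chrom, pos, ref, (alt,), sample_id=sample_id)
            )
            manifest.parallel.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
            )
        elif i < n_parallel + n_divergent:
            chrom, pos, alt = sampler.draw(int(ch), rng, predicate=non_loh)
            ref = genome.base(chrom, pos)
            others = [b for b in BASES if b not in (ref, alt)]
            alt2 = others[rng.integers(0, len(others))]
            records.append(
                MutationRecord(chrom, pos, ref, (alt, alt2), sample_id=sample_id)
            )
            manifest.divergent.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt1": alt,
                 "alt2": alt2}
            )
        else:
            chrom, pos, alt = sampler.draw(int(ch), rng)
            ref = genome.base(chrom, pos)
            records.append(
                MutationRecord(chrom, pos, ref, (alt,), sample_id=sample_id)
            )
            manifest.singles.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
            )
    return records, manifest


def _betabinom_draw(
    rng: np.random.Generator, n: int, m: float, omega: float
) -> int:
    m = min(max(m, 1e-9), 1 - 1e-9)
    p = rng.beta(m * omega, (1 - m) * omega)
    return int(rng.binomial(n, p))


def simulate_observations(
    manifest: TruthManifest,
    layout: SegmentLayout,
    pp: PurityPloidy,
    mean_depth: float = 60.0,
    omega_true: float = 300.0,
    het_snp_density: float = 1 / 1500,
    seed: int = 0,
    pre_gain_fraction: float = 0.2,
    late_parallel: bool = False,
    n_trap_germline: int = 0,
    n_trap_sv: int = 0,
) -> SampleBundle:
    """Simulate read-count observations for a generated catalog.

    Het SNPs are placed at the stated density with beta-binomial major-allele
    counts at the segment's expected BAF; SNV alternate counts are
    beta-binomial at the multiplicity-determined expected VAF. Parallel
    events get multiplicity major+minor (clonal early event) unless
    ``late_parallel``, which mutates a single copy of each allele. A fraction
    ``pre_gain_fraction`` of single SNVs in gained segments predate the gain
    (multiplicity = major). Trap sites (an SNV placed on a het SNP, an SNV
    inside an emitted common-SV window) exercise the positional filters.
    """
    rng = np.random.default_rng(seed)
    rho, psi = pp.rho, pp.psi_t
    cbar = 2 * (1 - rho) + rho * psi

    chrom_lengths = {
        chrom: segs[-1][1] for chrom, segs in layout.segments.items()
    }
    snv_positions = {
        (e["chrom"], e["pos"])
        for group in (manifest.parallel, manifest.divergent, manifest.singles)
        for e in group
    }

    # --- heterozygous SNPs
    het_snps: List[HetSNPObservation] = []
    snp_positions: Dict[str, List[int]] = {c: [] for c in chrom_lengths}
    for chrom, length in chrom_lengths.items():
        n_snps = rng.poisson(length * het_snp_density)
        pos_pool = rng.choice(np.arange(2, length), size=min(n_snps, length - 2),
                              replace=False)
        for pos in sorted(int(p) for p in pos_pool):
            if (chrom, pos) in snv_positions:
                continue
            spec = layout.spec_at(chrom, pos)
            if spec.minor == 0:
                continue  # no heterozygous signal in LOH
            c = spec.total
            csite = 2 * (1 - rho) + rho * c
            depth = max(1, int(rng.poisson(mean_depth * csite / cbar)))
            baf_true = ((1 - rho) + rho * spec.major) / csite
            v = _betabinom_draw(rng, depth, baf_true, omega_true)
            het_snps.append(
                HetSNPObservation(
                    chrom=chrom,
                    pos=pos,
                    major_count=v,
                    minor_count=depth - v,
                    logr=math.log2(max(depth, 1) / mean_depth),
                )
            )
            snp_positions[chrom].append(pos)

    # --- segments with data-derived BAF_seg / logR_seg
    segments: List[CopyNumberSegment] = []
    for chrom, segs in layout.segments.items():
        for start, end, spec in segs:
            in_seg = [
                s for s in het_snps if s.chrom == chrom and start <= s.pos <= end
            ]
            if in_seg:
                baf = sum(s.major_count for s in in_seg) / sum(
                    s.total for s in in_seg
                )
                logr = float(np.median([s.logr for s in in_seg]))
            else:
                csite = 2 * (1 - rho) + rho * spec.total
                baf = ((1 - rho) + rho * spec.major) / csite if spec.total else 1.0
                logr = math.log2(csite / cbar)
            segments.append(
                CopyNumberSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    major=spec.major,
                    minor=spec.minor,
                    baf_seg=min(max(baf, 0.5), 1.0),
                    logr_seg=logr,
                )
            )

    # --- somatic SNV read counts
    def observe(chrom: str, pos: int, ref: str, alt: str, mult: int) -> SNVObservation:
        spec = layout.spec_at(chrom, pos)
        csite = 2 * (1 - rho) + rho * spec.total
        depth = max(1, int(rng.poisson(mean_depth * csite / cbar)))
        vaf = rho * mult / csite if csite > 0 else 0.0
        v = _betabinom_draw(rng, depth, vaf, omega_true)
        return SNVObservation(
            chrom=chrom, pos=pos, ref=ref, alt=alt, alt_count=v, total=depth
        )

    snvs: List[SNVObservation] = []
    truth_mult: Dict[Tuple[str, int], Tuple[int, int]] = {}  # (maj_mult, min_mult)
    for e in manifest.parallel:
        spec = layout.spec_at(e["chrom"], e["pos"])
        if late_parallel:
            maj_m, min_m = 1, min(1, spec.minor)
        else:
            maj_m, min_m = spec.major, spec.minor
        truth_mult[(e["chrom"], e["pos"])] = (maj_m, min_m)
        snvs.append(observe(e["chrom"], e["pos"], e["ref"], e["alt"],
                            maj_m + min_m))
    for e in manifest.divergent:
        snvs.append(observe(e["chrom"], e["pos"], e["ref"], e["alt1"], 1))
    for e in manifest.singles:
        spec = layout.spec_at(e["chrom"], e["pos"])
        if spec.major >= 2 and rng.random() < pre_gain_fraction:
            mult, hap = spec.major, "major"
        else:
            on_minor = (
                spec.minor >= 1
                and rng.random() < spec.minor / max(spec.total, 1)
            )
            mult, hap = 1, ("minor" if on_minor else "major")
        e["multiplicity"] = mult
        e["haplotype"] = hap
        snvs.append(observe(e["chrom"], e["pos"], e["ref"], e["alt"], mult))

    # --- positional resources (+ optional trap sites)
    sv_intervals: Dict[str, List[Tuple[int, int]]] = {}
    trap_records: List[Dict] = []
    chroms = list(chrom_lengths)
    for i in range(n_trap_sv):
        chrom = chroms[i % len(chroms)]
        length = chrom_lengths[chrom]
        start = int(rng.integers(2, length - 200))
        sv_intervals.setdefault(chrom, []).append((start, start + 100))
        pos = start + 50
        snvs.append(observe(chrom, pos, "A", "T", 1))
        trap_records.append({"chrom": chrom, "pos": pos, "filter": "common-sv"})
    for i in range(n_trap_germline):
        chrom = chroms[i % len(chroms)]
        candidates = snp_positions[chrom]
        if not candidates:
            continue
        pos = candidates[int(rng.integers(0, len(candidates)))]
        snvs.append(observe(chrom, pos, "A", "T", 1))
        trap_records.append(
            {"chrom": chrom, "pos": pos, "filter": "germline-overlap"}
        )
    manifest.traps.extend(trap_records)
    manifest.params.update(
        {
            "rho": rho,
            "psi_t": psi,
            "mean_depth": mean_depth,
            "omega_true": omega_true,
            "het_snp_density": het_snp_density,
            "observation_seed": seed,
            "late_parallel": late_parallel,
        }
    )

    resources = SiteResources(
        germline_snp_positions={
            c: frozenset(p) for c, p in snp_positions.items()
        },
        common_sv_intervals=sv_intervals,
        het_snp_positions={
            c: np.array(sorted(p), dtype=np.int64)
            for c, p in snp_positions.items()
        },
    )
    return SampleBundle(
        sample_id=manifest.sample_id,
        pp=pp,
        segments=segments,
        het_snps=het_snps,
        snvs=snvs,
        resources=resources,
    )


def simulate_phased_pairs(
    manifest: TruthManifest,
    bundle: SampleBundle,
    layout: SegmentLayout,
    pairs_per_site: int = 20,
    error_rate: float = 0.0,
    seed: int = 0,
) -> List[PhasedPairEvidence]:
    """Phased read-pair evidence for every SNV with a het SNP in range.

    The SNP alternate allele sits on the major haplotype. Pair-category
    probabilities mix tumour haplotype copies (weighted by copy number and
    the mutation's per-haplotype multiplicity) with admixed normal cells;
    a symmetric ``error_rate`` independently flips each observed allele.
    SNVs without a SNP within 700 bp are omitted.
    """
    rng = np.random.default_rng(seed)
    rho = bundle.pp.rho
    snp_by_chrom: Dict[str, np.ndarray] = {}
    for snp in bundle.het_snps:
        snp_by_chrom.setdefault(snp.chrom, [])
    tmp: Dict[str, List[int]] = {c: [] for c in snp_by_chrom}
    for snp in bundle.het_snps:
        tmp[snp.chrom].append(snp.pos)
    snp_by_chrom = {c: np.array(sorted(v)) for c, v in tmp.items()}

    def haplotype_mults(entry: Dict, kind: str) -> Tuple[float, float]:
        spec = layout.spec_at(entry["chrom"], entry["pos"])
        if kind == "parallel":
            if manifest.params.get("late_parallel"):
                return (
                    1 / max(spec.major, 1),
                    (1 / spec.minor) if spec.minor else 0.0,
                )
            return 1.0, 1.0
        mult = entry.get("multiplicity", 1)
        if entry.get("haplotype", "major") == "minor":
            return 0.0, (min(mult, spec.minor) / spec.minor) if spec.minor else 0.0
        return min(mult, spec.major) / max(spec.major, 1), 0.0

    evidence: List[PhasedPairEvidence] = []
    for kind, group in (("parallel", manifest.parallel),
                        ("single", manifest.singles)):
        for entry in group:
            chrom, pos = entry["chrom"], entry["pos"]
            snps = snp_by_chrom.get(chrom)
            if snps is None or len(snps) == 0:
                continue
            nearest = int(snps[np.argmin(np.abs(snps - pos))])
            if abs(nearest - pos) > MAX_PHASING_DISTANCE:
                continue
            spec = layout.spec_at(chrom, pos)
            mu_maj, mu_min = haplotype_mults(entry, kind)
            w = np.array(
                [
                    (1 - rho) + rho * spec.minor * (1 - mu_min),  # RR
                    rho * spec.minor * mu_min,                    # RA
                    (1 - rho) + rho * spec.major * (1 - mu_maj),  # AR
                    rho * spec.major * mu_maj,                    # AA
                ]
            )
            p = w / w.sum()
            if error_rate > 0:
                e = error_rate
                # independent flip of each of the two observed alleles
                flip = np.array(
                    [
                        [(1-e)*(1-e), (1-e)*e, e*(1-e), e*e],
                        [(1-e)*e, (1-e)*(1-e), e*e, e*(1-e)],
                        [e*(1-e), e*e, (1-e)*(1-e), (1-e)*e],
                        [e*e, e*(1-e), (1-e)*e, (1-e)*(1-e)],
                    ]
                )
                p = p @ flip
            counts = rng.multinomial(pairs_per_site, p)
            evidence.append(
                PhasedPairEvidence(
                    snp_chrom=chrom,
                    snp_pos=nearest,
                    snv_pos=pos,
                    n_rr=int(counts[0]),
                    n_ra=int(counts[1]),
                    n_ar=int(counts[2]),
                    n_aa=int(counts[3]),
                    sample_id=manifest.sample_id,
                )
            )
    return evidence
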