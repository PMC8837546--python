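"""Trinucleotide mutation spectra and infinite-sites violation classes.

The 96-channel convention classifies every single-base substitution by the
mutated pyrimidine and its two flanking bases. Substitutions observed at a
purine are reverse-complemented onto the pyrimidine strand, so that e.g.
``TGT G>A`` and ``ACA C>T`` fall in the same channel, ``A[C>T]A``.

Channels are ordered in the standard COSMIC lexicographic order: the six
pyrimidine substitutions C>A, C>G, C>T, T>A, T>C, T>G, each expanded over the
sixteen 5'/3' flank combinations (A, C, G, T on each side). This ordering is
frozen and used for all serialisation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine substitutions in frozen order.
SUBSTITUTIONS: Tuple[Tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
)

N_CHANNELS = 96
#: Number of pyrimidine-centred trinucleotide context classes (2 centres x 16 flanks).
N_CONTEXTS = 32


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_label(channel: int) -> str:
    """Human-readable label such as ``A[C>T]G`` for a channel index."""
    sub, flank = divmod(channel, 16)
    five, three = divmod(flank, 4)
    ref, alt = SUBSTITUTIONS[sub]
    return f"{BASES[five]}[{ref}>{alt}]{BASES[three]}"


CHANNEL_LABELS: Tuple[str, ...] = tuple(channel_label(i) for i in range(N_CHANNELS))


def _build_channel_map() -> Dict[Tuple[str, str], int]:
    """Map every strand-specific (trinucleotide, alt) pair to its channel.

    Covers all 64 trinucleotides x 3 alternate bases = 192 cases; purine-centred
    triplets are reverse-complemented before lookup.
    """
    sub_index = {s: i for i, s in enumerate(SUBSTITUTIONS)}
    table: Dict[Tuple[str, str], int] = {}
    for five, centre, three in itertools.product(BASES, repeat=3):
        tri = five + centre + three
        for alt in BASES:
            if alt == centre:
                continue
            if centre in PYRIMIDINES:
                sub = sub_index[(centre, alt)]
                idx = sub * 16 + BASES.index(five) * 4 + BASES.index(three)
            else:
                rc_tri = revcomp(tri)
                rc_alt = COMPLEMENT[alt]
                sub = sub_index[(rc_tri[1], rc_alt)]
                idx = sub * 16 + BASES.index(rc_tri[0]) * 4 + BASES.index(rc_tri[2])
            table[(tri, alt)] = idx
    return table


#: (trinucleotide, alt base) -> channel index, for all 192 strand-specific cases.
CHANNEL_OF: Dict[Tuple[str, str], int] = _build_channel_map()


def context_class_of_channel(channel: int) -> int:
    """Context class (0..31) of a channel: pyrimidine centre x 16 flanks.

    Three channels (the three alternate bases) share each context class.
    """
    sub, flank = divmod(channel, 16)
    centre = 0 if sub < 3 else 1  # C-centred vs T-centred
    return centre * 16 + flank


#: Per-channel context class, as an array for vectorised lookups.
CHANNEL_CONTEXT = np.array(
    [context_class_of_channel(j) for j in range(N_CHANNELS)], dtype=np.int64
)


def context_class_of_trinuc(tri: str) -> Optional[int]:
    """Context class of a trinucleotide (pyrimidine-normalised); None if it has N."""
    if any(b not in BASES for b in tri):
        return None
    if tri[1] not in PYRIMIDINES:
        tri = revcomp(tri)
    return PYRIMIDINES.index(tri[1]) * 16 + BASES.index(tri[0]) * 4 + BASES.index(tri[2])


class ViolationClass(str, Enum):
    """The four classes of infinite sites violations at a diploid locus.

    A second, independent mutation can hit the sister allele and recreate the
    same alternate base (parallel) or a different one (divergent), or it can
    hit the already-mutated allele, either restoring the reference (back) or
    producing a third state (forward).
    """

    PARALLEL = "parallel"
    DIVERGENT = "divergent"
    BACK = "back"
    FORWARD = "forward"


class ReferenceMismatchError(ValueError):
    """Raised when a record's stated reference base disagrees with the genome."""


class UncallableContextError(ValueError):
    """Raised when a trinucleotide context contains N or falls off a chromosome."""


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic variant call.

    ``alts`` holds one alternate allele for ordinary records and two for
    divergent candidates (both parental alleles mutated to different bases).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: Tuple[str, ...]
    vtype: str = "snv"  # "snv" | "indel"
    is_driver: bool = False
    sample_id: str = ""
    passed: bool = True

    def __post_init__(self) -> None:
        if self.vtype not in ("snv", "indel"):
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if not 1 <= len(self.alts) <= 2:
            raise ValueError("a record carries one or two alternate alleles")
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if len(self.alts) == 2 and self.alts[0] == self.alts[1]:
            raise ValueError("divergent record needs two distinct alternates")
        if self.vtype == "snv":
            if self.ref not in BASES:
                raise ValueError(f"SNV ref must be a single base, got {self.ref!r}")
            for alt in self.alts:
                if alt not in BASES:
                    raise ValueError(f"SNV alt must be a single base, got {alt!r}")

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def is_divergent_candidate(self) -> bool:
        return len(self.alts) == 2


@dataclass
class ContextGenome:
    """Reference sequences plus callable intervals and context abundances.

    Callable intervals are 0-based half-open. A position contributes to the
    context-abundance table (and is a sampling target for the simulators) only
    when its full trinucleotide lies inside one callable interval and contains
    no N; the two edge positions of every interval therefore do not count.
    """

    sequences: Dict[str, str]
    callable_intervals: Dict[str, List[Tuple[int, int]]]
    _abundance: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _positions: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}
        for chrom, ivs in self.callable_intervals.items():
            if chrom not in self.sequences:
                raise ValueError(f"callable interval on unknown chromosome {chrom}")
            length = len(self.sequences[chrom])
            prev_end = -1
            for start, end in sorted(ivs):
                if not (0 <= start < end <= length):
                    raise ValueError(f"interval ({start},{end}) outside {chrom}")
                if start < prev_end:
                    raise ValueError(f"overlapping callable intervals on {chrom}")
                prev_end = end
            self.callable_intervals[chrom] = sorted(ivs)

    @property
    def chromosomes(self) -> List[str]:
        return list(self.sequences)

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]

    def trinucleotide(self, chrom: str, pos: int) -> str:
        """Reference trinucleotide centred at a 1-based position."""
        seq = self.sequences[chrom]
        if not 2 <= pos <= len(seq) - 1:
            raise UncallableContextError(
                f"position {chrom}:{pos} lacks a full trinucleotide context"
            )
        return seq[pos - 2 : pos + 1]

    def callable_positions(self, chrom: str) -> np.ndarray:
        """0-based positions with a fully-callable, N-free context."""
        if chrom not in self._positions:
            self._scan(chrom)
        return self._positions[chrom]

    def context_abundance(self, chrom: Optional[str] = None) -> np.ndarray:
        """Counts of the 32 pyrimidine-normalised context classes.

        With ``chrom=None`` sums over all chromosomes with callable intervals.
        """
        if chrom is not None:
            if chrom not in self._abundance:
                self._scan(chrom)
            return self._abundance[chrom]
        total = np.zeros(N_CONTEXTS, dtype=np.int64)
        for c in self.callable_intervals:
            total += self.context_abundance(c)
        return total

    def channel_abundance(self, chrom: Optional[str] = None) -> np.ndarray:
        """Per-channel context abundance f_j (class abundance of each channel)."""
        return self.context_abundance(chrom)[CHANNEL_CONTEXT]

    def callable_locus_count(self, chrom: Optional[str] = None) -> int:
        """Number of mutable positions (valid contexts inside callable regions)."""
        return int(self.context_abundance(chrom).sum())

    def _scan(self, chrom: str) -> None:
        seq = self.sequences[chrom]
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        base_idx = np.full(codes.shape, -1, dtype=np.int8)
        for i, b in enumerate(BASES):
            base_idx[codes == ord(b)] = i
        positions: List[np.ndarray] = []
        abundance = np.zeros(N_CONTEXTS, dtype=np.int64)
        for start, end in self.callable_intervals.get(chrom, []):
            lo, hi = start + 1, end - 1  # full context inside the interval
            if hi <= lo:
                continue
            pos = np.arange(lo, hi)
            five, centre, three = base_idx[pos - 1], base_idx[pos], base_idx[pos + 1]
            ok = (five >= 0) & (centre >= 0) & (three >= 0)
            pos, five, centre, three = pos[ok], five[ok], centre[ok], three[ok]
            # pyrimidine-normalise: A->T/G->C centre means reverse complement
            pur = (centre == 0) | (centre == 2)  # A or G
            cls = np.where(
                pur,
                # revcomp: centre A->T(1), G->C(0); flanks swap and complement
                np.where(centre == 0, 1, 0) * 16 + (3 - three) * 4 + (3 - five),
                np.where(centre == 1, 0, 1) * 16 + five * 4 + three,
            )
            abundance += np.bincount(cls, minlength=N_CONTEXTS)
            positions.append(pos)
        self._abundance[chrom] = abundance
        self._positions[chrom] = (
            np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
        )


def extract_channel(
    genome: ContextGenome, chrom: str, pos: int, ref: str, alt: str
) -> int:
    """Channel index (0..95) of a substitution, reverse-complementing purines.

    ``pos`` is 1-based; the genome base there must equal ``ref``.
    """
    tri = genome.trinucleotide(chrom, pos)
    if tri[1] != ref:
        raise ReferenceMismatchError(
            f"reference mismatch at {chrom}:{pos}: genome has {tri[1]!r}, "
            f"record says {ref!r}"
        )
    if "N" in tri:
        raise UncallableContextError(f"uncallable context {tri!r} at {chrom}:{pos}")
    return CHANNEL_OF[(tri, alt)]


@dataclass
class TrinucleotideSpectrum:
    """A 96-channel mutation spectrum in frozen COSMIC channel order."""

    counts: np.ndarray
    normalised: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CHANNELS,):
            raise ValueError(f"spectrum needs exactly {N_CHANNELS} channels")
        if np.any(self.counts < 0):
            raise ValueError("spectrum counts must be non-negative")
        if self.normalised and abs(self.counts.sum() - 1.0) > 1e-12:
            raise ValueError("normalised spectrum must sum to 1")

    def normalise(self) -> "TrinucleotideSpectrum":
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot normalise an empty spectrum")
        return TrinucleotideSpectrum(self.counts / total, normalised=True)

    def __add__(self, other: "TrinucleotideSpectrum") -> "TrinucleotideSpectrum":
        return TrinucleotideSpectrum(self.counts + other.counts)


def compute_spectrum(
    mutations: Iterable[MutationRecord],
    genome: ContextGenome,
    normalise: bool = False,
) -> TrinucleotideSpectrum:
    """Tally the 96-channel spectrum of an SNV catalog.

    Divergent candidates contribute one count per alternate allele.
    """
    counts = np.zeros(N_CHANNELS, dtype=float)
    for rec in mutations:
        if rec.vtype != "snv":
            raise ValueError("spectra are defined for SNVs only")
        for alt in rec.alts:
            counts[extract_channel(genome, rec.chrom, rec.pos, rec.ref, alt)] += 1
    spec = TrinucleotideSpectrum(counts)
    return spec.normalise() if normalise else spec


def cosine_similarity(a: TrinucleotideSpectrum, b: TrinucleotideSpectrum) -> float:
    """Cosine similarity of two spectra; scale-invariant, in [0, 1]."""
    na, nb = np.linalg.norm(a.counts), np.linalg.norm(b.counts)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero spectrum")
    return float(np.clip(np.dot(a.counts, b.counts) / (na * nb), 0.0, 1.0))


def predicted_parallel_spectrum(
    snv_spectrum: TrinucleotideSpectrum,
    genome: ContextGenome,
    abundance_correction: bool = True,
) -> TrinucleotideSpectrum:
    """Expected spectrum of biallelic parallel hits under independent mutation.

    Two independent hits of the same channel j collide within one of f_j
    equivalent context positions, so the collision mass per channel is
    p_j^2 / f_j (normalised). With ``abundance_correction=False`` the raw
    squared spectrum p_j^2 is used instead. This is an analytic cross-check of
    simulator output, not a caller.
    """
    if not snv_spectrum.normalised:
        snv_spectrum = snv_spectrum.normalise()
    p = snv_spectrum.counts
    if abundance_correction:
        f = genome.channel_abundance().astype(float)
        bad = (p > 0) & (f == 0)
        if np.any(bad):
            labels = [CHANNEL_LABELS[j] for j in np.nonzero(bad)[0]]
            raise ValueError(
                f"spectrum has mass in channels with no genomic context: {labels}"
            )
        q = np.divide(p * p, f, out=np.zeros_like(p), where=f > 0)
    else:
        q = p * p
    return TrinucleotideSpectrum(q).normalise()


def classify_violation(
    ref: str,
    current_same: str,
    current_other: str,
    new_base: str,
) -> Optional[ViolationClass]:
    """Classify a new hit at a locus with mutation history.

    ``current_same`` is the pre-hit base of the allele being mutated and
    ``current_other`` the current base of the sister allele; classification is
    against the current allelic state, matching sequential simulation. Returns
    None in the unreachable-by-two-hits corner where both alleles have been
    restored to reference (the hit is then a fresh first mutation).
    """
    if new_base == current_same:
        raise ValueError("no-op mutation: new base equals the allele's current base")
    if current_same != ref:
        return ViolationClass.BACK if new_base == ref else ViolationClass.FORWARD
    if current_other != ref:
        return (
            ViolationClass.PARALLEL
            if new_base == current_other
            else ViolationClass.DIVERGENT
        )
    return None
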