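"""Read-backed phasing of SNP-SNV pairs and biallelic-burden extrapolation.

When a somatic variant lies within read-pair range (700 bp) of a heterozygous
germline SNP, reads phase the variant onto the SNP's two alleles. A parallel
mutation shows the somatic alternate on *both* SNP alleles (Ref-Alt and
Alt-Alt pairs), which the VAF approach can miss for late events with low
multiplicity. The sparse phasing calls also benchmark the VAF caller
(precision/recall) and anchor a beta-binomial extrapolation of the total
parallel burden of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

MAX_PHASING_DISTANCE = 700  # bp between SNP and SNV


@dataclass
class ReadPairObservation:
    """One read pair spanning a SNP-SNV pair, with its quality metrics."""

    mq1: int
    mq2: int
    bq_snp: int
    bq_snv: int
    snp_allele: str  # "ref" | "alt"
    snv_allele: str  # "ref" | "alt"
    clipped: bool = False
    proper_pair: bool = True
    duplicate: bool = False
    vendor_fail: bool = False
    has_indel: bool = False
    mismatches1: int = 0
    mismatches2: int = 0

    def __post_init__(self) -> None:
        for q in (self.mq1, self.mq2, self.bq_snp, self.bq_snv):
            if q < 0:
                raise ValueError("qualities must be non-negative")
        if self.mismatches1 < 0 or self.mismatches2 < 0:
            raise ValueError("mismatch counts must be non-negative")


def filter_read_pair(
    obs: ReadPairObservation,
    min_mq: int = 20,
    min_bq: int = 25,
    max_mismatches_read: int = 2,
    max_mismatches_pair: int = 3,
) -> bool:
    """Accept a read pair for phasing evidence.

    Requires mapping quality >= 20 on both reads, base quality >= 25 at the
    two phased positions, no clipping, a proper non-duplicate pair without
    vendor failure or indels, and fewer than 2 mismatches in either read and
    fewer than 3 across the pair (the phased positions are not counted as
    mismatches).
    """
    if obs.mq1 < min_mq or obs.mq2 < min_mq:
        return False
    if obs.bq_snp < min_bq or obs.bq_snv < min_bq:
        return False
    if obs.clipped or not obs.proper_pair or obs.duplicate or obs.vendor_fail:
        return False
    if obs.has_indel:
        return False
    if max(obs.mismatches1, obs.mismatches2) >= max_mismatches_read:
        return False
    if obs.mismatches1 + obs.mismatches2 >= max_mismatches_pair:
        return False
    return True


@dataclass
class PhasedPairEvidence:
    """Phased read-pair counts for one SNP-SNV pair.

    Counts index the SNP allele first: ``n_ra`` is reference-SNP reads
    carrying the somatic alternate, ``n_aa`` alternate-SNP reads carrying it.
    """

    snp_chrom: str
    snp_pos: int
    snv_pos: int
    n_rr: int = 0
    n_ra: int = 0
    n_ar: int = 0
    n_aa: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        for c in (self.n_rr, self.n_ra, self.n_ar, self.n_aa):
            if c < 0:
                raise ValueError("phased read counts must be non-negative")
        if abs(self.snv_pos - self.snp_pos) > MAX_PHASING_DISTANCE:
            raise ValueError(
                f"SNP-SNV distance exceeds {MAX_PHASING_DISTANCE} bp"
            )

    @property
    def total(self) -> int:
        return self.n_rr + self.n_ra + self.n_ar + self.n_aa

    @classmethod
    def from_read_pairs(
        cls,
        snp_chrom: str,
        snp_pos: int,
        snv_pos: int,
        pairs: Iterable[ReadPairObservation],
        **filter_kwargs,
    ) -> "PhasedPairEvidence":
        ev = cls(snp_chrom=snp_chrom, snp_pos=snp_pos, snv_pos=snv_pos)
        for obs in pairs:
            if not filter_read_pair(obs, **filter_kwargs):
                continue
            attr = f"n_{obs.snp_allele[0]}{obs.snv_allele[0]}"
            setattr(ev, attr, getattr(ev, attr) + 1)
        return ev


@dataclass
class PhasingCall:
    """Phasing verdict for one SNV via one informative SNP."""

    snv_key: Tuple[str, int]
    verdict: str  # "parallel" | "single" | "uninformative"
    snp_outlier_p: Optional[float] = None
    evidence: Optional[PhasedPairEvidence] = None


def call_parallel_phasing(
    evidence: PhasedPairEvidence,
    snp_two_sided_p: float,
    min_reads: int = 2,
    min_fraction: float = 0.1,
    snp_outlier_p: float = 0.001,
) -> PhasingCall:
    """Infer a parallel mutation from phased read-pair counts.

    Parallel requires >= 2 Ref-Alt and >= 2 Alt-Alt reads, each exceeding 10%
    of the total phased reads, and the SNP's two-sided beta-binomial p-value
    above 0.001 (guarding against a gained copy whose in-cis SNP allele was
    subsequently mutated).
    """
    key = (evidence.snp_chrom, evidence.snv_pos)
    total = evidence.total
    if total == 0:
        return PhasingCall(key, "uninformative", snp_two_sided_p, evidence)
    ok = (
        evidence.n_ra >= min_reads
        and evidence.n_aa >= min_reads
        and evidence.n_ra / total > min_fraction
        and evidence.n_aa / total > min_fraction
        and snp_two_sided_p > snp_outlier_p
    )
    return PhasingCall(
        key, "parallel" if ok else "single", snp_two_sided_p, evidence
    )


def call_snv_phasing(
    calls_per_pair: Sequence[PhasingCall],
) -> Dict[Tuple[str, int], str]:
    """Collapse per-pair calls to one verdict per SNV.

    An SNV with several informative SNPs is parallel if any pair calls
    parallel; uninformative only if every pair is.
    """
    verdicts: Dict[Tuple[str, int], str] = {}
    rank = {"uninformative": 0, "single": 1, "parallel": 2}
    for call in calls_per_pair:
        prev = verdicts.get(call.snv_key)
        if prev is None or rank[call.verdict] > rank[prev]:
            verdicts[call.snv_key] = call.verdict
    return verdicts


@dataclass
class PrecisionRecall:
    """Per-sample precision/recall of the VAF caller against phasing."""

    precision: Optional[float]
    recall: Optional[float]
    n_phaseable: int = 0


def evaluate_precision_recall(
    vaf_calls: Set[Tuple[str, int]],
    phasing_calls: Set[Tuple[str, int]],
    phaseable_snvs: Set[Tuple[str, int]],
) -> PrecisionRecall:
    """Precision and recall of VAF calls with phasing as the benchmark.

    Precision = |VAF and phasing| / |VAF and phaseable|; recall =
    |VAF and phasing| / |phasing|. Empty denominators yield None (missing),
    never zero.
    """
    confirmed = len(vaf_calls & phasing_calls)
    vaf_phaseable = len(vaf_calls & phaseable_snvs)
    precision = confirmed / vaf_phaseable if vaf_phaseable else None
    recall = confirmed / len(phasing_calls) if phasing_calls else None
    return PrecisionRecall(precision, recall, n_phaseable=len(phaseable_snvs))


def cohort_medians(
    per_sample: Sequence[PrecisionRecall],
    min_phaseable: int = 10_000,
) -> Tuple[Optional[float], Optional[float]]:
    """Median precision and recall over samples with enough phaseable SNVs."""
    eligible = [
        s for s in per_sample if s.n_phaseable >= min_phaseable
    ]
    precisions = [s.precision for s in eligible if s.precision is not None]
    recalls = [s.recall for s in eligible if s.recall is not None]
    return (
        float(np.median(precisions)) if precisions else None,
        float(np.median(recalls)) if recalls else None,
    )


@dataclass
class ExtrapolationResult:
    """Posterior-predictive estimate of a sample's total parallel burden."""

    mean: float
    lower: float
    upper: float
    n_tested: int


def extrapolate_total_parallel(
    n_tested: int,
    n_phas_par: int,
    n_phas_single: int,
    pseudocount: float = 0.001,
    ci: float = 0.95,
) -> ExtrapolationResult:
    """Extrapolate the phaseable parallel rate to all tested SNVs.

    The total violation count is modelled as Binomial(n_tested, P) with
    P ~ Beta(n_phas_par + 0.001, n_phas_single + 0.001); the point estimate is
    the posterior-predictive mean and the interval its 2.5/97.5 percentiles.
    """
    if n_phas_par < 0 or n_phas_single < 0 or n_tested < 0:
        raise ValueError("counts must be non-negative")
    if n_phas_par + n_phas_single < 1:
        raise ValueError("extrapolation needs at least one phaseable observation")
    a = n_phas_par + pseudocount
    b = n_phas_single + pseudocount
    mean = n_tested * a / (a + b)
    tail = (1 - ci) / 2
    lower = float(stats.betabinom.ppf(tail, n_tested, a, b))
    upper = float(stats.betabinom.ppf(1 - tail, n_tested, a, b))
    return ExtrapolationResult(mean=mean, lower=lower, upper=upper, n_tested=n_tested)
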