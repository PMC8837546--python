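"""VAF-based detection of biallelic parallel mutations.

A parallel mutation raises the variant allele frequency above what a clonal
mutation on all copies of the major allele could produce. The caller models
allele counts with a beta-binomial whose mean is the purity/ploidy-corrected
segment B-allele frequency (BAF_som) and whose concentration omega (a
pseudo-coverage) is calibrated per sample on heterozygous SNPs so that a
QQ-plot of their two-sided p-values has robust slope 1. Candidate SNVs then
get a one-sided tail test, an independent power filter, Benjamini-Hochberg
correction (q <= 0.1), positional filters against germline SNPs, common
structural variants, SNP-dense windows and LOH, flank-outlier guards on
neighbouring SNP BAF and logR, and two sample-level exclusions (inflated
final QQ slope; zero simulated violations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MAD_CONSISTENCY = 1.4826  # Gaussian asymptotic-consistency factor for the MAD

OMEGA_BOUNDS = (50.0, 1000.0)


@dataclass(frozen=True)
class PurityPloidy:
    """Tumour purity rho in (0, 1] and tumour ploidy psi_t > 0."""

    rho: float
    psi_t: float

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("purity must lie in (0, 1]")
        if self.psi_t <= 0:
            raise ValueError("ploidy must be positive")


@dataclass(frozen=True)
class CopyNumberSegment:
    """Allele-specific copy-number segment with per-segment BAF and logR.

    Coordinates are 1-based inclusive; ``baf_seg`` is the mean phased BAF
    after haplotype-block flipping (>= 0.5 by convention).
    """

    chrom: str
    start: int
    end: int
    major: int
    minor: int
    baf_seg: float
    logr_seg: float

    def __post_init__(self) -> None:
        if self.major < self.minor or self.minor < 0:
            raise ValueError("need major >= minor >= 0")
        if not 0.5 <= self.baf_seg <= 1.0:
            raise ValueError("segment BAF must lie in [0.5, 1] after flipping")
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")

    @property
    def is_loh(self) -> bool:
        return self.minor == 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class HetSNPObservation:
    """Phased heterozygous germline SNP allele counts (major/minor)."""

    chrom: str
    pos: int
    major_count: int  # V_i
    minor_count: int  # R_i
    phase: str = ""
    logr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.major_count < 0 or self.minor_count < 0:
            raise ValueError("allele counts must be non-negative")
        if self.major_count + self.minor_count == 0:
            raise ValueError("SNP must have at least one read")

    @property
    def total(self) -> int:
        return self.major_count + self.minor_count


@dataclass
class SNVObservation:
    """Somatic SNV with read counts and annotation flags."""

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    total: int
    snv_id: str = ""
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.total:
            raise ValueError("alt count must lie within total depth")

    @property
    def key(self) -> Tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class BetaBinomialModel:
    """Beta-binomial with mean m and concentration (pseudo-coverage) omega."""

    m: float
    omega: float

    def __post_init__(self) -> None:
        if not 0 < self.m < 1:
            raise ValueError("beta-binomial mean must lie strictly in (0, 1)")
        if self.omega <= 0:
            raise ValueError("concentration omega must be positive")

    @property
    def alpha(self) -> float:
        return self.m * self.omega

    @property
    def beta(self) -> float:
        return (1.0 - self.m) * self.omega


def _pmf_masses(n: int, a: float, b: float) -> Optional[List[float]]:
    """Beta-binomial pmf over 0..n by the ratio recurrence.

    pmf(0) = prod_i (b+i)/(a+b+i) and pmf(k+1)/pmf(k) =
    (n-k)(k+a) / ((k+1)(n-k-1+b)): every factor is a single rounding, so the
    table is accurate to ~n ulps — well beyond log-gamma routes. Returns None
    when pmf(0) underflows (huge n with extreme skew); callers then fall back
    to the scipy tail.
    """
    p0 = 1.0
    for i in range(n):
        p0 *= (b + i) / (a + b + i)
    if p0 == 0.0:
        return None
    masses = [p0]
    for k in range(n):
        masses.append(masses[-1] * (n - k) / (k + 1) * (k + a) / (n - k - 1 + b))
    return masses


def betabinom_tail(v: int, n: int, model: BetaBinomialModel) -> float:
    """One-sided upper tail P(V >= v) by exact pmf summation.

    Monotone non-increasing in v; compensated summation keeps the result
    within ~1e-13 of the true tail for n up to several hundred.
    """
    if not 0 <= v <= n:
        raise ValueError("observed count must satisfy 0 <= v <= n")
    if v == 0:
        return 1.0
    masses = _pmf_masses(n, model.alpha, model.beta)
    if masses is None:
        return float(stats.betabinom.sf(v - 1, n, model.alpha, model.beta))
    return min(1.0, math.fsum(masses[v:]))


def two_sided_pvalue(v: int, n: int, model: BetaBinomialModel) -> float:
    """Two-sided p as twice the smaller tail, capped at 1."""
    if not 0 <= v <= n:
        raise ValueError("observed count must satisfy 0 <= v <= n")
    masses = _pmf_masses(n, model.alpha, model.beta)
    if masses is None:
        lower = float(stats.betabinom.cdf(v, n, model.alpha, model.beta))
        upper = float(stats.betabinom.sf(v - 1, n, model.alpha, model.beta))
    else:
        lower = math.fsum(masses[: v + 1])
        upper = math.fsum(masses[v:])
    return min(1.0, 2.0 * min(lower, upper))


def _two_sided_vec(
    v: np.ndarray,
    n: np.ndarray,
    m: np.ndarray,
    omega: float,
    mid_p: bool = False,
) -> np.ndarray:
    """Vectorised two-sided p-values, grouped by unique (depth, mean) pairs.

    Full pmf tables per unique (n, m) make repeated evaluation across an
    omega grid cheap. ``mid_p`` halves the point mass at the observed count
    in both tails — the standard continuity correction that renders discrete
    p-values near-uniform under the null (the plain doubled tail is
    conservative, which would bias a QQ-slope calibration).
    """
    v = np.asarray(v, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    m = np.asarray(m, dtype=float)
    out = np.empty(len(v), dtype=float)
    keys = np.stack([n, (m * 1e12).astype(np.int64)], axis=1)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        idx = np.nonzero(inverse == g)[0]
        ni, mi = int(n[idx[0]]), float(m[idx[0]])
        a, b = mi * omega, (1 - mi) * omega
        pmf = np.exp(stats.betabinom.logpmf(np.arange(ni + 1), ni, a, b))
        cdf = np.cumsum(pmf)
        vi = v[idx]
        if mid_p:
            lower = cdf[vi] - 0.5 * pmf[vi]
            upper = 1.0 - cdf[vi] + 0.5 * pmf[vi]
        else:
            lower = cdf[vi]
            upper = 1.0 - cdf[vi] + pmf[vi]
        out[idx] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.clip(out, 0.0, 1.0)


def qq_slope(pvalues: np.ndarray, n_quantiles: int = 500) -> float:
    """Theil-Sen slope of -log10 observed vs expected uniform p quantiles.

    Exact p = 1 ties (common for discrete two-sided tests) are excluded from
    the regression but kept in the expected-quantile denominator, so uniform
    p-values still give slope 1. Quantile pairs are thinned to at most
    ``n_quantiles`` evenly spaced order statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        raise ValueError("QQ slope needs at least one p-value")
    order = np.sort(p)
    keep = order < 1.0
    ranks = np.arange(1, m + 1)[keep]
    obs = order[keep]
    if len(obs) < 10:
        return 0.0
    if len(obs) > n_quantiles:
        sel = np.linspace(0, len(obs) - 1, n_quantiles).round().astype(int)
        obs, ranks = obs[sel], ranks[sel]
    x = -np.log10((ranks - 0.5) / m)
    y = -np.log10(np.maximum(obs, 1e-300))
    res = stats.theilslopes(y, x)
    return float(res.slope)


@dataclass
class OmegaCalibration:
    """Result of the per-sample concentration search."""

    omega: float
    slope: float
    grid: np.ndarray
    slopes: np.ndarray


def calibrate_omega(
    major_counts: np.ndarray,
    totals: np.ndarray,
    baf_segs: np.ndarray,
    bounds: Tuple[float, float] = OMEGA_BOUNDS,
    grid_size: int = 40,
    refine: int = 12,
    min_snps: int = 100,
) -> OmegaCalibration:
    """Optimise omega in [50, 1000] so het-SNP p-values have QQ slope 1.

    ``major_counts``, ``totals`` and ``baf_segs`` are aligned per-SNP arrays
    (each SNP tested against its own segment's BAF). The search is a
    deterministic log-spaced grid followed by local refinement between the
    best point's neighbours; smaller omega means more over-dispersion, larger
    p-values and a flatter QQ slope, so the slope is monotone in omega and
    the nearest-to-1 grid point brackets the optimum.
    """
    v = np.asarray(major_counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    m = np.asarray(baf_segs, dtype=float)
    if not (len(v) == len(n) == len(m)):
        raise ValueError("per-SNP arrays must be aligned")
    if len(v) < min_snps:
        raise ValueError(
            f"omega calibration needs >= {min_snps} heterozygous SNPs; "
            f"got {len(v)} — supply more loci"
        )
    m = np.clip(m, 1e-6, 1 - 1e-6)

    def slope_at(omega: float) -> float:
        return qq_slope(_two_sided_vec(v, n, m, omega, mid_p=True))

    grid = np.geomspace(bounds[0], bounds[1], grid_size)
    slopes = np.array([slope_at(w) for w in grid])
    best = int(np.argmin(np.abs(slopes - 1.0)))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    fine = np.geomspace(lo, hi, refine)
    fine_slopes = np.array([slope_at(w) for w in fine])
    fbest = int(np.argmin(np.abs(fine_slopes - 1.0)))
    omega = float(np.clip(fine[fbest], bounds[0], bounds[1]))
    return OmegaCalibration(
        omega=omega, slope=float(fine_slopes[fbest]), grid=grid, slopes=slopes
    )


def compute_baf_som(
    baf_seg: float,
    pp: PurityPloidy,
    logr_seg: float,
    floor: float = 0.05,
) -> float:
    """Purity/ploidy-corrected maximal expected somatic allele frequency.

    BAF_som = BAF_seg - (1 - rho) / [(2(1-rho) + rho psi_t) * 2^logR_seg],
    subtracting the admixed-normal contribution of the major allele. Estimates
    below ``floor`` are conservatively raised back to BAF_seg.
    """
    if not 0.5 <= baf_seg <= 1.0:
        raise ValueError("segment BAF must lie in [0.5, 1]")
    denom = (2 * (1 - pp.rho) + pp.rho * pp.psi_t) * 2.0**logr_seg
    if denom <= 0:
        raise ValueError("non-positive purity/ploidy denominator")
    raw = baf_seg - (1 - pp.rho) / denom
    # tolerance keeps exact-boundary arithmetic on the "keep" side
    return baf_seg if raw < floor - 1e-12 else raw


def power_filter(
    n: int, model: BetaBinomialModel, alpha: float = 0.001
) -> bool:
    """Whether the site can in principle reach significance.

    A site is powered when the minimal attainable one-sided p-value — the
    upper tail at v = n — is below ``alpha``; low depth or BAF_som near 1
    make even a fully-mutant pileup unremarkable.
    """
    if n < 1:
        raise ValueError("depth must be at least 1")
    return betabinom_tail(n, n, model) < alpha


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GuardResult:
    """Flank-outlier guard outcome: 'pass', 'fail' or 'untestable'."""

    status: str
    baf_pvalues: Tuple[float, ...] = ()
    baf_fisher_p: Optional[float] = None
    logr_pvalues: Tuple[float, ...] = ()
    logr_fisher_p: Optional[float] = None
    reason: str = ""

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def _fisher_p(pvalues: Sequence[float]) -> float:
    stat = -2.0 * sum(math.log(max(p, 1e-300)) for p in pvalues)
    return float(stats.chi2.sf(stat, 2 * len(pvalues)))


def neighbour_guard(
    snv_pos: int,
    segment_snps: Sequence[HetSNPObservation],
    model: BetaBinomialModel,
    per_snp_p: float = 0.001,
    fisher_p: float = 0.01,
) -> GuardResult:
    """Check the nearest flanking het SNPs for BAF/logR outliers.

    A missed copy-number event near a candidate shows up as outlying BAF or
    logR at the flanking SNPs. Each flank's two-sided beta-binomial BAF
    p-value must exceed ``per_snp_p`` and their Fisher-combined p must exceed
    ``fisher_p``; identical thresholds apply to Gaussian two-tailed logR
    p-values with mean the segment median and sd the consistency-adjusted MAD.
    """
    left = [s for s in segment_snps if s.pos < snv_pos]
    right = [s for s in segment_snps if s.pos > snv_pos]
    if not left or not right:
        return GuardResult(
            status="untestable", reason="no flanking SNP on one side"
        )
    flanks = [max(left, key=lambda s: s.pos), min(right, key=lambda s: s.pos)]

    baf_ps = tuple(
        two_sided_pvalue(s.major_count, s.total, model) for s in flanks
    )
    baf_fisher = _fisher_p(baf_ps)
    if any(p <= per_snp_p for p in baf_ps) or baf_fisher <= fisher_p:
        return GuardResult(
            status="fail",
            baf_pvalues=baf_ps,
            baf_fisher_p=baf_fisher,
            reason="flanking SNP BAF outlier",
        )

    logrs = np.array([s.logr for s in segment_snps if s.logr is not None])
    logr_ps: Tuple[float, ...] = ()
    logr_fisher: Optional[float] = None
    if len(logrs) >= 3 and all(s.logr is not None for s in flanks):
        med = float(np.median(logrs))
        sd = MAD_CONSISTENCY * float(np.median(np.abs(logrs - med)))
        sd = max(sd, 1e-12)
        logr_ps = tuple(
            2.0 * float(stats.norm.sf(abs(s.logr - med) / sd)) for s in flanks
        )
        logr_fisher = _fisher_p(logr_ps)
        if any(p <= per_snp_p for p in logr_ps) or logr_fisher <= fisher_p:
            return GuardResult(
                status="fail",
                baf_pvalues=baf_ps,
                baf_fisher_p=baf_fisher,
                logr_pvalues=logr_ps,
                logr_fisher_p=logr_fisher,
                reason="flanking SNP logR outlier",
            )
    return GuardResult(
        status="pass",
        baf_pvalues=baf_ps,
        baf_fisher_p=baf_fisher,
        logr_pvalues=logr_ps,
        logr_fisher_p=logr_fisher,
    )


@dataclass
class SiteResources:
    """Positional resources consumed by the site filters.

    Interval lists are 1-based inclusive internally; position sets are 1-based.
    """

    germline_snp_positions: Dict[str, frozenset] = field(default_factory=dict)
    common_sv_intervals: Dict[str, List[Tuple[int, int]]] = field(
        default_factory=dict
    )
    het_snp_positions: Dict[str, np.ndarray] = field(default_factory=dict)
    indel_positions: Dict[str, np.ndarray] = field(default_factory=dict)
    tcr_bcr_intervals: Dict[str, List[Tuple[int, int]]] = field(
        default_factory=dict
    )
    liftover_failed: frozenset = frozenset()  # (chrom, pos) keys
    sex: str = "female"
    par_intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)


def _in_intervals(pos: int, intervals: Sequence[Tuple[int, int]]) -> bool:
    return any(lo <= pos <= hi for lo, hi in intervals)


@dataclass
class FilterOutcome:
    """Per-SNV site-filter result with full provenance trail."""

    status: str  # "pass" | "removed" | "untested"
    reason: str = ""
    flags: List[str] = field(default_factory=list)


def apply_site_filters(
    snvs: Sequence[SNVObservation],
    resources: SiteResources,
    segments: Sequence[CopyNumberSegment],
    snp_window: int = 25,
    snp_max: int = 2,
    indel_window: Tuple[int, int] = (-10, 25),
) -> Dict[Tuple[str, int], FilterOutcome]:
    """Apply the positional filter cascade and attach QC flags.

    Removing filters: (i) overlap with a heterozygous germline SNP, (ii)
    common structural variation, (iv) >= 2 het SNPs within 25 bp, (v) LOH
    segments are not tested (in males only the X pseudoautosomal regions are
    considered). Non-removing flags: T-/B-cell receptor loci, proximity to an
    indel within the asymmetric -10/+25 bp window, failed liftover.
    """
    seg_by_chrom: Dict[str, List[CopyNumberSegment]] = {}
    for seg in segments:
        seg_by_chrom.setdefault(seg.chrom, []).append(seg)

    outcomes: Dict[Tuple[str, int], FilterOutcome] = {}
    for snv in snvs:
        chrom, pos = snv.chrom, snv.pos
        if pos in resources.germline_snp_positions.get(chrom, frozenset()):
            outcomes[snv.key] = FilterOutcome("removed", "germline-overlap")
            continue
        if _in_intervals(pos, resources.common_sv_intervals.get(chrom, [])):
            outcomes[snv.key] = FilterOutcome("removed", "common-sv")
            continue
        het = resources.het_snp_positions.get(chrom)
        if het is not None and len(het) > 0:
            near = np.sum(np.abs(het - pos) <= snp_window)
            if near >= snp_max:
                outcomes[snv.key] = FilterOutcome("removed", "snp-density")
                continue
        segment = next(
            (s for s in seg_by_chrom.get(chrom, []) if s.contains(pos)), None
        )
        if segment is not None and segment.is_loh:
            outcomes[snv.key] = FilterOutcome("untested", "loh-not-tested")
            continue
        if resources.sex == "male" and chrom in ("X", "chrX"):
            if not _in_intervals(pos, resources.par_intervals.get(chrom, [])):
                outcomes[snv.key] = FilterOutcome("untested", "male-x-non-par")
                continue
        flags = list(snv.flags)
        if _in_intervals(pos, resources.tcr_bcr_intervals.get(chrom, [])):
            flags.append("tcr-bcr")
        indels = resources.indel_positions.get(chrom)
        if indels is not None and len(indels) > 0:
            off = indels - pos
            if np.any((off >= indel_window[0]) & (off <= indel_window[1])):
                flags.append("indel-proximity")
        if (chrom, pos) in resources.liftover_failed:
            flags.append("liftover-failed")
        outcomes[snv.key] = FilterOutcome("pass", flags=flags)
    return outcomes


@dataclass
class VafCallResult:
    """Verdict for one SNV in the VAF pipeline, with full filter trail."""

    snv: SNVObservation
    verdict: str  # "parallel-candidate" | "not-significant" | "untested" | "removed"
    p: Optional[float] = None
    q: Optional[float] = None
    powered: Optional[bool] = None
    guard: Optional[GuardResult] = None
    trail: List[str] = field(default_factory=list)
    flags: List[str] = field(default_factory=list)


@dataclass
class SampleBundle:
    """All per-tumour inputs of the VAF caller."""

    sample_id: str
    pp: PurityPloidy
    segments: List[CopyNumberSegment]
    het_snps: List[HetSNPObservation]
    snvs: List[SNVObservation]
    resources: SiteResources = field(default_factory=SiteResources)


@dataclass
class VafConfig:
    """Thresholds of the VAF pipeline (values from the detection protocol)."""

    q_threshold: float = 0.1
    power_alpha: float = 0.001
    guard_snp_p: float = 0.001
    guard_fisher_p: float = 0.01
    baf_som_floor: float = 0.05
    omega_bounds: Tuple[float, float] = OMEGA_BOUNDS
    qq_slope_max: float = 1.0
    qq_slope_tol: float = 0.05
    min_calibration_snps: int = 100


@dataclass
class SampleCallResult:
    """Sample-level output: calls, calibration and QC verdict."""

    sample_id: str
    excluded: bool
    exclusion_reason: str
    omega: Optional[float]
    qq_slope_final: Optional[float]
    calls: List[VafCallResult]

    @property
    def candidates(self) -> List[VafCallResult]:
        if self.excluded:
            return []
        return [c for c in self.calls if c.verdict == "parallel-candidate"]


def _assign_segment(
    segments: Sequence[CopyNumberSegment], chrom: str, pos: int
) -> Optional[CopyNumberSegment]:
    # boundary positions shared by two segments resolve to the left segment
    hit = None
    for seg in segments:
        if seg.chrom == chrom and seg.contains(pos):
            if hit is None or seg.start < hit.start:
                hit = seg
    return hit


def call_sample(
    bundle: SampleBundle,
    config: Optional[VafConfig] = None,
    simulator_summary: Optional[Dict[str, float]] = None,
) -> SampleCallResult:
    """Run the full VAF pipeline on one tumour.

    Calibrate omega on het SNPs; derive per-segment BAF_som; apply site
    filters; keep powered sites; one-sided beta-binomial tests; BH with
    q <= 0.1; flank-outlier guards on candidates; finally the sample-level QC
    (final-p QQ slope must not exceed 1, and optionally both simulators must
    predict a non-zero violation count).

    ``simulator_summary``, when given, maps simulator name to its mean
    biallelic count over replicates; a sample where every entry is zero is
    excluded.
    """
    cfg = config or VafConfig()
    non_loh = {
        (s.chrom, s.start, s.end): s for s in bundle.segments if not s.is_loh
    }

    # --- omega calibration on het SNPs of non-LOH segments
    vs, ns, bafs = [], [], []
    snps_by_segment: Dict[Tuple[str, int, int], List[HetSNPObservation]] = {}
    for snp in bundle.het_snps:
        seg = _assign_segment(bundle.segments, snp.chrom, snp.pos)
        if seg is None or seg.is_loh:
            continue
        snps_by_segment.setdefault((seg.chrom, seg.start, seg.end), []).append(snp)
        vs.append(snp.major_count)
        ns.append(snp.total)
        bafs.append(seg.baf_seg)
    omega: Optional[float] = None
    if non_loh:
        calib = calibrate_omega(
            np.array(vs),
            np.array(ns),
            np.array(bafs),
            bounds=cfg.omega_bounds,
            min_snps=cfg.min_calibration_snps,
        )
        omega = calib.omega

    # --- per-segment corrected somatic BAF
    baf_som: Dict[Tuple[str, int, int], float] = {
        key: compute_baf_som(seg.baf_seg, bundle.pp, seg.logr_seg, cfg.baf_som_floor)
        for key, seg in non_loh.items()
    }

    outcomes = apply_site_filters(bundle.snvs, bundle.resources, bundle.segments)

    calls: List[VafCallResult] = []
    tested: List[VafCallResult] = []
    for snv in bundle.snvs:
        outcome = outcomes[snv.key]
        if outcome.status == "removed":
            calls.append(
                VafCallResult(snv, "removed", trail=[f"removed:{outcome.reason}"])
            )
            continue
        if outcome.status == "untested":
            calls.append(
                VafCallResult(snv, "untested", trail=[f"untested:{outcome.reason}"])
            )
            continue
        seg = _assign_segment(bundle.segments, snv.chrom, snv.pos)
        if seg is None:
            calls.append(
                VafCallResult(snv, "untested", trail=["untested:no-segment"])
            )
            continue
        key = (seg.chrom, seg.start, seg.end)
        model = BetaBinomialModel(
            m=min(baf_som[key], 1 - 1e-9), omega=omega
        )
        if snv.total < 1 or not power_filter(snv.total, model, cfg.power_alpha):
            calls.append(
                VafCallResult(
                    snv,
                    "untested",
                    powered=False,
                    trail=["untested:underpowered"],
                    flags=outcome.flags,
                )
            )
            continue
        p = betabinom_tail(snv.alt_count, snv.total, model)
        call = VafCallResult(
            snv,
            "not-significant",
            p=p,
            powered=True,
            trail=["tested"],
            flags=outcome.flags,
        )
        call._segment_key = key  # type: ignore[attr-defined]
        call._model = model  # type: ignore[attr-defined]
        calls.append(call)
        tested.append(call)

    # --- multiple testing over the tested universe
    if tested:
        qs = bh_adjust([c.p for c in tested])
        for call, q in zip(tested, qs):
            call.q = float(q)

    # --- neighbour guard on q-significant candidates
    for call in tested:
        if call.q is None or call.q > cfg.q_threshold:
            call.trail.append("not-significant")
            continue
        seg_key = call._segment_key  # type: ignore[attr-defined]
        guard = neighbour_guard(
            call.snv.pos,
            snps_by_segment.get(seg_key, []),
            BetaBinomialModel(m=non_loh[seg_key].baf_seg, omega=omega),
            per_snp_p=cfg.guard_snp_p,
            fisher_p=cfg.guard_fisher_p,
        )
        call.guard = guard
        if guard.status == "pass":
            call.verdict = "parallel-candidate"
            call.trail.append("candidate")
        elif guard.status == "fail":
            call.verdict = "removed"
            call.trail.append(f"removed:neighbour-guard:{guard.reason}")
        else:
            call.verdict = "untested"
            call.trail.append("untested:guard-untestable")

    # --- sample-level QC
    excluded = False
    reason = ""
    slope_final: Optional[float] = None
    if tested:
        slope_final = qq_slope(np.array([c.p for c in tested]))
        if slope_final > cfg.qq_slope_max + cfg.qq_slope_tol:
            excluded = True
            reason = (
                f"final QQ slope {slope_final:.2f} > {cfg.qq_slope_max} "
                "(purity possibly underestimated)"
            )
    if not excluded and simulator_summary is not None:
        if simulator_summary and all(v == 0 for v in simulator_summary.values()):
            excluded = True
            reason = "both simulators predict zero biallelic mutations"
    if excluded:
        logger.warning("sample %s excluded: %s", bundle.sample_id, reason)

    return SampleCallResult(
        sample_id=bundle.sample_id,
        excluded=excluded,
        exclusion_reason=reason,
        omega=omega,
        qq_slope_final=slope_final,
        calls=calls,
    )


@dataclass
class DivergentRecord:
    """Two-ALT candidate with per-allele germline posteriors and normal depth."""

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, str]
    p_germline: Optional[Tuple[float, float]] = None
    normal_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.alts) == 2 and self.alts[0] == self.alts[1]:
            raise ValueError("divergent record needs two distinct alternates")


def filter_divergent_candidates(
    record: DivergentRecord,
    max_p_germline: float = -1.0,
    min_normal_depth: int = 19,
) -> str:
    """Germline/depth rule filter for divergent (two-ALT) candidates.

    Passes when the germline posterior log-odds of *both* alternate alleles
    are below -1 and the matched normal holds >= 19 high-quality reads.
    Returns 'pass', 'fail' or 'unevaluable' (missing annotations).
    """
    if len(record.alts) != 2:
        raise ValueError("divergent filtering needs exactly two alternate alleles")
    if record.p_germline is None or record.normal_depth is None:
        return "unevaluable"
    if any(p >= max_p_germline for p in record.p_germline):
        return "fail"
    if record.normal_depth < min_normal_depth:
        return "fail"
    return "pass"
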