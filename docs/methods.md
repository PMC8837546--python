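# Methods

This note documents the models implemented in `biallelic`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## Violation classes and trinucleotide machinery

A diploid locus with mutation history is classified against its *current*
allelic state: a hit on the sister allele producing the same base is
**parallel**, a different base **divergent**; a second hit on the mutated
allele is **back** (restores the reference) or **forward** (third state).
This matches sequential simulation semantics at loci with more than two
hits. Two corner rules: re-drawing a mutation identical to the current state
(a "no-op") is rejected and resampled, since consensus variant calls cannot
represent it; and after back mutations restore a locus fully to reference, a
further hit has no violation class relative to the current state and is
treated as a fresh first hit.

Substitutions are binned into the standard 96 trinucleotide channels
(pyrimidine-strand normalised, COSMIC lexicographic order, frozen for
serialisation). Context abundance f_j counts positions whose full
trinucleotide lies inside one callable interval and contains no N; interval
edge positions therefore do not count and are not sampled.

The expected spectrum of parallel hits is the normalisation of p_j²/f_j:
two independent hits of channel j must meet within one of f_j equivalent
positions, so collision mass scales with the squared channel probability and
inversely with context abundance. The raw p² form (no abundance correction)
is available as a toggle; p²/f is the default because it is the
collision-probability derivation.

## Uniform-permutation simulator

Per replicate:

1. **Total burden** n_sim ~ Poisson(λ), λ ~ Gamma with mode equal to the
   observed burden n and standard deviation σ = cv·n (default cv = 0.05).
   The (rate r, shape β) pair solves these constraints exactly:
   r = (n + √(n² + 4σ²)) / (2σ²), β = 1 + n·r.
2. **Chromosome allocation**: multinomial with probabilities drawn from
   Dirichlet(observed per-chromosome counts + 1).
3. **Per-chromosome spectrum**: Dirichlet around the chromosome's channel
   counts plus pseudocounts ψ_j = (overall count_j + 1) × (2/3) / n — a weak
   prior totalling ≈ 2/3 that keeps rare channels reachable. The 2/3 scale
   is exposed as a configuration constant.
4. **Sequential rejection sampling**: candidate (position, allele, alt)
   triples are drawn uniformly over both allelic copies of the callable
   positions; a candidate whose *current* (overlay-aware) trinucleotide is T
   implies channel j and is accepted with probability (π_j/f_j)/max(π/f).
   Over reference contexts this reproduces the target spectrum exactly; at
   already-mutated sites it prices back/forward hits by the same per-position
   rate. Overlay contexts whose class is absent from the reference (f = 0)
   cannot be hit. Attempts are capped at 10⁶ per mutation.

Each accepted hit updates the diploid overlay and, when the locus has prior
hits, is tallied by violation class. Two counting conventions are kept:
per-class counts tally each classified second hit once (a parallel pair is
one event), while `n_violating_mutations` counts every mutation at a
multi-hit locus (a pair counts two) — the latter is the quantity the
birthday closed form n − n(1−1/N)^(n−1) measures.

Reproducibility: replicate r uses the deterministic child stream
SeedSequence(seed, spawn_key=(r,)), so replicates are order-independent.

## Neighbour-resampling simulator

Allele A keeps ⌈n/2⌉ of the target's own non-driver mutations; allele B
draws ⌊n/2⌋ without replacement from the pooled non-driver mutations of
representative donors — same histology, spectrum cosine ≥ 0.9 with the
target, target excluded from its own pool. The pool must hold at least half
the target burden (eligibility). Same-position duplicates *within* allele B
are discarded and redrawn, since the model defines only cross-allele events.
A positional A/B collision is parallel when the alternate alleles agree
(for indels: identical position, ref and inserted/deleted sequence),
divergent otherwise; back/forward mutations cannot arise. Input mutations
are treated as single events, which underestimates violations to the extent
that some inputs are already biallelic.

## Closed-form estimators

* Birthday expectation: exact = n − n(1−1/N)^(n−1) and approx = n²/N, with
  N the callable locus count of the genome at hand (never a hard-coded
  3.2 Gb).
* C_type: through-origin least squares of mean simulated violations on
  m²/N; no intercept because predictions must vanish at zero burden.
* Effective genome size: N_eff = N_callable × E_uniform / E_neighbour,
  since violations scale as 1/N. The ratio form is a reconstruction from
  the concept (the estimator is flagged as such in CLI output); degenerate
  expectations report missing rather than zero.

## VAF caller

Allele counts at phased heterozygous SNPs follow
V ~ Bin(n, p ~ Beta(BAF_seg·ω, (1−BAF_seg)·ω)). The sample concentration ω
(a pseudo-coverage, bounded to [50, 1000]) is found by a deterministic
log-spaced grid of 40 points plus local refinement, choosing the ω whose
het-SNP QQ slope is nearest 1. Numerical choices here:

* Scalar tail and two-sided p-values are computed by exact pmf summation
  (ratio recurrence + compensated summation; scipy fallback on underflow),
  accurate to ~10⁻¹³ — log-gamma routes lose ~10⁻¹² at n ≈ 200. The
  vectorised calibration path builds pmf tables per unique (depth, mean)
  pair from scipy log-pmfs.
* The public two-sided p is the doubled smaller tail capped at 1 — simple
  and conservative. *Inside the calibration only*, the mid-p correction
  (half the observed count's mass in each tail) is used: the doubled-tail p
  is conservative for discrete counts, which would bias the slope-1 search
  towards roughly double the true ω; mid-p restores near-uniformity under
  the null.
* "Robustly fitted" QQ slope: Theil–Sen on −log10 p quantile pairs,
  excluding exact p = 1 ties (but keeping them in the expected-quantile
  denominator), thinned to ≤ 500 evenly spaced order statistics for
  tractability.

The somatic null for a clonal mutation on all copies of the major allele is
the beta-binomial with mean BAF_som (formula in the README); estimates
below 0.05 are conservatively raised back to BAF_seg. A site is *powered*
when its minimal attainable one-sided p — the tail at v = n — is below
0.001; this is the only reading of the power condition that removes
low-depth and BAF_som ≈ 1 sites. BH correction runs over the tested
(post-filter, powered) universe; candidates need q ≤ 0.1.

Positional filters remove SNVs at heterozygous germline SNPs, in common
structural-variant regions, with ≥ 2 het SNPs within 25 bp (mapping bias),
and leave LOH segments untested (in males only the X pseudoautosomal
regions are considered). Non-removing flags mark T-/B-cell receptor loci,
indel proximity (offsets −10..+25 bp from the SNV) and failed liftover.
The flank guard takes the nearest het SNP on each side within the segment
(configurable to more): each flank's two-sided BAF p must exceed 0.001 and
the Fisher combination 0.01; identical thresholds on Gaussian logR
p-values with the segment median and the consistency-adjusted MAD
(1.4826×) as scale. Candidates whose guard is untestable (missing flank)
are reported as untested rather than called.

Sample-level QC: the Theil–Sen slope of the final one-sided p-values must
not exceed 1 (plus a 0.05 tolerance absorbing order-statistic noise at
finite SNV counts — an under-estimated purity inflates the slope far
beyond this); and, when simulator summaries are supplied, samples where
both models expect zero biallelic events are excluded. Segment assignment
is 1-based inclusive with boundary ties resolved to the left segment; BAF
values are consumed already phased and flipped to ≥ 0.5 per haplotype block.

Divergent candidates (two-ALT records) are filtered by rule: both alternate
alleles' germline posterior log-odds < −1 and ≥ 19 high-quality reads in
the matched normal; missing annotations yield "unevaluable".

## Phasing caller

Read pairs require mapping quality ≥ 20 on both reads, base quality ≥ 25 at
the two phased positions (not read-wide — that is what phasing consumes),
no clipping, proper non-duplicate pairs without vendor failure or indels,
and < 2 mismatches per read, < 3 per pair (the phased variants themselves
are not counted as mismatches). A parallel call needs ≥ 2 Ref-Alt and ≥ 2
Alt-Alt pairs, each > 10% of the four-cell total (the denominator includes
all informative pairs; pairs uninformative at one position are excluded
upstream by construction), and the SNP's two-sided p > 0.001 — the sole
guard against a gained in-cis allele being mutated to in-trans. An SNV with
several informative SNPs is parallel if any pair calls parallel. Note the
>10% rule makes the call non-monotone exactly at the fraction boundary:
adding an Alt-Alt read grows the denominator and can demote a Ref-Alt
fraction sitting at precisely 10%.

Precision is the fraction of VAF calls among phaseable SNVs confirmed by
phasing; recall the fraction of phasing hits recovered by VAF; cohort
medians are restricted to samples with ≥ 10,000 phaseable SNVs. The total
parallel burden extrapolates the phaseable rate to all tested SNVs via
n_viol ~ Bin(n_tested, P ~ Beta(n_par + 0.001, n_single + 0.001)), reported
as the posterior-predictive mean with 2.5/97.5 percentiles.

## Synthetic data generator

The generator emulates the detection substrate: i.i.d. random references at
a stated GC (default 0.41, genome-like), contiguous copy-number segment
layouts from a configurable menu (1+1, 2+1, 2+2, 2+0, 1+0), heterozygous
SNPs at ~1/1.5 kb with beta-binomial counts at the segment BAF, and somatic
SNVs whose expected VAF is ρk/(2(1−ρ)+ρc) for multiplicity k in a segment
of total copy number c. Depth is Poisson around the copy-number-scaled mean
coverage — deliberately simple, since the over-dispersion being tested
lives in the allele-count beta-binomial, not the depth. Per-SNP logR is
log2(depth/mean coverage), making E[logR_seg] = log2 of the copy-ratio, and
segment BAF_seg/logR_seg are estimated from the generated SNPs, as a
copy-number caller would.

Planted parallel events default to all copies of both alleles mutated (a
clonal early event); a late-event mode mutates one copy per allele to
exhibit the VAF caller's documented blind spot. A configurable fraction
(default 0.2) of background single SNVs in gained segments predates the
gain (multiplicity = major copy number) — these sit exactly on the caller's
null and are the realistic precision stressor. Optional trap sites (an SNV
on a het SNP; an SNV inside an emitted common-SV window) verify the filter
cascade end to end. Phased-pair evidence assigns the SNP alternate allele
to the major haplotype and mixes tumour haplotype copies with admixed
normal cells; a symmetric per-allele error rate corrupts observations.

What the synthetic benchmarks do **not** show: robustness to alignment and
sequencing artefacts (OxoG, strand bias, reference bias at flanking
germline variants), to copy-number segmentation errors beyond the planted
flank outliers, to subclonal copy-number mixtures, or to real mutation-rate
heterogeneity along the genome — on real data the neighbour-resampling
model exists precisely because uniform models understate clustering.

## Benchmark problem sizes

The bundled statistical checks use a 10⁴-locus homogeneous toy (burden 500,
1,000 replicates) for the birthday comparison — built on a two-letter
{C,T} alphabet so the mutation alphabet is closed (back hits representable)
and only 8 context classes exist, keeping the hierarchical resampling's
collision-rate inflation near 1% — a two-channel 2,000-locus toy at 10⁴
replicates for the squared-spectrum property, a 2 Mb genome with 10⁴ SNVs
and 20 planted events for spike-in recovery, 5,000 SNPs at depth 60 for ω
recovery, and 200 simulated samples for extrapolation coverage. These sizes
give Monte-Carlo standard errors comfortably below the tested tolerances.

## Known limitations

* The VAF caller is blind to parallel events with multiplicity below the
  major copy number (late events) and in LOH; phasing partially covers the
  former, nothing covers the latter.
* ω recovery by QQ slope is weakly identified at low over-dispersion
  (ω ≳ 600 at depth 60): the slope criterion approaches its asymptote and
  estimates scatter widely within the clamp.
* The uniform-permutation simulator's hierarchical burden/spectrum
  resampling slightly inflates collision counts relative to the fixed-burden
  closed form (≈ 1–6% depending on the number of context classes); this is
  a property of the model, not a defect of the sampler.
* The neighbour-resampling eligibility rule (pool ≥ half the burden) leaves
  tumours with rare histologies or idiosyncratic spectra unsimulatable.
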