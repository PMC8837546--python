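# biallelic

Modelling and detection of **biallelic somatic mutations** — violations of
the infinite sites assumption — in bulk tumour genomes.

## The problem

Most cancer-genomics methods assume each genomic position mutates at most
once in a tumour's history (the *infinite sites assumption*). In heavily
mutated tumours this breaks down: both parental alleles of one site can be
hit independently, either by the same substitution (**parallel**) or by two
different ones (**divergent**); a second hit on an already-mutated allele can
restore the reference (**back**) or create a third state (**forward**).
Unrecognised biallelic mutations distort variant allele frequencies and
confound driver inference, subclonal reconstruction, mutation timing and
phylogenetics.

This package provides, for users analysing somatic SNV/indel calls with
allele-specific copy number:

* **Simulators** of expected violation counts per tumour:
  - *uniform permutation*: resamples the observed burden uniformly over both
    allelic copies of the callable genome, respecting the trinucleotide
    spectrum, tracking every hit locus;
  - *neighbour resampling*: keeps half the tumour's own (non-driver)
    mutations on one allele and draws the other half without replacement
    from pooled, spectrum-matched (cosine ≥ 0.9) same-histology tumours.
* A **VAF-based caller** for parallel mutations: beta-binomial test of alt
  read counts against the purity/ploidy-corrected segment BAF,

  `BAF_som = BAF_seg − (1−ρ) / [(2(1−ρ) + ρΨ_t) · 2^logR_seg]`,

  with per-sample concentration ω calibrated on heterozygous SNPs (QQ slope
  1), an independent power filter, Benjamini–Hochberg correction (q ≤ 0.1)
  and a cascade of positional filters and flank-outlier guards.
* A **phasing-based caller**: an SNV within 700 bp of a heterozygous SNP is
  parallel when ≥ 2 Ref-Alt *and* ≥ 2 Alt-Alt read pairs each exceed 10% of
  phased reads; plus precision/recall benchmarking of the VAF caller and a
  beta-binomial extrapolation of the total parallel burden.
* **Closed-form estimators**: the birthday-problem expectation
  `E[violating mutations] = n − n(1 − 1/N)^(n−1) ≈ n²/N`, a per-tumour-type
  coefficient fit (`C_type·m²/N`), and the effective genome size implied by
  the two simulators.
* A **synthetic-cohort generator** producing reference genomes, catalogs
  with planted biallelic events, over-dispersed read counts and phased
  read-pair evidence, with truth manifests — every stage is testable with no
  access to controlled patient data.

## Worked example

```python
import numpy as np
import biallelic as bl

# synthetic tumour: 2 Mb genome, 1+1 and 2+1 segments, 5,000 SNVs with
# 8 planted biallelic parallel events, purity 0.9, depth 80
genome = bl.generate_reference({"chr1": 2_000_000}, seed=11)
layout = bl.SegmentLayout.even(
    {"chr1": 2_000_000}, [bl.SegmentSpec(1, 1), bl.SegmentSpec(2, 1)]
)
spectrum = bl.TrinucleotideSpectrum(np.ones(96)).normalise()
records, truth = bl.generate_catalog(
    genome, spectrum, 5_000, (8, 0), seed=12, layout=layout
)
bundle = bl.simulate_observations(
    truth, layout, bl.PurityPloidy(rho=0.9, psi_t=2.0),
    mean_depth=80, omega_true=300, seed=13,
)

# how many biallelic events does this burden predict by chance?
tallies = bl.run_uniform_permutation(records, genome, replicates=200, seed=14)
summary = bl.summarize_tallies(tallies)
print(f"expected biallelic events under uniform permutation: "
      f"{summary.mean_biallelic:.2f}")
exact = bl.birthday_expectation(
    bl.BirthdayInput(n=5_000, N=genome.callable_locus_count())
).exact
print(f"birthday closed form (violating mutations): {exact:.2f}")

# detect the planted events from read counts
result = bl.call_sample(bundle)
called = {c.snv.key for c in result.candidates}
print(f"calibrated omega: {result.omega:.0f}")
print(f"parallel candidates: {len(called)}, "
      f"true positives: {len(called & truth.parallel_keys())} / 8")
```

Output:

```
expected biallelic events under uniform permutation: 3.43
birthday closed form (violating mutations): 12.48
calibrated omega: 427
parallel candidates: 7, true positives: 7 / 8
```

The simulator's 3.43 counts biallelic *pairs* arising from cross-allele
collisions, while the closed form counts every *mutation* involved in any
same-locus collision (each pair twice, and same-allele collisions too) —
hence the factor of ~4 between them. The caller recovers 7 of the 8 planted
events (one falls to the filter cascade) with no false positives.

A command-line interface mirrors the library
(`biallelic synth-cohort | simulate-violations | call-vaf | call-phasing |
filter-divergent | estimate | evaluate`); see `biallelic --help`.

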