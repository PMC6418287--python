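# Methods

## Problem

When a patient presents with several synchronous tumors (the motivating
setting is multi-nodular hepatocellular carcinoma), the clinical question is
whether the nodules are independent primaries (multi-centric disease) or
clonally related (one seeded the other, an intrahepatic metastasis).
Comparing somatic mutation catalogues across tumors — recall rates — answers
this cleanly only when tumors share most or none of their mutations.  The
awkward middle case is a pair of tumors that share almost no SNVs but do
share chromosome-scale copy-number alterations (CNAs).  Convergent evolution
can produce the *same-looking* CNA twice independently; identity by descent
produces it once, in a common ancestral clone.  The two are distinguishable
because an inherited CNA must sit on the same homologous chromosome in both
tumors and carry the same breakpoints.

## The phasing test

At a germline heterozygous site the ALT allele sits on one of the two
parental homologs and the normal-tissue allele frequency (AF) is ~0.5.  A
one-homolog gain or loss unbalances the alleles, so in the tumor the AF
shifts up at sites whose ALT allele rides the amplified/retained homolog and
down at the others.  The per-site AF delta (tumor AF − normal AF) therefore
encodes phase: sites shifting the same way belong to the same haplotype
(H1 = up, H2 = down, |delta| ≤ `min_shift` = uninformative).

For a candidate CNA shared by tumors A and B the test is:

1. admit germline het sites inside the candidate interval (normal depth ≥
   `min_depth`, normal AF inside `het_band`); compute per-tumor deltas from
   pooled read counts across each tumor's regions;
2. group sites into haplotypes by tumor A's shift directions; take the H1
   set;
3. Welch two-sample t-test of the H1 sites' deltas in tumor A against the
   *same sites'* deltas in tumor B, treating one haplotype's AF observations
   as random variables with mean μ and variance σ²:

       t  = (x̄ − ȳ) / √(s²x/nx + s²y/ny)
       ν  = (s²x/nx + s²y/ny)² / [(s²x/nx)²/(nx−1) + (s²y/ny)²/(ny−1)]

   with unbiased sample variances and a two-sided p-value;
4. repeat with tumor B as the haplotype reference (the procedure is then
   symmetric in the pair);
5. verdict at significance level `alpha` (default 0.05), with the null
   hypothesis that both tumors altered the **same** homolog:
   `different_homolog` when both directions reject *and* the matched
   haplotype's mean deltas are not sign-concordant across the tumors;
   `same_homolog` when the signs agree in both directions and neither
   rejects; `inconclusive` otherwise, and always when either direction has
   fewer than `min_informative_sites` matched sites.

The sign guard exists because a purity difference between two tumors that
altered the *same* homolog scales delta magnitudes without flipping signs;
a plain Welch rejection would misread that as a phase difference.  With the
guard such pairs fall to `inconclusive` rather than `different_homolog`
(covered by a dedicated test).

Which quantities enter the t-test is a genuine design choice: deltas are
the default because the procedure is defined in terms of AF differences
against the matched normal; a `use_raw_af` flag compares raw tumor AFs on
the matched site set instead.

### Calibration note (why the delta test is conservative)

At a given site the normal-sample AF noise enters both tumors' deltas with
the same sign.  Because both Welch samples are evaluated on the *same* site
set, that shared term cancels from the difference of means but still
inflates both sample variances.  The Welch denominator therefore
overestimates the variance of the numerator, and under the same-homolog
null the p-values pile up toward 1 rather than being uniform: the test is
conservative, with type-I error well below `alpha` at realistic depths
(measured at ~0 for depth 100; the acceptance script recomputes this).
Uniformity of p-values is a property of the `welch_t_test` primitive itself
(verified on iid null samples), not of the pipeline statistic.  Selection of
H1 sites by the reference tumor's observed deltas introduces a small
anti-conservative truncation bias in the opposite direction; at the default
`min_shift` (0.05) and chromosome-arm effect sizes (|delta| ≈ 0.33 at purity
0.8) it is negligible.

## Breakpoint concordance

Candidate shared CNAs are same-chromosome, same-state segment pairs with
reciprocal overlap ≥ 0.5, where reciprocal overlap is intersection length
over the *longer* segment.  Segments first pass validity thresholds: length
strictly greater than 50 kb and at least 21 supporting probes.  Breakpoints
are concordant when both ends agree within `breakpoint_tolerance` (default
1 Mb — array/exome segmentation is coarse; configurable).  A segment end
that reaches a telomere (coordinate 0, or the chromosome length when known)
is auto-concordant at that end: terminal events are bounded by the
chromosome, not by where the break occurred.  This is what resolves the
shared-terminal-loss pattern: same homolog, same state, but proximal
breakpoints 10 Mb apart ⇒ two independent events.

## Variant filtering and recall

Somatic status is presence/absence in the matched normal (any ALT read ⇒
germline).  Somatic candidates then face exclusion filters, all reasons
reported without short-circuiting: segmental-duplication membership; any
ALT read in the normal; normal depth < 10; tumor depth < 8; tumor ALT reads
< 3; tumor VAF < 3%; population frequency strictly above 2%; local-cohort
frequency at or above 5%.  Boundary semantics follow the filter wording
("larger than", "at a frequency of", "<3%"); "fewer three variant reads" is
read as "fewer than three".  Population and cohort frequencies are supplied
as lookup tables; an absent entry means the filter is not applicable.

Recall of region A in region B is |A ∩ B| / |A| over somatic SNV keys —
directional, so the matrix is asymmetric while shared counts are symmetric.
The denominator convention is a choice (no standard exists); Jaccard is
available via `metric="jaccard"`.  Averages are taken over ordered
off-diagonal pairs, within-tumor and cross-tumor separately; undefined
entries (empty reference set) are excluded, not zeroed.

## Origin classification

Per tumor pair: `common_origin` if cross-tumor recall ≥ `high_recall`
(default 0.5) or any shared CNA is same-homolog *with* concordant
breakpoints (identity by descent); `independent_origin` if cross-tumor
recall ≤ `low_recall` (default 0.15) and every shared CNA is explained as
independent (different homolog, or discordant breakpoints); otherwise
`indeterminate`.  Mutation sharing has no accepted universal cutoff; the
defaults separate the observed regimes (within-tumor recalls of 65–85%
versus cross-tumor 7–11%) and are configurable.

## Synthetic data

The generator emulates a multi-region exome study: per patient, germline
het sites (Poisson count at `het_site_density` per Mb, uniform unique
positions, fair-coin parental phase), per-tumor CNAs on a labelled homolog,
and somatic SNVs split into per-tumor trunks (offered to every region,
each detected with `trunk_detection_prob`, modelling caller misses — the
mechanism that keeps within-tumor recall below 1), per-region private
mutations, and optional cross-tumor shared mutations (`cross_tumor_shared`
> 0 switches the ground-truth scenario to metastasis).  Position pools are
disjoint by construction, so mutation keys never collide.

Read counts: expected AF from the purity mixture

    AF = (φ·c_alt + (1−φ)) / (φ·(c_A + c_B) + 2(1−φ))

(φ = purity; c are tumor homolog copy numbers; 1 each outside a CNA), depth
zero-truncated Poisson(`mean_depth`), ALT reads Binomial(depth, AF).
Somatic VAFs are drawn from a beta distribution parameterised by (mean,
concentration), default (0.25, 15), mimicking the low-VAF spread of real
tumor regions.  There is no sequencing-error term by default (`error_rate`
flag available): errors are the filtering module's concern, and a clean
noise model keeps the generator's moments exactly checkable.  Breakpoints
are emitted exactly unless `breakpoint_jitter` is set; probe support is
emulated at one probe per 5 kb.

Defaults mirror the study design the package targets: 2 patients, 3 tumors
each, ≥2 regions per tumor, mean depth 118 (average exome depth), purity
0.8 (samples pathologically verified to contain ≥80% tumor cells — the
purity itself is a modelling choice, not a measured value), genome = the
four hs37d5 chromosomes carrying the candidate events (6, 8, 17, 21).

What the simulation does *not* model — hence what passing tests do not
show about real data: mapping and sequencing artifacts, caller-specific
biases, subclonal copy number, allele-specific states beyond single
gain/loss of one homolog, indel realism (indels are opaque keys), and
germline sites violating Hardy–Weinberg phase independence.

## Problem sizes and numerics

Calibration and power suites use 50-site segments at depth 100 (≈25
informative sites per haplotype), 1,000 replicates for the type-I bound and
500 for power; haplotype-recovery uses purity 1 at depth 10,000, where
binomial noise cannot cross 0.5.  End-to-end runs use full-length
chromosomes at 5 het sites per Mb.  Welch degenerate inputs: two zero
variances with equal means give t = 0, p = 1; with unequal means p = 0 plus
a warning; fewer than two observations per side is an error.  All
randomness flows from `numpy.random.default_rng` seeds; every generator
output is a pure function of (config, seed), and pipeline reports are
byte-identical across reruns with the same seed.

## Known limitations

- Phasing compares tumor pairs only; >2 tumors are handled pairwise.
- Pooling read counts across a tumor's regions assumes the CNA is clonal
  within the tumor.
- The union interval of two matched segments is used for site selection; a
  large breakpoint offset dilutes the matched-haplotype comparison toward
  `inconclusive` (the breakpoint verdict carries the signal there, as in
  the terminal-loss case).
- No multiple-testing correction across candidate CNAs by default (per-CNA
  decisions at `alpha`); apply your own when scanning many candidates.
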