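# Methods

This note records the models, conventions and numerical choices behind
`rohscan`, and what the synthetic-data validation does and does not show.

## Genotype model and QC

Genotypes are held as an allele-B dosage matrix (`int8`, −1 = missing)
with a 1-based variant map. Every downstream statistic depends only on
the {homozygous, heterozygous, missing} partition, so the arbitrary
choice of counted allele is inert; a `canonicalize_alleles` step puts
matrices in first-observed allele order so PED round trips are exact.

QC applies, in order: autosome restriction (labels 1–18 by default, for
the pig), sample call rate, SNP call rate (recomputed on retained
samples), then MAF. Call-rate bounds are inclusive (a rate exactly at the
threshold is kept); the MAF bound is strict (MAF equal to the threshold
is removed). The order — samples before SNP filters, call rate before
MAF — follows the dominant convention of array-QC tooling; the report
records it so alternative orders are auditable. Mean expected
heterozygosity uses the uncorrected 2p(1−p); the small-sample correction
is reserved for F_HOM's expectation term, where method-of-moments
estimators conventionally apply it.

## ROH detection

The scan is the incremental sliding-window heuristic used by PLINK's
`--homozyg`: windows of `window_snps` consecutive SNPs (default 50) are
judged homozygous when they contain at most `max_het_per_window` (1)
heterozygotes and `max_missing_per_window` (5) missing calls; each SNP's
hit fraction is the proportion of its covering windows that are
homozygous; SNPs with hit fraction ≥ `window_hit_threshold` (0.05, the
established default of this method family) are flagged; maximal runs of
flagged SNPs, split at inter-SNP gaps above `max_gap_kb` (1,000), become
segments if they satisfy `min_length_bp` (1 Mb), `min_snps` (50) and the
density bound `length_kb / n_snps ≤ 100`.

Conventions worth stating explicitly:

- Coordinates are 1-based inclusive; segment length is end − start + 1
  (the convention reproduces published island lengths exactly).
- Windows never span chromosomes and are never truncated, except that a
  chromosome with fewer SNPs than the window size is scanned as one
  whole-chromosome window. End-of-chromosome SNPs are simply covered by
  fewer windows; the per-SNP denominator accounts for it.
- Length classes are the left-closed partition [1, 5), [5, 10),
  [10, ∞) Mb, so a 5 Mb segment is "5–10". The labels "1–5 / 5–10 / >10"
  are ambiguous at the boundaries; left-closed makes them a partition.
- No heterozygote limit applies to a final segment beyond what the
  window criterion induces.
- Because flagging requires ≥ 5% of covering windows to be homozygous,
  the flagged region begins ⌈0.05 × 50⌉ ≈ 2–3 SNPs inside a true
  autozygous tract: detected boundaries are systematically inside the
  truth by up to ~3 marker spacings. Tests assert exactly this bound.

A deliberately naive reference caller (`naive_roh_oracle`, pure-Python
enumeration of every window) shares the contract and is held equal to
the vectorised implementation on hundreds of random instances; it exists
to catch indexing errors in the cumulative-sum scan, not for production
use.

## Inbreeding coefficients

F_ROH = Σ L_ROH / L_auto per individual, per length class and in total,
all with the same denominator so the class values add exactly. L_auto is
the sum over chromosomes of (last − first marker position + 1) — a
literal "length covered by the SNPs"; a fixed override is accepted for
cross-study comparability with nominal genome sizes.

F_HOM = (O − E)/(L − E) over each individual's non-missing autosomal
SNPs: E sums 1 − 2p(1−p)·2N/(2N−1) with p the sample allele frequency
and N the SNP's non-missing count. Restricting O, E and L to the same
per-sample support keeps the three terms on one footing; an `all_snps`
flag evaluates the alternative. F_HOM is NaN when L = E (monomorphic
support) and may legitimately be negative — heterozygosity excess, as
expected in admixed and composite populations. Correlations between the
five coefficients are pairwise-complete Pearson; constant columns yield
NaN entries rather than propagating.

## ROH islands

Per-SNP incidence counts individuals (once each) whose segment spans the
SNP. The threshold is the incidence at rank ⌈0.01 × n_SNPs⌉ from the
top, applied inclusively, so ties can push the qualifying set slightly
past 1%. "Adjacent" qualifying SNPs means consecutive in map order on
one chromosome with no intervening non-qualifying SNP; an optional
maximum gap is off by default. Islands need ≥ 2 SNPs by default so a
single noisy SNP cannot form one. Annotation counts user-supplied
features overlapping an island by ≥ 1 bp in 1-based inclusive
coordinates (BED input is shifted from 0-based half-open).

## LD decay

r² is the squared Pearson correlation of dosage vectors over samples
non-missing at both SNPs — the composite genotype-level estimator, the
standard surrogate for haplotype r² on unphased array data (an EM
haplotype estimator is out of scope). Pairs are same-chromosome, within
99,999 index positions and 1,000 kb by default. Monomorphic-on-support
pairs and pairs with < 2 common samples are skipped. Bins are half-open
[lo, hi) 100-kb intervals; LD extent interpolates linearly between bin
midpoints around the crossing, anchored at distance 0 with the
consecutive-pair mean when even the first bin is below the level. Both
readings of "adjacent SNP" LD — strictly consecutive pairs, and all
pairs under 100 kb — are reported side by side. Panel size is
⌈genome / spacing⌉.

## Synthetic data generator

The generator models exactly what the analyses consume, no more: an
array-like map (per-chromosome exponential spacings), HWE background
genotypes at frequencies drawn uniformly from [0.05, 0.5], and planted
autozygous tracts. Per individual the tract count is Poisson with mean
`target_f · L / tract_mean_bp`, lengths are shifted-exponential (minimum
1 Mb, mean 4 Mb), placement is uniform with overlap rejection — so the
expected autozygous fraction is `target_f` while individuals vary, as in
real populations. Inside tracts one allele is drawn from the population
frequency and doubled; a configurable heterozygote error (default 0.5%)
exercises the one-het-per-window allowance, and uniform missingness
(default 1%) the missing allowance. An optional forced tract shared by a
chosen carrier fraction creates a ROH island of known coordinates.

Defaults are one scientist-chosen condition set, fixed once: 18
chromosomes × 2,000 SNPs at 25 kb mean spacing, 200 individuals, mean
autozygosity 0.08 (the level reported for composite pig populations).
The 25 kb spacing makes the canonical 1 Mb / 50-SNP minimum operative
(~40 SNPs per Mb); at a physical 50K-chip density the 50-SNP floor
silently raises the effective minimum detectable ROH to ~3 Mb — a
property of the chip, not the method — so the simulated genome is best
read as a scaled model, not a pig genome replica.

LD structure, when requested (`ld_block_snps > 1`), comes from founder-
haplotype copying: each haplotype copies one of `n_founder_haplotypes`
(30) founders, resampling the founder with probability
1/`ld_block_snps` per SNP. Pairs sharing a copied stretch are
associated, giving r² that decays smoothly with marker distance towards
the 1/n sampling floor; with `ld_block_snps = 1` genotypes are
independent Binomial(2, p) draws. The achievable short-range r² is
bounded near 1/K + 1/n, so the generator reproduces the *shape* of
empirical decay curves, not the high absolute r² of a real bottlenecked
breed. All randomness flows from one seeded `numpy.random.Generator`;
identical configurations are byte-identical on disk.

What the simulator deliberately omits: pedigree/coalescent ancestry,
selection and demography, allele-frequency spectra estimated from a real
chip, genotyping-error modes other than tract heterozygote calls and
uniform missingness, and sex chromosomes. Passing tests therefore show
that the implementation does what the method specifies and recovers
planted structure under array-like conditions — not that the method is
robust to every artefact of real array data.

## Validation problem sizes

The test-suite and acceptance-script simulations are sized for a
single-CPU desk run: recovery uses three populations of 200 individuals
× 36,000 SNPs; island recovery 100 × 6,000; LD checks 500 × 2,000 and
200 × 4,000; the oracle comparison 500 instances of ≤ 200 SNPs × 3
chromosomes. The LD null check compares the pooled mean r² to 1/n using
the standard error across per-chromosome means, because pairs sharing a
SNP are not independent and a per-pair standard error would be
anti-conservative.

## Known limitations

- The sliding-window caller is genotype-based; genotype-likelihood or
  HMM callers for sequencing data are out of scope.
- F estimators beyond F_ROH and F_HOM (F_GRM, F_UNI) are not provided.
- Island annotation is plain interval overlap against user intervals;
  no gene-function inference.
- The PED reader infers allele order from first observation, so a file
  whose first observed genotype at a SNP is the rarer homozygote flips
  which allele is counted; homozygosity statistics are unaffected.
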