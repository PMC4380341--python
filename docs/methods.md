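# Methods

`poolsweep` analyses pooled resequencing (Pool-seq) data from two related
populations — a selected line and an unselected control — to locate selective
sweeps and nominate candidate genes under directional selection. This note
records the statistical model, the conventions the package fixes where the
procedure leaves choices open, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Data model

The pipeline consumes samtools 6-column text pileups (one per pool), a FASTA
reference, and GTF gene models. Pileup base strings are decoded per the
mpileup dialect: `.`/`,` are reference matches, letters are mismatches
(strand case merged), `^X`/`$` read boundaries and `+N`/`-N` indel suffixes
are consumed, and `*` deletion placeholders are removed from coverage. Bases
with Phred quality below the configured minimum (default 25) are dropped
together with their qualities. `N` bases carry no allelic information and
never enter allele counts. The Y chromosome, mitochondrial genome, and
dot-chromosome analogues are excluded by the default whitelist.

Internally, coordinates are 0-based half-open; pileup and GTF positions
(1-based) are converted at the boundary.

## Nucleotide diversity

At a site with allele counts `c_A..c_T` summing to `n`, diversity is the
read-pair heterozygosity

    pi = n/(n-1) * (1 - sum_i p_i^2),  p_i = c_i/n,

i.e. the fraction of mismatching unordered read pairs, defined for any
number of alleles and undefined below two reads. Reads are treated as
sampled chromosomes ("read-based" mode): no correction is applied for two
reads sampling the same pool chromosome, so a small negative bias relative
to the pool's true diversity is expected and accepted (see *Calibration*).

The sliding-window scan (500-kb windows, 100-kb step by default) reports,
per window, the sum of per-site pi divided by the number of
coverage-qualifying sites (coverage within [min, max], defaults [2, 75]),
alongside the covered fraction of the window. Only sites passing the SNP
rule — at least two alleles at or above `min_count` (default 2) — contribute
to the numerator. This gating is the package's convention: isolated
sequencing-error reads would otherwise add an error-rate-dependent floor to
every window (at coverage 60 and residual error 5e-5, roughly 1e-4 per
site — half of a typical fly-autosome theta), which matters most exactly
where sweeps suppress true polymorphism. Windows with zero SNPs, or with a
covered fraction below `min_covered_fraction` (default 0.6, a guard for
degenerate inputs), are reported as `"na"` and excluded from means.

## Sweep calling

Each window's fold reduction is the chromosome-arm mean diversity (over
defined windows) divided by the window's diversity; a window of exactly zero
diversity passes any cutoff (infinite fold). Windows at >= 100-fold are
"major", >= 90- but < 100-fold "minor". Flagged windows are labelled by
their start on the step grid and abutting labels merge into intervals,
numbered 1..k in genome order within each tier; tiers never merge with each
other. Cutoffs are conventions of the procedure, not significance
thresholds; no permutation null is attached.

## Tajima's D at uniform coverage

D depends on sample size, so every usable site (coverage within range and at
least the uniform depth, default 30) is first subsampled to exactly that
depth without replacement (multivariate hypergeometric). Per window,

    D = (pi_w - S/a1) / sqrt(e1*S + e2*S*(S-1)),

where `pi_w` is the sum of per-site heterozygosity over the subsampled
sites, `S` the number of sites still polymorphic (any two alleles present)
after subsampling, and `a1, e1, e2` the Tajima (1989) constants at the
uniform depth. `S = 0` gives `"na"`. Subsampling is seeded per (chromosome,
window index) from the run seed, so reruns are bit-identical and windows are
independent. Gene-level D applies the same formula with a gene's
concatenated CDS as the window, seeded per gene id.

Singletons deliberately count toward `S`: truncating them (e.g. by applying
the SNP min-count rule after subsampling) removes the spectrum class the
constants weight most and pushes neutral D strongly positive.

## Coding selection (piN/piS)

Gene models come from GTF CDS rows; when a gene has several transcripts the
longest total CDS is analysed. Genes whose CDS length is not a multiple of
three are excluded with a warning. Codons are read from the concatenated CDS
in transcript orientation; minus-strand genes complement both codon and
alternate allele. Site counts use Nei–Gojobori fractional counting: each
codon position contributes `f` synonymous sites, `f` being the fraction of
its three possible single-base changes that preserve the amino acid, with
stop-creating changes counted as nonsynonymous and N-containing codons
skipped; nonsynonymous and synonymous sites partition `3 x codons` exactly.

Each CDS SNP passing the coding thresholds (min count 4, coverage in
[8, 75]) contributes its per-site heterozygosity to the synonymous or
nonsynonymous accumulator according to the codon consequence of its
non-reference allele(s); multi-allelic sites split the contribution in
proportion to each alternate's pairwise-mismatch share, conserving the
total. `piN` and `piS` are the accumulator sums over the respective site
counts. Genes lacking synonymous and/or nonsynonymous polymorphism have an
undefined ratio and are excluded; `piN/piS > 1.0` flags a candidate.

Fixed differences are positions where the selected pool is monomorphic
(single allele, coverage in range, zero alternate reads after quality
filtering — the strictest reading of "fixed", with no frequency tolerance)
while the control pool still segregates under the SNP rule. Positions
covered in only one pool are skipped and counted.

## The synthetic-data generator

The generator emulates the inputs of a two-pool study of common origin. Per
chromosome, polymorphic sites are placed i.i.d. with per-site probability
`theta * a1(pool_size)` (the Watterson expectation of segregation) and each
site's allele frequency is `i/pool_size` with `i` drawn from weights
`1/i + 1/(pool_size - i)` — the neutral folded spectrum. With these choices
the expected pool heterozygosity per site equals theta exactly. Reads are
then Poisson-coverage, binomially sampled from the site frequency, with a
uniform base-error process flipping individual reads.

Defaults (the study conditions of the test suite): two 5-Mbp chromosome
arms, theta = 0.002 (inside the fly autosomal arm-level band), Poisson
coverage mean 60, pool of 100 chromosomes, residual error rate 5e-5, and one
1-Mbp sweep at 200-fold reduction on one arm. The error rate is the
post-quality-filter, post-mapping substitution rate; the rendered quality
strings (around Phred 38) are cosmetic and independent of the error process.
The sweep spans two full 500-kb windows plus flanks because only windows
entirely inside a swept tract can show ~100-fold reductions; the flagged
runs real scans report imply tracts of this scale. Sweeps thin polymorphism
binomially (each site survives with probability 1/factor, otherwise fixing
for its major allele), so majority-alternate sites become fixed differences
— exactly the signal the fixed-vs-segregating detector looks for.

Simulated genes are tiled two-exon models with alternating strands on the
neutral arm. Selection modes constrain CDS polymorphism: `nonsyn_excess`
clears background CDS variation and implants enough verified nonsynonymous
SNPs (plus three synonymous, so the ratio is defined) that piN/piS lands
well above 1; `syn_only` implants synonymous SNPs only; `neutral` leaves the
background. Implanted variants sit at frequency 0.5 and are validated
through the codon classifier at build time.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: linkage and coalescent genealogies (sites are
independent, so D is calibrated only approximately and sweep detection tests
rest on the diversity contrast, which is the procedure's primary signal);
demography and migration; mapping artefacts, indels and structural
variation; base-quality miscalibration; finite-pool read resampling
(reads are drawn from the population frequency directly).

## Calibration and numerical notes

* Neutral window diversity recovers ~0.96–0.97 of theta at the default
  conditions. The shortfall is deterministic, not noise: the folded-spectrum
  expectation contributes a factor (pool-1)/pool (~1%), and min-count
  gating discards true sites whose minor allele is seen in a single read
  (~2.5% at coverage 60). The ungated alternative overshoots by ~+4–5%
  through error singletons. The bias is uniform across a genome, and the
  sweep statistic (a ratio of window to arm mean) cancels it.
* Neutral mean D at the defaults sits near -0.4 — inside the acknowledged
  negative-bias band for read-based Pool-seq D — while fully swept windows
  fall below -2.5; the contrast, not the absolute level, carries the signal.
* Sweep recovery at the defaults: a 200-fold, 1-Mbp sweep is recovered as an
  overlapping major interval in >= 95 of 100 replicates at 3-Mbp chromosome
  scale (the statistical tests' problem size), with false major intervals on
  fully neutral chromosomes in <= 5 of 100.
* Tajima constants are evaluated directly from their definitions and checked
  against exact rational arithmetic; `e1, e2 > 0` throughout n in [4, 1000].
* All randomness flows from a single seed through named
  `numpy.random.SeedSequence` fan-outs (per stage, per chromosome, per
  window, per gene), so every output is bit-reproducible and partial reruns
  are consistent.
* Degenerate inputs: zero-coverage and sub-min-coverage sites count toward
  nothing but the covered-fraction denominator; windows truncate at
  chromosome ends; unsorted pileups and mixed-chromosome aggregations raise
  errors naming the first offending position.

## Limitations

The estimators are intentionally the simple read-based forms; no
Kofler-style pooled corrections are applied (an optional pool-size-corrected
mode is out of scope for the default pipeline since the pool size of the
motivating datasets is typically unreported). Fold-reduction cutoffs have no
attached significance model. The coding scan analyses one transcript per
gene and ignores splice-isoform differences. BAM input, read trimming and
alignment are outside the package boundary: the pileup is the contract.
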