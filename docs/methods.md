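# Methods

## LD measure

The package's LD statistic is the squared Pearson correlation between two
SNPs' additive dosage vectors (0/1/2 copies of allele B), computed over
pairwise-complete samples. This genotype-level r² is the measure chip
studies report when phase is unknown: it needs no haplotype inference, is
symmetric, and is invariant to swapping either SNP's allele labels
(d → 2 − d), so the arbitrary choice of which allele dosage counts cannot
affect any downstream summary. Under random mating (genotypes in
Hardy–Weinberg proportions and two-locus frequencies at their random-union
values) its expectation coincides with the haplotype-level
r² = D²/(p_A q_A p_B q_B); the package carries an independent EM estimator
of the four haplotype frequencies (expectation step splits only the
double heterozygote between coupling and repulsion phases, starting from an
equal split; convergence when the largest frequency change is below 1e−10)
precisely so the two routes can be compared on data with known truth. On
multinomial two-SNP panels of n = 10,000 the two agree within ~0.03 and the
EM recovers the generating frequencies within ~0.01 (see the acceptance
tests).

Pairs with fewer than 2 complete observations or zero dosage variance at
either SNP have undefined r²; they are skipped and tallied, never silently
dropped. Pairs at zero distance (duplicate map positions) are likewise
excluded and counted.

## QC cascade

Filters run in a fixed order — call rate, no-het degeneracy, exact
Hardy–Weinberg test, unknown position, sex chromosome, MAF floor — and each
removed SNP is attributed to the first filter that rejects it, so the
report's counts always sum to input − retained and the cascade is
idempotent. Defaults follow common chip-QC practice:

- **call rate** ≥ 0.90 retained (removal requires strictly < 0.90);
- **no-het rule**: both homozygote classes present with zero heterozygotes
  is an assay artefact signature and is removed outright (monomorphic SNPs
  are left to the MAF floor);
- **Hardy–Weinberg**: the exact conditional test — condition on the
  observed allele counts, enumerate all heterozygote counts of the same
  parity, sum the probabilities of outcomes no more probable than the
  observed one — at α = 1e−6, a conventional chip threshold. Computed in
  log-space with a 1e−12 relative slack when comparing probability masses
  so floating-point rounding cannot break ties; validated against an exact
  rational-arithmetic enumeration.
- **MAF floor** 0.03, *strict*: a SNP at exactly 0.03 is retained, so the
  first spectrum category (which begins at 0.03) stays populated. The
  boundary convention is configurable (`maf_drop_equal`) because reasonable
  pipelines differ here.

No per-sample QC is performed, and no pedigree-based checks: neither has a
defensible default without pedigree records.

## MAF spectrum

MAF is estimated from genotype counts with missing genotypes excluded from
the denominator, folded to [0, 0.5]. The five categories
[0.03, 0.1), [0.1, 0.2), [0.2, 0.3), [0.3, 0.4), [0.4, 0.5] assign every
edge to the upper bin, with 0.5 closing the last bin. SNPs below 0.03 are
tallied separately as excluded and do not enter the proportions, which are
taken over binned SNPs only. Per-chromosome counts sum to the genome-wide
counts by construction (each SNP belongs to exactly one chromosome group).

## Decay curves and crossing distance

Pairs are assigned to half-open distance windows [lo, hi) of fixed width;
the final window also accepts pairs at exactly the distance cap so the
advertised range (0, max] is covered. Bin SD uses the n − 1 denominator and
is undefined (NaN) for bins with fewer than 2 pairs; empty bins are
reported with NaN means rather than omitted, so curves from the same
configuration always align row-for-row.

The crossing distance scans non-empty bins in ascending distance for the
first adjacent pair whose means straddle the level (mean_i ≥ L > mean_{i+1})
and interpolates linearly between the two bin midpoints. If the first
non-empty bin is already below the level its midpoint is returned with a
`below_from_start` flag; if the mean never drops below the level the result
is `not_reached`. The straddling bins are returned alongside the
interpolated value so users preferring an edge convention can apply their
own rule.

The conventional r² ≥ 0.1 prefilter is available (and is the pipeline
default for decay tables, mirroring common practice) but it truncates the
r² distribution from below and therefore inflates every bin mean — a
monotone bias the test suite asserts. Summaries record whether the filter
was applied.

## Wright–Fisher simulator

The generator is a discrete-generation forward simulator: 2·Ne founder
haplotypes receive independent Bernoulli alleles with per-SNP frequencies
drawn from the configured law (default uniform(0.05, 0.5)), giving exact
initial linkage equilibrium. Each generation forms Ne diploids by random
mating (parents drawn uniformly with replacement, selfing allowed); each
transmitted gamete recombines with a Poisson number of crossovers (mean =
chromosome map length in Morgans, default rate 1e−8 M/bp = 1 cM/Mb) at
uniform map positions, without interference. After the configured number of
generations, n_sample individuals are drawn without replacement and their
haplotypes summed into dosages; missingness is applied uniformly at random.
Chromosomes are simulated as independent replicates of the same population
process, which is exact for within-chromosome LD statistics because
chromosomes assort freely. Output is a pure function of the config
including the seed.

Because founders carry no LD, all terminal LD is drift-generated — the
regime Sved's approximation E[r²] ≈ 1/(1 + 4·Ne·c) describes at
drift–recombination equilibrium. Equilibration is not instantaneous: r²
between loci at recombination fraction c approaches its equilibrium on a
timescale of order min(2·Ne, 1/(2c)) generations, so short runs leave
tightly linked pairs below their equilibrium LD and the fitted Ne above the
simulated value. The parameter-recovery experiment in the acceptance suite
therefore runs 300 generations at Ne = 100 (three times Ne) across four
independent chromosomes of 120 markers at 25 kb spacing, where the median
fitted Ne over ten seeds lands within ±40% of truth — the residual spread
is genuine drift noise at this population size, not estimator error.

What the generator does *not* emulate: mutation after generation 0,
selection, migration, overlapping generations, variable recombination maps,
ascertainment bias of chip SNP discovery, genotyping error, and
family structure in the sample. Passing tests on simulated panels therefore
validate the statistical machinery, not the biological faithfulness of any
particular chip; on real data the MAF spectrum additionally reflects the
chip's ascertainment scheme, and the decay curve reflects the population's
full demographic history rather than a single equilibrium Ne.

## Ne estimation

`fit_ne_from_decay` minimizes the sum of squared differences between bin
means and Sved's expectation (c = bin midpoint / bp-per-Morgan, optional
+ 1/n sample-size inflation, curve capped at 1) over log Ne, using a coarse
deterministic grid start followed by bounded least squares with tight
tolerances; on a noiseless Sved curve the simulated Ne is recovered to
better than 1e−6. At least 3 non-empty bins are required, flat curves are
rejected as non-identifiable, and curves built from r²-prefiltered pairs
are refused unless explicitly overridden, because the floor biases Ne
downward. With few distance bins the estimate compresses the population's
history into one number; it should be read as an order-of-magnitude
summary, not a demographic inference.

## File formats

PLINK 1 text (PED/MAP) and binary (BED/BIM/FAM, SNP-major, magic bytes
`6C 1B 01`, two bits per genotype packed little-endian within each byte,
rows padded to byte boundaries) are read and written bit-exactly; an
individual-major BED mode byte is rejected. On PED import alleles are
assigned from observed counts (minor → a1, lexicographic tie-break), so
import normalizes allele polarity: a dataset whose stored a2 is the
minor-count allele flips dosage polarity on its first write→read cycle,
after which the cycle is the identity. r² and MAF are invariant to this
polarity. Position 0 encodes an unknown genomic position; MISSING is a
negative sentinel (−1) that can never enter dosage arithmetic unmasked.

## Pipeline determinism

`run_pipeline` writes CSVs whose bytes depend only on the input files and
the configuration; the JSON manifest records the config, package version,
SHA-256 checksums of the inputs, and the pair-count bookkeeping
(candidate = emitted + undefined + zero-distance + filtered), so silent
input drift between runs is detectable. The acceptance script's panel — 29
autosomes, 120 markers each, irregular positions at ~49 kb mean spacing,
Ne = 500 for 500 generations, 1% missingness — was chosen to emulate a
medium-density chip on a small closed population whose mean r² remains
above 0.3 to roughly the 100 kb scale; problem sizes throughout the test
suite are set so the full validation runs in well under a minute of
simulation time while keeping ≥ 200 pairs in every bin used for inference.
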